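"""Double-stranded PSSM scanning, composite cluster detection and densities.

Hits are windows whose conservative theoretical p-value is <= alpha; any
window containing a masked position is unscoreable and contributes neither a
hit nor a window to rate denominators. Reverse-strand hits are reported in
forward coordinates. A composite cluster is one anchor (Hox/Pbx) hit with at
least one partner (Meis) hit whose edge-to-edge gap is within the spacing
window on either side (overlap counts as gap 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .motif_model import ScoreDistribution, ScoringMatrix
from .sequence_io import MASKED_CODE, MaskedSequence

__all__ = [
    "MotifHit",
    "CompositeCluster",
    "DensityResult",
    "scan",
    "window_scores",
    "count_scannable_windows",
    "detect_clusters",
    "cluster_density",
    "hits_to_bed",
]


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    motif_id: str
    start: int  # forward coordinates, 0-based half-open
    end: int
    strand: str
    score: float
    pvalue: float


@dataclass(frozen=True)
class CompositeCluster:
    seq_id: str
    anchor: MotifHit
    partners: tuple[MotifHit, ...]
    span: tuple[int, int]
    gap: int  # nt between nearest edges of anchor and closest partner


@dataclass(frozen=True)
class DensityResult:
    set_id: str
    n_clusters: int
    scanned_kb: float
    density: float  # clusters per kb of unmasked sequence


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge distance between two intervals; 0 when they overlap."""
    return max(b_start - a_end, a_start - b_end, 0)


def window_scores(seq: MaskedSequence, sm: ScoringMatrix):
    """Scores of every scoreable window on both strands.

    Returns (positions, fwd_scores, rev_scores); positions are the forward
    start coordinates of windows containing no masked letter.
    """
    w = sm.width
    codes = seq.codes()
    if len(codes) < w:
        return np.empty(0, dtype=int), np.empty(0), np.empty(0)
    win = sliding_window_view(codes, w)
    valid = (win != MASKED_CODE).all(axis=1)
    pos = np.nonzero(valid)[0]
    if pos.size == 0:
        return pos, np.empty(0), np.empty(0)
    wv = win[pos]
    cols = np.arange(w)
    fwd = sm.scores[cols[None, :], wv].sum(axis=1)
    rc = sm.reverse_complement().scores
    rev = rc[cols[None, :], wv].sum(axis=1)
    return pos, fwd, rev


def scan(
    seqs,
    sm: ScoringMatrix,
    dist: ScoreDistribution,
    alpha: float = 1e-4,
) -> list[MotifHit]:
    """All hits with p-value <= alpha, sorted by (seq_id, start, strand)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    w = sm.width
    hits: list[MotifHit] = []
    tol = alpha * (1 + 1e-12)
    for seq in seqs:
        pos, fwd, rev = window_scores(seq, sm)
        if pos.size == 0:
            continue
        for strand, scores in (("+", fwd), ("-", rev)):
            pv = dist.pvalues(scores)
            sel = np.nonzero(pv <= tol)[0]
            hits.extend(
                MotifHit(
                    seq.seq_id, sm.motif_id,
                    int(pos[i]), int(pos[i]) + w, strand,
                    float(scores[i]), float(pv[i]),
                )
                for i in sel
            )
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand, h.motif_id))
    return hits


def count_scannable_windows(seqs, width: int) -> int:
    """Unmasked width-w windows summed over sequences, times 2 strands."""
    total = 0
    for seq in seqs:
        codes = seq.codes()
        if len(codes) < width:
            continue
        win = sliding_window_view(codes, width)
        total += int((win != MASKED_CODE).all(axis=1).sum())
    return 2 * total


def detect_clusters(anchor_hits, partner_hits, window: int = 40) -> list[CompositeCluster]:
    """Pair each anchor with all partners within the spacing window.

    One cluster per anchor hit with >= 1 qualifying partner; anchors without
    a partner yield nothing. Sorted by (seq_id, anchor start).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_seq: dict[str, list[MotifHit]] = {}
    for p in partner_hits:
        by_seq.setdefault(p.seq_id, []).append(p)
    for plist in by_seq.values():
        plist.sort(key=lambda h: h.start)
    clusters: list[CompositeCluster] = []
    for a in anchor_hits:
        near = [
            p for p in by_seq.get(a.seq_id, ())
            if _gap(a.start, a.end, p.start, p.end) <= window
        ]
        if not near:
            continue
        gap = min(_gap(a.start, a.end, p.start, p.end) for p in near)
        span = (
            min([a.start] + [p.start for p in near]),
            max([a.end] + [p.end for p in near]),
        )
        clusters.append(CompositeCluster(a.seq_id, a, tuple(near), span, gap))
    clusters.sort(key=lambda c: (c.seq_id, c.anchor.start, c.anchor.strand))
    return clusters


def cluster_density(clusters, seqs, set_id: str = "regions") -> DensityResult:
    """Clusters per kilobase of unmasked sequence in the region set."""
    unmasked = sum(s.unmasked_length for s in seqs)
    if unmasked == 0:
        raise ValueError("scanned_kb is zero: region set has no unmasked sequence")
    kb = unmasked / 1000.0
    n = len(clusters)
    return DensityResult(set_id, n, kb, n / kb)


def hits_to_bed(hits, path) -> None:
    """BED6 + motif_id, score, pvalue extra columns."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.motif_id}\t"
                f"{h.score:.4f}\t{h.strand}\t{h.pvalue:.4g}\n"
            )
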