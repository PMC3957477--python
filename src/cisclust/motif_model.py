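"""Count matrices, log-odds scoring, exact score distributions and p-values.

A binding-site model starts life as a per-position nucleotide count matrix
(:class:`CountMatrix`), is converted against an order-0 background into a
log2-odds :class:`ScoringMatrix`, and from there into the exact theoretical
distribution of window scores under that background
(:class:`ScoreDistribution`), computed by position-wise convolution over a
discretised score grid.  Site p-values are upper-tail lookups in that
distribution.

Rounding convention
-------------------
Column scores are rounded *up* to the bin grid inside the convolution, while
p-value queries use the word's exact score.  Every word whose exact score is
>= s then has a binned score >= s, so the reported p-value is conservative:
it is never smaller than the exact enumeration p-value, and exceeds it by at
most the exact probability mass lying within ``width * bin_width`` below s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DNA = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(DNA)}

__all__ = [
    "DNA",
    "Background0",
    "CountMatrix",
    "ScoringMatrix",
    "ScoreDistribution",
    "build_scoring_matrix",
    "score_word",
    "score_distribution",
    "pvalue",
    "permute_matrix",
    "read_count_matrices",
    "write_count_matrix",
    "write_distribution_tsv",
]


@dataclass(frozen=True)
class Background0:
    """Order-0 nucleotide background: one probability per base, summing to 1."""

    probs: tuple[float, float, float, float]  # A, C, G, T

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4,):
            raise ValueError("background needs exactly 4 probabilities (A,C,G,T)")
        if not np.all(p > 0):
            raise ValueError("background probabilities must all be > 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("background probabilities must sum to 1")

    @classmethod
    def uniform(cls) -> "Background0":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "Background0":
        return cls(tuple(float(d[b]) for b in DNA))

    @classmethod
    def from_sequences(cls, seqs, pseudocount: float = 1.0) -> "Background0":
        """Estimate base frequencies from unmasked positions of sequences.

        `seqs` is any iterable of objects with a ``residues`` string (see
        sequence_io.MaskedSequence) or plain strings; lowercase and N are
        ignored.
        """
        counts = np.full(4, float(pseudocount))
        for s in seqs:
            res = getattr(s, "residues", s)
            for b in res:
                i = BASE_INDEX.get(b)  # lowercase/N -> None
                if i is not None:
                    counts[i] += 1
        return cls(tuple(counts / counts.sum()))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


@dataclass
class CountMatrix:
    """Per-position nucleotide counts for one site model.

    ``counts`` has shape (width, 4), columns ordered A, C, G, T.
    """

    motif_id: str
    counts: np.ndarray
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] < 1:
            raise ValueError("counts must have shape (width >= 1, 4)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if np.any(self.counts.sum(axis=1) + 4 * self.pseudocount <= 0):
            raise ValueError("degenerate column: zero total count and zero pseudocount")

    @classmethod
    def from_dicts(cls, motif_id: str, columns, pseudocount: float = 0.25) -> "CountMatrix":
        arr = np.array([[col[b] for b in DNA] for col in columns], dtype=float)
        return cls(motif_id, arr, pseudocount)

    @property
    def width(self) -> int:
        return self.counts.shape[0]


@dataclass
class ScoringMatrix:
    """log2-odds scores per position and base; shape (width, 4)."""

    motif_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 4:
            raise ValueError("scores must have shape (width, 4)")

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.scores.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in self.scores.argmax(axis=1))

    def reverse_complement(self) -> "ScoringMatrix":
        return ScoringMatrix(self.motif_id, self.scores[::-1, ::-1].copy())


def build_scoring_matrix(cm: CountMatrix, bg: Background0) -> ScoringMatrix:
    """Convert counts to log2( frequency / background ) scores.

    frequency[i][x] = (counts[i][x] + pseudocount) / sum_y (counts[i][y] + pseudocount)

    Raises ValueError("degenerate column ...") if any cell frequency is zero
    (possible only with pseudocount 0).
    """
    adj = cm.counts + cm.pseudocount
    totals = adj.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("degenerate column: zero total count")
    freq = adj / totals[:, None]
    if np.any(freq <= 0):
        pos = int(np.argwhere(freq <= 0)[0][0])
        raise ValueError(
            f"degenerate column {pos}: zero frequency with pseudocount 0; "
            "use a positive pseudocount"
        )
    return ScoringMatrix(cm.motif_id, np.log2(freq / bg.as_array()[None, :]))


def score_word(sm: ScoringMatrix, word: str) -> float:
    """Exact score of one width-w word (sum of per-position lookups).

    Words containing masked (lowercase) or ambiguous letters are not
    scoreable and raise ValueError("unscoreable window").
    """
    if len(word) != sm.width:
        raise ValueError(f"word length {len(word)} != matrix width {sm.width}")
    try:
        idx = [BASE_INDEX[b] for b in word]
    except KeyError:
        raise ValueError("unscoreable window") from None
    return float(sm.scores[np.arange(sm.width), idx].sum())


@dataclass
class ScoreDistribution:
    """Discretised exact distribution of window scores under an order-0 background.

    ``bins`` are integer multiples of ``bin_width`` (ascending);
    ``probs`` the corresponding probabilities (sum to 1).
    """

    bin_width: float
    bins: np.ndarray  # int64 bin indices, ascending
    probs: np.ndarray
    sf: np.ndarray = field(init=False)  # P(score >= bins[k]*bin_width)

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.int64)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.bins.shape != self.probs.shape or self.bins.ndim != 1:
            raise ValueError("bins and probs must be 1-D and aligned")
        if np.any(np.diff(self.bins) <= 0):
            raise ValueError("bins must be strictly ascending")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        self.sf = np.cumsum(self.probs[::-1])[::-1]

    @property
    def support(self) -> list[tuple[float, float]]:
        return [(float(b * self.bin_width), float(p)) for b, p in zip(self.bins, self.probs)]

    @property
    def min_pvalue(self) -> float:
        """Smallest attainable p-value (p-value of the maximum score)."""
        return float(self.sf[-1])

    def pvalues(self, scores) -> np.ndarray:
        """Vectorised upper-tail P(binned score >= s) for exact scores s."""
        s = np.asarray(scores, dtype=float)
        # first bin whose value is >= s (tolerance keeps exact grid points stable)
        k = np.searchsorted(self.bins * self.bin_width, s - 1e-9, side="left")
        out = np.where(k < len(self.bins), self.sf[np.minimum(k, len(self.bins) - 1)], 0.0)
        return out if out.shape else float(out)

    def pvalue(self, s: float) -> float:
        return float(self.pvalues(s))

    def score_threshold(self, alpha: float) -> float:
        """Smallest support score s with P(>= s) <= alpha (inf if unattainable)."""
        ok = self.sf <= alpha * (1 + 1e-12)
        if not ok.any():
            return float("inf")
        return float(self.bins[np.argmax(ok)] * self.bin_width)


def score_distribution(
    sm: ScoringMatrix, bg: Background0, bin_width: float = 0.01
) -> ScoreDistribution:
    """Exact distribution of the total score over iid background letters.

    Position-wise convolution over integer score bins; column scores are
    rounded up (ceil) to the grid, making downstream p-values conservative.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    p = bg.as_array()
    # ceil with a tolerance so scores already on the grid are not pushed up
    col_bins = np.ceil(sm.scores / bin_width - 1e-9).astype(np.int64)
    for i in range(sm.width):
        if len(set(col_bins[i])) < len(set(np.round(sm.scores[i], 12))):
            warnings.warn(
                f"bin_width {bin_width} collapses distinct scores in column {i}",
                stacklevel=2,
            )
    lo = 0
    arr = np.array([1.0])
    for i in range(sm.width):
        cmin, cmax = int(col_bins[i].min()), int(col_bins[i].max())
        col = np.zeros(cmax - cmin + 1)
        for b in range(4):
            col[col_bins[i, b] - cmin] += p[b]
        arr = np.convolve(arr, col)
        lo += cmin
    bins = lo + np.arange(len(arr))
    keep = arr > 0
    return ScoreDistribution(bin_width, bins[keep], arr[keep])


def pvalue(dist: ScoreDistribution, s: float) -> float:
    """P(score >= s) under the theoretical distribution (conservative)."""
    return dist.pvalue(s)


def permute_matrix(cm: CountMatrix, mode: str = "columns", seed=None) -> CountMatrix:
    """Seeded random permutation of matrix columns (positions).

    Under an order-0 background the theoretical score distribution is
    invariant to column order, so permuted matrices keep the statistical
    properties of the original while destroying the biological word.
    """
    if mode != "columns":
        raise ValueError(f"unsupported permutation mode: {mode!r}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cm.width)
    return CountMatrix(cm.motif_id, cm.counts[perm].copy(), cm.pseudocount)


# ---------------------------------------------------------------------------
# I/O: JASPAR-like whitespace-delimited count files, one motif per record
# ---------------------------------------------------------------------------

def read_count_matrices(path, pseudocount: float = 0.25) -> list[CountMatrix]:
    """Read count matrices: '>motif_id' header then 4 rows labeled A C G T."""
    matrices: list[CountMatrix] = []
    motif_id = None
    rows: dict[str, list[float]] = {}

    def flush():
        if motif_id is None:
            return
        missing = [b for b in DNA if b not in rows]
        if missing:
            raise ValueError(f"matrix {motif_id!r}: missing rows for {missing}")
        widths = {len(rows[b]) for b in DNA}
        if len(widths) != 1:
            raise ValueError(f"matrix {motif_id!r}: ragged rows")
        arr = np.array([rows[b] for b in DNA], dtype=float).T
        matrices.append(CountMatrix(motif_id, arr, pseudocount))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                rows = {}
            else:
                fields = line.replace("[", " ").replace("]", " ").split()
                base = fields[0].upper()
                if base not in DNA:
                    raise ValueError(f"unexpected row label {fields[0]!r}")
                rows[base] = [float(x) for x in fields[1:]]
    flush()
    if not matrices:
        raise ValueError(f"no matrices found in {path}")
    return matrices


def write_count_matrix(cm: CountMatrix, fh) -> None:
    fh.write(f">{cm.motif_id}\n")
    for j, base in enumerate(DNA):
        vals = " ".join(f"{v:g}" for v in cm.counts[:, j])
        fh.write(f"{base} {vals}\n")


def write_distribution_tsv(dist: ScoreDistribution, path) -> None:
    """Two-column TSV: score_bin <TAB> P(score >= bin)."""
    with open(path, "w") as fh:
        fh.write("score_bin\tp_ge\n")
        for b, s in zip(dist.bins, dist.sf):
            fh.write(f"{b * dist.bin_width:.6g}\t{s:.10g}\n")
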