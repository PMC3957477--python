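"""Sequence and interval I/O: FASTA, BED6, a minimal GFF3 subset, promoter
extraction and non-coding region complements.

Coordinates are 0-based half-open everywhere internally (BED-native); GFF is
converted on read. Masking follows the repeat-masking convention: lowercase
letters and N count as masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .motif_model import BASE_INDEX

logger = logging.getLogger(__name__)

MASKED_CODE = 4
_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

__all__ = [
    "MaskedSequence",
    "GeneRecord",
    "PromoterSet",
    "RegionSet",
    "BedRecord",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_genes_bed",
    "extract_promoters",
    "noncoding_regions",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MaskedSequence:
    """A DNA sequence whose lowercase/N positions are treated as masked."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.seq_id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def mask(self) -> frozenset[int]:
        """0-based positions that are masked (lowercase or N)."""
        return frozenset(np.nonzero(self.codes() == MASKED_CODE)[0].tolist())

    def codes(self) -> np.ndarray:
        """Integer encoding A,C,G,T -> 0..3; masked/ambiguous -> 4."""
        arr = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        lut = np.full(256, MASKED_CODE, dtype=np.int8)
        for b, i in BASE_INDEX.items():
            lut[ord(b)] = i
        return lut[arr].astype(np.int64)

    @property
    def unmasked_length(self) -> int:
        return int((self.codes() != MASKED_CODE).sum())

    def reverse_complement(self) -> "MaskedSequence":
        return MaskedSequence(self.seq_id, reverse_complement(self.residues))


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int  # 0-based; for '-' genes the coordinate just past the first base
    tissue_label: str = "none"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative tss")


@dataclass
class PromoterSet:
    """A labeled collection of (masked) promoter sequences."""

    set_id: str
    sequences: list[MaskedSequence]
    upstream_len: int | None = None
    tissue_label: str = "none"

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class RegionSet:
    set_id: str
    intervals: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open
    source_label: str = "custom"

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "+"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[MaskedSequence]:
    """One MaskedSequence per record, case preserved; duplicate ids error."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    seqs, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seqs.append(MaskedSequence(rec.id, str(rec.seq)))
    return seqs


def write_fasta(seqs, path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.seq_id}\n")
            for i in range(0, len(s.residues), line_width):
                fh.write(s.residues[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[BedRecord]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            start, end = int(f[1]), int(f[2])
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{ln}: bad interval {start}-{end}")
            out.append(
                BedRecord(
                    f[0], start, end,
                    f[3] if len(f) > 3 else ".",
                    f[4] if len(f) > 4 else "0",
                    f[5] if len(f) > 5 else "+",
                )
            )
    return out


def write_bed(records, path, extra_fields=None) -> None:
    """Write BED6 (+ optional parallel list of extra-column tuples)."""
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            row = [r.chrom, str(r.start), str(r.end), r.name, str(r.score), r.strand]
            if extra_fields is not None:
                row.extend(str(x) for x in extra_fields[i])
            fh.write("\t".join(row) + "\n")


def read_genes_bed(path, tissue_label: str = "none") -> list[GeneRecord]:
    """BED6 gene intervals -> GeneRecords; TSS = start (+) or end (-)."""
    genes = []
    for r in read_bed(path):
        tss = r.start if r.strand == "+" else r.end
        genes.append(GeneRecord(r.name, r.chrom, r.strand, tss, tissue_label))
    return genes


# ---------------------------------------------------------------------------
# Promoters and non-coding regions
# ---------------------------------------------------------------------------

def extract_promoters(
    genes,
    genome: dict[str, MaskedSequence] | list[MaskedSequence],
    upstream_len: int = 1000,
    set_id: str | None = None,
) -> PromoterSet:
    """Fixed-length windows strictly upstream of each TSS.

    '+' strand: [tss - L, tss), forward sequence.
    '-' strand: [tss, tss + L), reverse-complemented.
    Windows are truncated at contig edges (logged); genes on missing contigs
    are skipped (logged).
    """
    if upstream_len < 1:
        raise ValueError("upstream_len must be >= 1")
    if not isinstance(genome, dict):
        genome = {s.seq_id: s for s in genome}
    sequences, labels = [], set()
    for g in genes:
        contig = genome.get(g.chrom)
        if contig is None:
            logger.warning("gene %s: contig %s absent from genome; skipped", g.gene_id, g.chrom)
            continue
        clen = len(contig)
        if not (0 <= g.tss <= clen):
            logger.warning("gene %s: tss %d off contig %s; skipped", g.gene_id, g.tss, g.chrom)
            continue
        if g.strand == "+":
            start, end = g.tss - upstream_len, g.tss
        else:
            start, end = g.tss, g.tss + upstream_len
        tstart, tend = max(start, 0), min(end, clen)
        if (tstart, tend) != (start, end):
            logger.warning(
                "gene %s: promoter truncated to [%d, %d) at contig edge", g.gene_id, tstart, tend
            )
        if tstart >= tend:
            logger.warning("gene %s: empty promoter window; skipped", g.gene_id)
            continue
        sub = contig.residues[tstart:tend]
        if g.strand == "-":
            sub = reverse_complement(sub)
        sequences.append(MaskedSequence(f"{g.gene_id}|promoter", sub))
        labels.add(g.tissue_label)
    label = labels.pop() if len(labels) == 1 else "none"
    return PromoterSet(
        set_id or f"promoters_{upstream_len}bp",
        sequences,
        upstream_len=upstream_len,
        tissue_label=label,
    )


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_gff(path) -> list[dict]:
    """Minimal GFF3: seqid, type, start, end, strand, ID attribute.

    Coordinates are converted from 1-based closed to 0-based half-open.
    """
    feats = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{ln}: GFF needs >= 8 columns")
            attrs = f[8] if len(f) > 8 else ""
            fid = "."
            for kv in attrs.split(";"):
                if kv.strip().startswith("ID="):
                    fid = kv.strip()[3:]
            feats.append(
                {
                    "seqid": f[0],
                    "type": f[2],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                    "id": fid,
                }
            )
    return feats


def noncoding_regions(
    annotation,
    genome: dict[str, MaskedSequence] | list[MaskedSequence],
    min_len: int = 60,
    feature_types: tuple[str, ...] = ("gene", "exon", "CDS"),
    set_id: str = "noncoding_all",
) -> RegionSet:
    """Complement of annotated features over the genome, length-filtered.

    `annotation` is a GFF path or a pre-parsed feature list (see read_gff).
    """
    if not isinstance(genome, dict):
        genome = {s.seq_id: s for s in genome}
    feats = annotation if isinstance(annotation, list) else read_gff(annotation)
    by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for f in feats:
        if f["type"] not in feature_types:
            continue
        if f["seqid"] not in genome:
            raise ValueError(f"contig {f['seqid']!r} in annotation but absent from genome")
        by_contig[f["seqid"]].append((f["start"], f["end"]))
    intervals: list[tuple[str, int, int]] = []
    for chrom in sorted(by_contig):
        clen = len(genome[chrom])
        pos = 0
        for s, e in _merge(by_contig[chrom]) + [(clen, clen)]:
            s, e = max(0, min(s, clen)), max(0, min(e, clen))
            if s - pos >= min_len:
                intervals.append((chrom, pos, s))
            pos = max(pos, e)
    return RegionSet(set_id, intervals, source_label="noncoding_all")


def region_sequences(regions: RegionSet, genome) -> list[MaskedSequence]:
    """Materialise a RegionSet as sequences named chrom:start-end."""
    if not isinstance(genome, dict):
        genome = {s.seq_id: s for s in genome}
    out = []
    for chrom, start, end in regions.intervals:
        contig = genome[chrom]
        out.append(MaskedSequence(f"{chrom}:{start}-{end}", contig.residues[start:end]))
    return out
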