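"""Hexapeptide (HX) candidate scanning in protein sequences.

The rule: an invariant tryptophan with a lysine or arginine at offset +2 to
+5, flagged (not filtered) for hydrophobic context at the W's immediate
neighbours, and optionally positioned relative to a user-annotated
homeodomain start.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

HYDROPHOBIC = frozenset("AVLIMFYP")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = frozenset(AMINO_ACIDS + "X")

__all__ = ["ProteinRecord", "HxMatch", "hx_scan", "read_protein_fasta", "write_matches_tsv"]


@dataclass(frozen=True)
class ProteinRecord:
    prot_id: str
    residues: str
    hd_start: int | None = None  # 0-based first residue of the homeodomain

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.prot_id!r} is empty")
        bad = set(self.residues.upper()) - _VALID
        if bad:
            raise ValueError(f"protein {self.prot_id!r}: invalid residues {sorted(bad)}")
        if self.hd_start is not None and not 0 <= self.hd_start < len(self.residues):
            raise ValueError(f"protein {self.prot_id!r}: hd_start out of range")


@dataclass(frozen=True)
class HxMatch:
    prot_id: str
    position: int  # 0-based index of the tryptophan
    basic_offset: int  # +2..+5 offset of the supporting K/R (smallest)
    context_ok: bool
    upstream_of_hd: bool | None = None
    distance_to_hd: int | None = None


def hx_scan(p: ProteinRecord, hydrophobic=HYDROPHOBIC) -> list[HxMatch]:
    """Every tryptophan with K or R at +2..+5, sorted by position."""
    res = p.residues.upper()
    matches: list[HxMatch] = []
    for i, aa in enumerate(res):
        if aa != "W":
            continue
        offset = next(
            (d for d in (2, 3, 4, 5) if i + d < len(res) and res[i + d] in "KR"),
            None,
        )
        if offset is None:
            continue
        neighbours = res[max(i - 1, 0) : i] + res[i + 1 : i + 2]
        context_ok = any(c in hydrophobic for c in neighbours)
        upstream = dist = None
        if p.hd_start is not None:
            upstream = i < p.hd_start
            dist = p.hd_start - i
        matches.append(HxMatch(p.prot_id, i, offset, context_ok, upstream, dist))
    return matches


def read_protein_fasta(path, hd_positions: dict[str, int] | None = None) -> list[ProteinRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    hd_positions = hd_positions or {}
    return [
        ProteinRecord(r.id, str(r.seq), hd_positions.get(r.id)) for r in records
    ]


def write_matches_tsv(matches, path) -> None:
    with open(path, "w") as fh:
        fh.write("prot_id\tposition\tbasic_offset\tcontext_ok\tupstream_of_hd\tdistance_to_hd\n")
        for m in matches:
            fh.write(
                f"{m.prot_id}\t{m.position}\t{m.basic_offset}\t{int(m.context_ok)}\t"
                f"{'' if m.upstream_of_hd is None else int(m.upstream_of_hd)}\t"
                f"{'' if m.distance_to_hd is None else m.distance_to_hd}\n"
            )
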