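"""End-to-end orchestration of the two headline analyses.

``run_enrichment_analysis`` drives promoter extraction (or pre-extracted
promoter FASTAs) -> per-class scanning -> cluster detection -> enrichment
curves with controls -> verdicts. ``run_density_analysis`` computes composite
cluster densities over one or more region sets plus permuted-matrix
enrichment ratios. Both are deterministic given the config seed and write a
JSON report whose config echo suffices to rerun identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .enrichment import DEFAULT_ALPHAS, compare_sets
from .motif_model import (
    Background0,
    build_scoring_matrix,
    permute_matrix,
    read_count_matrices,
    score_distribution,
)
from .scanner import cluster_density, detect_clusters, scan
from .sequence_io import read_fasta

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_enrichment_analysis", "run_density_analysis"]


@dataclass
class RunConfig:
    """Parameters of one analysis run; every path must exist at run time."""

    mode: str  # enrichment | density
    matrices: list[str] = field(default_factory=list)  # anchor matrix files
    meis_matrix: str | None = None
    endoderm: str | None = None  # promoter FASTA
    ectoderm: str | None = None
    pool: str | None = None  # promoter pool FASTA for random-set control
    region_sets: dict[str, str] = field(default_factory=dict)  # set_id -> FASTA
    upstream: int = 1000
    window: int = 40
    min_noncoding_len: int = 60
    alphas: list[float] = field(default_factory=lambda: DEFAULT_ALPHAS.tolist())
    alpha_star: float = 1e-3
    cluster_alpha: float = 1e-4
    partner_alpha: float = 1e-3
    n_random: int = 100
    n_perms: int = 100
    seed: int = 0
    background: str = "auto"  # auto (estimate from scanned set) | uniform
    bin_width: float = 0.01
    pseudocount: float = 0.25

    def validate(self) -> None:
        if self.mode not in ("enrichment", "density"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.matrices:
            raise ValueError("config needs at least one anchor matrix")
        if self.mode == "enrichment" and not (self.endoderm and self.ectoderm):
            raise ValueError("enrichment mode needs endoderm and ectoderm FASTAs")
        if self.mode == "density" and not self.region_sets:
            raise ValueError("density mode needs at least one region set")
        if self.upstream not in (1000, 2000) and self.upstream < 1:
            raise ValueError("upstream must be positive")
        for p in self._paths():
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def _paths(self):
        yield from self.matrices
        for p in (self.meis_matrix, self.endoderm, self.ectoderm, self.pool):
            if p:
                yield p
        yield from self.region_sets.values()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunReport:
    config: dict
    input_digests: dict[str, str]
    stage_counts: dict[str, int]
    tables: dict
    verdicts: dict
    provenance: dict

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "report.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        return path


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _provenance(cfg: RunConfig) -> dict:
    return {
        "cisclust_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": cfg.seed,
    }


def _background(cfg: RunConfig, seqs) -> Background0:
    if cfg.background == "uniform":
        return Background0.uniform()
    if cfg.background == "auto":
        return Background0.from_sequences(seqs)
    raise ValueError(f"unknown background mode {cfg.background!r}")


def _write_curve_tsv(result, path) -> None:
    with open(path, "w") as fh:
        cols = ["alpha"]
        for name in result.curves:
            cols += [f"{name}_rate", f"{name}_fold"]
        for key in result.bands:
            cols += [f"{key}_mean", f"{key}_lo", f"{key}_hi"]
        fh.write("\t".join(cols) + "\n")
        for i, a in enumerate(result.alphas):
            row = [f"{a:.6g}"]
            for c in result.curves.values():
                row += [f"{c.observed_rate[i]:.6g}", f"{c.fold_enrichment[i]:.6g}"]
            for b in result.bands.values():
                row += [f"{b.mean[i]:.6g}", f"{b.lower[i]:.6g}", f"{b.upper[i]:.6g}"]
            fh.write("\t".join(row) + "\n")


def run_enrichment_analysis(config: RunConfig, out_dir="cisclust_out") -> RunReport:
    """Endoderm-vs-ectoderm enrichment per anchor matrix class (+ clusters)."""
    t0 = time.monotonic()
    config.validate()
    endo = read_fasta(config.endoderm)
    ecto = read_fasta(config.ectoderm)
    pool = read_fasta(config.pool) if config.pool else None
    from .sequence_io import PromoterSet  # local import avoids cycle at module load

    endo_set = PromoterSet("endoderm", endo, config.upstream, "endoderm")
    ecto_set = PromoterSet("ectoderm", ecto, config.upstream, "ectoderm")
    pool_set = PromoterSet("pool", pool) if pool else None

    anchors = []
    for mpath in config.matrices:
        anchors.extend(read_count_matrices(mpath, config.pseudocount))
    meis_cm = (
        read_count_matrices(config.meis_matrix, config.pseudocount)[0]
        if config.meis_matrix
        else None
    )
    bg = _background(config, endo + ecto)
    ss = np.random.SeedSequence(config.seed)
    substreams = dict(zip(["compare"], ss.spawn(1)))

    tables: dict = {}
    verdicts: dict = {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, cm in enumerate(anchors):
        logger.info("scanning anchor class %s", cm.motif_id)
        res = compare_sets(
            endo_set, ecto_set, cm,
            meis_cm=meis_cm, bg=bg,
            alphas=np.asarray(config.alphas), alpha_star=config.alpha_star,
            window=config.window, n_perms=config.n_perms,
            n_random=config.n_random if pool_set else 0, pool=pool_set,
            cluster_alpha=config.cluster_alpha, partner_alpha=config.partner_alpha,
            bin_width=config.bin_width,
            seed=substreams["compare"].spawn(len(anchors))[i],
        )
        tables[cm.motif_id] = res.to_dict()
        verdicts[cm.motif_id] = res.verdicts
        _write_curve_tsv(res, out / f"curves_{cm.motif_id}.tsv")

    report = RunReport(
        config=asdict(config),
        input_digests={p: _digest(p) for p in config._paths()},
        stage_counts={
            "endoderm_promoters": len(endo),
            "ectoderm_promoters": len(ecto),
            "pool_promoters": len(pool) if pool else 0,
            "anchor_matrices": len(anchors),
        },
        tables=tables,
        verdicts=verdicts,
        provenance={**_provenance(config), "wall_seconds": round(time.monotonic() - t0, 3)},
    )
    report.write(out)
    return report


def run_density_analysis(config: RunConfig, out_dir="cisclust_out") -> RunReport:
    """Composite-cluster densities per region set + permuted-matrix ratios."""
    t0 = time.monotonic()
    config.validate()
    anchors = []
    for mpath in config.matrices:
        anchors.extend(read_count_matrices(mpath, config.pseudocount))
    if not config.meis_matrix:
        raise ValueError("density mode needs --meis-matrix for cluster detection")
    meis_cm = read_count_matrices(config.meis_matrix, config.pseudocount)[0]

    region_seqs = {sid: read_fasta(path) for sid, path in config.region_sets.items()}
    all_seqs = [s for seqs in region_seqs.values() for s in seqs]
    bg = _background(config, all_seqs)

    msm = build_scoring_matrix(meis_cm, bg)
    mdist = score_distribution(msm, bg, config.bin_width)
    ss = np.random.SeedSequence(config.seed)

    tables: dict = {}
    for cm in anchors:
        sm = build_scoring_matrix(cm, bg)
        dist = score_distribution(sm, bg, config.bin_width)
        per_set = {}
        children = ss.spawn(len(region_seqs))
        for (sid, seqs), child in zip(region_seqs.items(), children):
            anchors_hits = scan(seqs, sm, dist, config.cluster_alpha)
            partner_hits = scan(seqs, msm, mdist, config.partner_alpha)
            clusters = detect_clusters(anchors_hits, partner_hits, config.window)
            dens = cluster_density(clusters, seqs, sid)
            # permuted-matrix null: same regions, shuffled anchor+partner columns
            null_counts = []
            for pc in child.spawn(config.n_perms):
                c1, c2 = pc.spawn(2)
                pa = build_scoring_matrix(permute_matrix(cm, seed=c1), bg)
                pm = build_scoring_matrix(permute_matrix(meis_cm, seed=c2), bg)
                ah = scan(seqs, pa, dist, config.cluster_alpha)
                ph = scan(seqs, pm, mdist, config.partner_alpha)
                null_counts.append(len(detect_clusters(ah, ph, config.window)))
            mean_null = float(np.mean(null_counts))
            per_set[sid] = {
                "n_clusters": dens.n_clusters,
                "scanned_kb": dens.scanned_kb,
                "density_per_kb": dens.density,
                "null_mean_clusters": mean_null,
                "enrichment_ratio": dens.n_clusters / mean_null if mean_null else float("inf"),
            }
        tables[cm.motif_id] = per_set

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "densities.tsv", "w") as fh:
        fh.write("matrix\tset_id\tn_clusters\tscanned_kb\tdensity_per_kb\t"
                 "null_mean_clusters\tenrichment_ratio\n")
        for mid, per_set in tables.items():
            for sid, row in per_set.items():
                fh.write(
                    f"{mid}\t{sid}\t{row['n_clusters']}\t{row['scanned_kb']:.3f}\t"
                    f"{row['density_per_kb']:.6g}\t{row['null_mean_clusters']:.3f}\t"
                    f"{row['enrichment_ratio']:.6g}\n"
                )
    report = RunReport(
        config=asdict(config),
        input_digests={p: _digest(p) for p in config._paths()},
        stage_counts={sid: len(seqs) for sid, seqs in region_seqs.items()},
        tables=tables,
        verdicts={},
        provenance={**_provenance(config), "wall_seconds": round(time.monotonic() - t0, 3)},
    )
    report.write(out)
    return report
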