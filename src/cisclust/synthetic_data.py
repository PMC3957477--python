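"""Synthetic inputs: Markov backgrounds, consensus-derived matrices, repeat
tracts, and labeled promoter sets with planted anchor+partner clusters.

Everything is a pure function of (parameters, seed); ground truth for planted
sites is emitted alongside the sequences so recovery can be scored exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .motif_model import BASE_INDEX, DNA, CountMatrix
from .sequence_io import MaskedSequence, PromoterSet, reverse_complement

__all__ = [
    "MarkovModel",
    "PlantingSpec",
    "PlantedSite",
    "SimulationResult",
    "train_markov",
    "sample_markov",
    "consensus_pwm",
    "default_matrices",
    "make_promoter_sets",
]

# consensus cores of the three Hox/Pbx site classes and the Meis site
HOX_PBX_CORES = {"hoxpbx_classI": "TGATTGAT", "hoxpbx_classII": "TGATTAAT",
                 "hoxpbx_classIII": "TGATTTAT"}
MEIS_CORE = "TGACAG"


@dataclass
class MarkovModel:
    """Order-k Markov chain over A,C,G,T.

    ``transitions`` has shape (4**k, 4): conditional base probabilities given
    the k-mer context (contexts indexed base-4, A=0..T=3). ``initial`` is the
    distribution of the first k-mer (length 4**k; scalar [1.0] for k = 0).
    """

    order: int
    initial: np.ndarray
    transitions: np.ndarray

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        self.initial = np.asarray(self.initial, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        n_ctx = 4 ** self.order
        if self.transitions.shape != (n_ctx, 4):
            raise ValueError(f"transitions must have shape ({n_ctx}, 4)")
        if self.initial.shape != (n_ctx,):
            raise ValueError(f"initial must have length {n_ctx}")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each conditional distribution must sum to 1")
        if abs(self.initial.sum() - 1.0) > 1e-12:
            raise ValueError("initial distribution must sum to 1")

    @classmethod
    def uniform(cls, order: int = 0) -> "MarkovModel":
        n_ctx = 4 ** order
        return cls(order, np.full(n_ctx, 1 / n_ctx), np.full((n_ctx, 4), 0.25))


def _unmasked_runs(seqs):
    """Yield maximal uppercase-ACGT runs as integer code arrays."""
    for s in seqs:
        res = getattr(s, "residues", s)
        run: list[int] = []
        for ch in res:
            i = BASE_INDEX.get(ch)
            if i is None:
                if run:
                    yield np.array(run)
                    run = []
            else:
                run.append(i)
        if run:
            yield np.array(run)


def train_markov(seqs, order: int) -> MarkovModel:
    """Maximum-likelihood transitions with +1 smoothing on every cell.

    Masked positions break the chain: only transitions entirely inside
    unmasked runs are counted.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    n_ctx = 4 ** order
    counts = np.ones((n_ctx, 4))  # +1 smoothing
    init = np.ones(n_ctx)
    pows = 4 ** np.arange(order - 1, -1, -1) if order else np.empty(0, dtype=int)
    for codes in _unmasked_runs(seqs):
        if len(codes) <= order:
            continue
        if order == 0:
            np.add.at(counts[0], codes, 1)
            init[0] += len(codes)
        else:
            ctx = np.convolve(codes, pows[::-1], mode="valid")[: len(codes) - order + 1]
            # ctx[i] encodes codes[i:i+order]; transition to codes[i+order]
            np.add.at(counts, (ctx[:-1], codes[order:]), 1)
            np.add.at(init, ctx, 1)
    return MarkovModel(order, init / init.sum(), counts / counts.sum(axis=1, keepdims=True))


def sample_markov(model: MarkovModel, length: int, seed=None) -> MaskedSequence:
    """Seeded sequence of the given length from the model."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    k = model.order
    if k == 0:
        codes = rng.choice(4, size=length, p=model.transitions[0])
    else:
        codes = np.empty(length, dtype=np.int64)
        ctx = int(rng.choice(len(model.initial), p=model.initial))
        # spell the initial k-mer out of its base-4 encoding
        first = [(ctx // 4 ** (k - 1 - j)) % 4 for j in range(min(k, length))]
        codes[: len(first)] = first
        mod = 4 ** (k - 1)
        cum = model.transitions.cumsum(axis=1)
        u = rng.random(length)
        for i in range(len(first), length):
            b = int(np.searchsorted(cum[ctx], u[i], side="right"))
            b = min(b, 3)
            codes[i] = b
            ctx = (ctx % mod) * 4 + b
    return MaskedSequence("markov", "".join(DNA[c] for c in codes))


def consensus_pwm(consensus: str, concentration: float = 97.0,
                  motif_id: str | None = None, pseudocount: float = 0.25) -> CountMatrix:
    """Count matrix with `concentration` for the consensus letter, 1 elsewhere."""
    if concentration < 1:
        raise ValueError("concentration must be >= 1")
    bad = set(consensus) - set(DNA)
    if bad:
        raise ValueError(f"consensus must be over ACGT, got {sorted(bad)}")
    counts = np.ones((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, BASE_INDEX[b]] = concentration
    return CountMatrix(motif_id or f"consensus_{consensus}", counts, pseudocount)


def default_matrices(concentration: float = 97.0) -> dict[str, CountMatrix]:
    """Stand-in matrices for the three anchor classes and the Meis partner."""
    mats = {
        mid: consensus_pwm(core, concentration, motif_id=mid)
        for mid, core in HOX_PBX_CORES.items()
    }
    mats["meis"] = consensus_pwm(MEIS_CORE, concentration, motif_id="meis")
    return mats


@dataclass(frozen=True)
class PlantedSite:
    seq_id: str
    start: int
    end: int
    motif_id: str
    strand: str
    word: str  # forward-strand residues written into the sequence


@dataclass
class PlantingSpec:
    """How to plant anchor+partner clusters into the endoderm set."""

    hox_matrix: CountMatrix
    meis_matrix: CountMatrix
    clusters_per_promoter: float = 1.0
    fixed_count: bool = True  # False -> Poisson(clusters_per_promoter)
    spacing_max: int = 40  # edge-to-edge gap drawn uniform on [0, spacing_max]
    site_sampling: str = "consensus"  # or "pwm"
    repeat_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.clusters_per_promoter < 0:
            raise ValueError("clusters_per_promoter must be >= 0")
        if self.spacing_max < 0:
            raise ValueError("spacing_max must be >= 0")
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0, 1)")
        if self.site_sampling not in ("consensus", "pwm"):
            raise ValueError("site_sampling must be 'consensus' or 'pwm'")


@dataclass
class SimulationResult:
    endoderm: PromoterSet
    ectoderm: PromoterSet
    pool: PromoterSet
    ground_truth: list[PlantedSite] = field(default_factory=list)

    def __iter__(self):
        return iter((self.endoderm, self.ectoderm, self.pool, self.ground_truth))


def _sample_word(cm: CountMatrix, mode: str, rng) -> str:
    if mode == "consensus":
        return "".join(DNA[i] for i in cm.counts.argmax(axis=1))
    freq = cm.counts / cm.counts.sum(axis=1, keepdims=True)
    return "".join(DNA[rng.choice(4, p=freq[i])] for i in range(cm.width))


def _plant_clusters(residues: str, seq_id: str, spec: PlantingSpec, rng) -> tuple[str, list[PlantedSite]]:
    n = (
        int(round(spec.clusters_per_promoter))
        if spec.fixed_count
        else int(rng.poisson(spec.clusters_per_promoter))
    )
    chars = list(residues)
    occupied: list[tuple[int, int]] = []
    sites: list[PlantedSite] = []
    wa, wm = spec.hox_matrix.width, spec.meis_matrix.width
    for _ in range(n):
        for attempt in itertools.count():
            if attempt >= 1000:
                raise RuntimeError(
                    f"{seq_id}: could not place planted cluster without overlap "
                    "after 1000 attempts"
                )
            gap = int(rng.integers(0, spec.spacing_max + 1))
            meis_first = bool(rng.integers(2))
            w1, w2 = (wm, wa) if meis_first else (wa, wm)
            span = w1 + gap + w2
            if span > len(chars):
                raise RuntimeError(f"{seq_id}: promoter too short for a planted cluster")
            start = int(rng.integers(0, len(chars) - span + 1))
            iv = [(start, start + w1), (start + w1 + gap, start + span)]
            if any(s < oe and os_ < e for s, e in iv for os_, oe in occupied):
                continue
            break
        words, mids, mats = [], [], []
        for cm in ((spec.meis_matrix, spec.hox_matrix) if meis_first
                   else (spec.hox_matrix, spec.meis_matrix)):
            mats.append(cm)
            mids.append(cm.motif_id)
            words.append(_sample_word(cm, spec.site_sampling, rng))
        for (s, e), word, mid in zip(iv, words, mids):
            strand = "+" if rng.integers(2) else "-"
            placed = word if strand == "+" else reverse_complement(word)
            chars[s:e] = placed
            occupied.append((s, e))
            sites.append(PlantedSite(seq_id, s, e, mid, strand, placed))
    return "".join(chars), sites


def _add_repeats(residues: str, fraction: float, rng, mean_len: float = 150.0,
                 protected: list[tuple[int, int]] | None = None) -> str:
    """Lowercase geometric-length tracts until `fraction` of positions masked.

    Tracts never overwrite protected (planted) intervals; the final tract is
    clipped so the achieved fraction matches the target closely.
    """
    if fraction <= 0:
        return residues
    L = len(residues)
    target = int(round(fraction * L))
    chars = list(residues)
    masked = [False] * L
    protected = protected or []
    is_protected = [False] * L
    for s, e in protected:
        for i in range(s, e):
            is_protected[i] = True
    n_masked, guard = 0, 0
    while n_masked < target and guard < 10_000:
        guard += 1
        tract = min(1 + int(rng.geometric(1.0 / mean_len)), target - n_masked)
        start = int(rng.integers(0, L))
        for i in range(start, min(start + tract, L)):
            if n_masked >= target:
                break
            if not masked[i] and not is_protected[i]:
                chars[i] = chars[i].lower()
                masked[i] = True
                n_masked += 1
    return "".join(chars)


def make_promoter_sets(
    n_per_set: int = 38,
    length: int = 1000,
    background: MarkovModel | None = None,
    planting: PlantingSpec | None = None,
    seed=0,
    pool_size: int = 100,
) -> SimulationResult:
    """Two labeled promoter sets plus a pool for random-set draws.

    Endoderm promoters carry planted anchor+partner clusters (when a
    PlantingSpec is given); ectoderm and pool promoters are background-only.
    Repeat tracts are applied to every set at the spec's repeat_fraction,
    never overwriting planted sites.
    """
    if background is None:
        background = MarkovModel.uniform(0)
    ss = np.random.SeedSequence(seed)
    s_endo, s_ecto, s_pool, s_plant, s_rep = ss.spawn(5)
    rng_plant = np.random.default_rng(s_plant)
    rng_rep = np.random.default_rng(s_rep)
    repeat_fraction = planting.repeat_fraction if planting else 0.0

    def gen_set(set_id, n, stream, tissue, plant: bool):
        seqs, truth = [], []
        children = stream.spawn(n)
        for i in range(n):
            seq_id = f"{set_id}_{i:03d}"
            res = sample_markov(background, length, seed=children[i]).residues
            protected: list[tuple[int, int]] = []
            if plant and planting is not None:
                res, sites = _plant_clusters(res, seq_id, planting, rng_plant)
                truth.extend(sites)
                protected = [(st.start, st.end) for st in sites]
            if repeat_fraction > 0:
                res = _add_repeats(res, repeat_fraction, rng_rep, protected=protected)
            seqs.append(MaskedSequence(seq_id, res))
        return PromoterSet(set_id, seqs, upstream_len=length, tissue_label=tissue), truth

    endo, truth = gen_set("endoderm", n_per_set, s_endo, "endoderm",
                          planting is not None)
    ecto, _ = gen_set("ectoderm", n_per_set, s_ecto, "ectoderm", False)
    pool, _ = gen_set("pool", pool_size, s_pool, "none", False)
    return SimulationResult(endo, ecto, pool, truth)


def default_background(seed: int = 20140423, genome_length: int = 100_000,
                       order: int = 2) -> MarkovModel:
    """Order-k model trained on a bundled seed-fixed synthetic 100-kb genome."""
    genome = sample_markov(MarkovModel.uniform(0), genome_length, seed=seed)
    return train_markov([genome], order)
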