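"""Synthetic genotype data: drifted source populations and admixed hybrids.

The generator is a statistical stand-in for a three-continent reference
panel (European / East Asian / African style differentiation).  Population
allele frequencies follow the Balding–Nichols model: for ancestral
frequency ``p`` and drift parameter ``F`` in (0, 1), each population's
frequency is Beta-distributed with mean ``p`` and variance ``F p (1-p)``.
Unadmixed individuals are binomial draws under Hardy–Weinberg; hybrid
"AA-genomes" are built by copying each locus's genotype from a donor of one
of the source populations, with loci partitioned among sources in fixed
expected proportions (equal thirds by default, so the expected ancestry of
every hybrid is 1/3 per continental group).

Loci are independent: no linkage disequilibrium, recombination tracts or
mutation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ancestry_model import AlleleFrequencies
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "simulate_frequencies",
    "simulate_genotypes",
    "make_aa_genomes",
    "inject_missing",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study setting.

    Defaults emulate three strongly differentiated continental source
    populations with 50 individuals each — divergence (the Balding–Nichols
    drift parameter) 0.15 per population, continental scale; set it near
    0.01 to emulate closely related groups instead.
    """

    L: int = 5000
    K: int = 3
    n_per_pop: int = 50
    divergence: float | tuple[float, ...] = 0.15
    maf_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    seed: int = 0
    pop_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.n_per_pop < 1:
            raise ValueError("n_per_pop must be >= 1")
        div = self.divergence_per_pop()
        if div.shape != (self.K,):
            raise ValueError("divergence must be scalar or length K")
        if np.any(div <= 0) or np.any(div >= 1):
            raise ValueError("divergence must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must lie within (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not self.pop_names:
            self.pop_names = [f"POP{k + 1}" for k in range(self.K)]
        elif len(self.pop_names) != self.K:
            raise ValueError("pop_names length must equal K")

    def divergence_per_pop(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.divergence, dtype=float),
                               (self.K,)).copy()


def simulate_frequencies(cfg: SimulationConfig) -> AlleleFrequencies:
    """Draw per-population allele frequencies under Balding–Nichols drift.

    Ancestral frequencies are uniform on ``cfg.maf_range``; population *k*'s
    frequency at each locus is ``Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k)``.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    p = rng.uniform(lo, hi, size=cfg.L)
    F = np.empty((cfg.K, cfg.L))
    for k, fk in enumerate(cfg.divergence_per_pop()):
        a = p * (1 - fk) / fk
        b = (1 - p) * (1 - fk) / fk
        F[k] = rng.beta(a, b)
    loci = [f"rs{j + 1}" for j in range(cfg.L)]
    return AlleleFrequencies(list(cfg.pop_names), loci, np.clip(F, 0.0, 1.0))


def simulate_genotypes(
    freqs: AlleleFrequencies, n_per_pop: int, seed: int = 0
) -> GenotypeMatrix:
    """Unadmixed individuals: ``g_il ~ Binomial(2, p_kl)`` per population."""
    rng = np.random.default_rng(seed)
    K, L = freqs.F.shape
    blocks, samples, labels = [], [], []
    for k, pop in enumerate(freqs.pops):
        blocks.append(rng.binomial(2, freqs.F[k], size=(n_per_pop, L)))
        samples.extend(f"{pop}_{i + 1:03d}" for i in range(n_per_pop))
        labels.extend([pop] * n_per_pop)
    return GenotypeMatrix(
        samples=samples, loci=list(freqs.loci),
        G=np.vstack(blocks).astype(np.int16), pop_labels=labels,
    )


def _largest_remainder(L: int, proportions: np.ndarray) -> np.ndarray:
    """Integer locus-set sizes matching proportions; ties to lower index."""
    exact = L * proportions
    base = np.floor(exact).astype(int)
    short = L - base.sum()
    # stable sort on descending remainder => ties broken by population index
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def make_aa_genomes(
    sources: GenotypeMatrix,
    n_hybrids: int,
    proportions: np.ndarray | list[float] | None = None,
    seed: int = 0,
    label: str = "ADMIX",
) -> GenotypeMatrix:
    """Build artificial admixed genomes by per-locus donor copying.

    For each hybrid, the loci are partitioned at random into one set per
    source population, with set sizes matching ``proportions``
    (largest-remainder rounding; equal shares by default).  The genotype at
    each locus in set *k* is copied from a single donor drawn uniformly
    from population *k* (one donor per population per hybrid).  The
    expected ancestry of every hybrid therefore equals ``proportions``.
    """
    if sources.pop_labels is None:
        raise ValueError("sources must carry population labels")
    pops = list(dict.fromkeys(sources.pop_labels))
    K = len(pops)
    if proportions is None:
        proportions = np.full(K, 1.0 / K)
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape != (K,):
        raise ValueError(f"proportions must have length {K}")
    if abs(proportions.sum() - 1.0) > 1e-8 or np.any(proportions < 0):
        raise ValueError("proportions must be nonnegative and sum to 1")
    labels = np.asarray(sources.pop_labels)
    pop_rows = [np.flatnonzero(labels == pop) for pop in pops]
    if any(r.size == 0 for r in pop_rows):
        raise ValueError("every population needs at least one individual")

    rng = np.random.default_rng(seed)
    L = sources.n_loci
    sizes = _largest_remainder(L, proportions)
    G = np.empty((n_hybrids, L), dtype=np.int16)
    for h in range(n_hybrids):
        perm = rng.permutation(L)
        start = 0
        for k in range(K):
            idx = perm[start:start + sizes[k]]
            start += sizes[k]
            donor = int(rng.choice(pop_rows[k]))
            G[h, idx] = sources.G[donor, idx]
    return GenotypeMatrix(
        samples=[f"AA_{h + 1:03d}" for h in range(n_hybrids)],
        loci=list(sources.loci), G=G, pop_labels=[label] * n_hybrids,
    )


def inject_missing(gm: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each entry to MISSING independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return gm
    rng = np.random.default_rng(seed)
    mask = rng.random(gm.G.shape) < rate
    G = gm.G.copy()
    G[mask] = MISSING
    return GenotypeMatrix(
        samples=list(gm.samples), loci=list(gm.loci), G=G,
        pop_labels=None if gm.pop_labels is None else list(gm.pop_labels),
    )


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[AlleleFrequencies, GenotypeMatrix]:
    """Frequencies plus unadmixed individuals in one call.

    Genotype and missingness seeds are derived from ``cfg.seed`` so the
    whole dataset is reproducible from the config alone.
    """
    freqs = simulate_frequencies(cfg)
    gm = simulate_genotypes(freqs, cfg.n_per_pop, seed=cfg.seed + 1)
    if cfg.missing_rate > 0:
        gm = inject_missing(gm, cfg.missing_rate, seed=cfg.seed + 2)
    return freqs, gm
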