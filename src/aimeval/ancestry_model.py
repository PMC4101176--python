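"""Individual ancestry estimation under the admixture likelihood.

The model: individual *i* draws each allele at locus *l* from ancestral
population *k* with probability ``q_ik`` and that allele is the reference
allele with probability ``f_kl``.  Assuming Hardy–Weinberg equilibrium
within ancestral populations and independent loci, the log-likelihood of a
genotype row is

    l_i(q) = sum_l [ g_il * ln(sum_k q_ik f_kl)
                     + (2 - g_il) * ln(sum_k q_ik (1 - f_kl)) ]

Supervised mode fixes ``F`` from labelled reference panels and maximises
over each row of ``Q`` independently; unsupervised mode maximises jointly
over ``Q`` and ``F``.  Both use EM updates, which keep every row of ``Q``
on the probability simplex and never decrease the log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "AncestryProportions",
    "FitResult",
    "estimate_frequencies",
    "supervised_ancestry",
    "unsupervised_admixture",
    "cross_validation_error",
    "choose_k",
    "align_clusters",
]

#: Frequencies are clamped into [EPS, 1-EPS] so the log-likelihood stays finite
#: at loci fixed in a reference population.
EPS: float = 1e-6

#: Lower clamp on ancestry components inside the accelerated solver; a
#: component this small is indistinguishable from zero in the likelihood,
#: and bounding its log keeps the extrapolation step length finite.
_QFLOOR: float = 1e-12


@dataclass
class AlleleFrequencies:
    """K populations x L loci reference-allele frequencies (the model's F)."""

    pops: list[str]
    loci: list[str]
    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (len(self.pops), len(self.loci)):
            raise ValueError(
                f"F shape {self.F.shape} inconsistent with "
                f"{len(self.pops)} pops x {len(self.loci)} loci"
            )
        if np.any(self.F < 0) or np.any(self.F > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_pops(self) -> int:
        return len(self.pops)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, loci: list[str]) -> "AlleleFrequencies":
        """Columns restricted to ``loci``, in that order."""
        pos = {l: j for j, l in enumerate(self.loci)}
        missing = [l for l in loci if l not in pos]
        if missing:
            raise KeyError(f"loci absent from frequency table: {missing[:5]}")
        idx = [pos[l] for l in loci]
        return AlleleFrequencies(list(self.pops), list(loci), self.F[:, idx])


@dataclass
class AncestryProportions:
    """N individuals x K ancestries membership matrix Q; rows on the simplex."""

    samples: list[str]
    ancestries: list[str]
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (len(self.samples), len(self.ancestries)):
            raise ValueError("Q shape inconsistent with labels")
        if np.any(self.Q < -1e-12):
            raise ValueError("ancestry proportions must be nonnegative")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each Q row must sum to 1 within 1e-8")


@dataclass
class FitResult:
    Q: AncestryProportions
    loglik: float
    n_iter: int
    converged: bool
    F: AlleleFrequencies | None = None
    loglik_trace: list[float] = field(default_factory=list)


def estimate_frequencies(gm: GenotypeMatrix) -> AlleleFrequencies:
    """Reference-allele frequencies per labelled population.

    ``f_kl = allele count / (2 * called samples)``, clamped into
    ``[EPS, 1-EPS]``.  A locus with no calls in some population gets 0.5
    there, with a warning.
    """
    if gm.pop_labels is None:
        raise ValueError("genotype matrix has no population labels")
    pops = list(dict.fromkeys(gm.pop_labels))
    labels = np.asarray(gm.pop_labels)
    F = np.empty((len(pops), gm.n_loci))
    called = gm.G != MISSING
    Gn = np.where(called, gm.G, 0).astype(float)
    n_uncallable = 0
    for k, pop in enumerate(pops):
        rows = labels == pop
        counts = Gn[rows].sum(axis=0)
        denom = 2.0 * called[rows].sum(axis=0)
        empty = denom == 0
        n_uncallable += int(empty.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(empty, 0.5, counts / np.maximum(denom, 1.0))
        F[k] = f
    if n_uncallable:
        warnings.warn(
            f"{n_uncallable} population/locus cells had no called genotypes; "
            "frequency set to 0.5", UserWarning,
        )
    return AlleleFrequencies(pops, list(gm.loci), np.clip(F, EPS, 1 - EPS))


def _prepare(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split genotypes into ref-allele and alt-allele dose with missing zeroed."""
    called = gm.G != MISSING
    Gr = np.where(called, gm.G, 0).astype(float)
    Ga = np.where(called, 2 - gm.G, 0).astype(float)
    return Gr, Ga, called


def _loglik(Gr: np.ndarray, Ga: np.ndarray, P: np.ndarray) -> float:
    return float(np.sum(Gr * np.log(P) + Ga * np.log1p(-P)))


def supervised_ancestry(
    gm: GenotypeMatrix,
    freqs: AlleleFrequencies,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> FitResult:
    """Maximum-likelihood Q with ancestral frequencies fixed.

    Per-individual EM on the simplex, accelerated with per-row SQUAREM
    extrapolation: each recorded iteration runs two EM steps, extrapolates
    along the step direction, and keeps the plain double-EM result for any
    row the extrapolation fails to improve — so the recorded log-likelihood
    trace is still non-decreasing.  ``tol`` is an absolute log-likelihood
    tolerance per individual: iteration stops when the total log-likelihood
    changes by less than ``tol * n_samples``.  Missing loci are skipped (each
    individual is scored on its called loci only); individuals with zero
    called loci receive uniform membership, with a warning.
    """
    F = freqs.subset(gm.loci).F if freqs.loci != gm.loci else freqs.F
    F = np.clip(F, EPS, 1 - EPS)
    K = F.shape[0]
    N = gm.n_samples
    Gr, Ga, called = _prepare(gm)
    L_i = called.sum(axis=1).astype(float)
    no_calls = L_i == 0
    if no_calls.any():
        warnings.warn(
            f"{int(no_calls.sum())} individual(s) with zero called loci; "
            "assigned uniform ancestry", UserWarning,
        )
    denom_full = np.where(no_calls, 1.0, 2.0 * L_i)[:, None]
    Ft = np.ascontiguousarray(F.T)

    def fused(Q, Gr, Ga, denom):
        """One EM step plus the log-likelihood at the input point."""
        P = np.clip(Q @ F, 1e-15, 1 - 1e-15)
        ll = np.sum(Gr * np.log(P) + Ga * np.log1p(-P), axis=1)
        B = Ga / (1 - P)
        R = (Gr / P - B) @ Ft + B.sum(axis=1)[:, None]
        Qn = Q * R / denom
        s = Qn.sum(axis=1, keepdims=True)
        zero = s[:, 0] <= 0  # rows with no called loci have a zero update
        if zero.any():
            Qn[zero] = 1.0 / K
            s[zero] = 1.0
        return ll, Qn / s

    Q_full = np.full((N, K), 1.0 / K)
    ll_full = np.zeros(N)
    active = np.arange(N)
    Q = Q_full.copy()
    ll_prev_rows = np.full(N, -np.inf)
    # adaptive per-row step-length cap (standard SQUAREM safeguard):
    # doubled when a capped extrapolation succeeds, shrunk when one fails
    caps_full = np.full(N, 16.0)
    trace: list[float] = []
    frozen_sum = 0.0
    it = 0
    while it < max_iter and active.size:
        it += 1
        Gr_a, Ga_a, denom_a = Gr[active], Ga[active], denom_full[active]
        ll0, Q1 = fused(Q, Gr_a, Ga_a, denom_a)
        Q_full[active] = Q
        ll_full[active] = ll0
        trace.append(frozen_sum + float(ll0.sum()))
        # freeze individually converged rows (tol: absolute log-likelihood
        # change per individual — relative change on genome-scale
        # magnitudes is vacuous)
        delta = ll0 - ll_prev_rows[active]
        done = delta <= max(tol, 1e-9 * float(np.abs(ll0).max() or 1.0))
        if done.any():
            frozen_sum += float(ll0[done].sum())
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            Q, ll0, Q1 = Q[keep], ll0[keep], Q1[keep]
            Gr_a, Ga_a, denom_a = Gr[active], Ga[active], denom_full[active]
        ll_prev_rows[active] = ll0
        ll1, Q2 = fused(Q1, Gr_a, Ga_a, denom_a)
        # SQUAREM-style extrapolation in log space: the EM map is
        # multiplicative, so a geometric approach to the simplex boundary
        # is linear there, positivity is automatic, and no component is
        # absorbed at zero when the row optimum is interior
        W0 = np.log(np.maximum(Q, _QFLOOR))
        r = np.log(np.maximum(Q1, _QFLOOR)) - W0
        v = np.log(np.maximum(Q2, _QFLOOR)) - W0 - 2 * r
        alpha = -np.sqrt(
            np.einsum("ij,ij->i", r, r)
            / np.maximum(np.einsum("ij,ij->i", v, v), 1e-300)
        )
        caps = caps_full[active]
        hit = alpha <= -caps
        alpha = np.clip(alpha, -caps, -1.0)[:, None]  # at least one EM step
        Wacc = W0 - 2 * alpha * r + alpha**2 * v
        Wacc -= Wacc.max(axis=1, keepdims=True)
        Qacc = np.maximum(np.exp(Wacc), _QFLOOR)
        Qacc /= Qacc.sum(axis=1, keepdims=True)
        ll_acc, Qacc1 = fused(Qacc, Gr_a, Ga_a, denom_a)
        # monotonicity safeguard: keep the plain double-EM iterate for rows
        # the extrapolation failed to improve (ll_acc < ll1 <= ll(Q2))
        ok = ll_acc >= ll1
        Q = np.where(ok[:, None], Qacc1, Q2)
        caps_full[active[ok & hit]] *= 2.0
        caps_full[active[~ok]] = np.maximum(caps_full[active[~ok]] / 2.0, 2.0)
    converged = active.size == 0
    Q_full[no_calls] = 1.0 / K
    qres = AncestryProportions(list(gm.samples), list(freqs.pops), Q_full)
    return FitResult(Q=qres, loglik=trace[-1], n_iter=it,
                     converged=converged, loglik_trace=trace)


def unsupervised_admixture(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_starts: int = 1,
) -> FitResult:
    """Joint EM over Q and F from a seeded random start.

    Initialisation: Q rows ~ Dirichlet(1, ..., 1), F ~ Uniform(0.05, 0.95).
    With ``n_starts > 1`` the best local maximum over restarts is returned.
    Cluster labels are arbitrary (``C1..CK``); resolve label switching with
    :func:`align_clusters` before comparing to truth.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_samples:
        raise ValueError(f"K={K} exceeds the number of individuals")
    if gm.n_samples == 0 or gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    rng = np.random.default_rng(seed)
    Gr, Ga, called = _prepare(gm)
    L_i = called.sum(axis=1).astype(float)
    no_calls = L_i == 0
    denom = np.where(no_calls, 1.0, 2.0 * L_i)[:, None]

    best: FitResult | None = None
    for _ in range(max(1, n_starts)):
        Q = rng.dirichlet(np.ones(K), size=gm.n_samples)
        F = rng.uniform(0.05, 0.95, size=(K, gm.n_loci))
        trace: list[float] = []
        converged = False
        ll = -np.inf
        it = 0
        for it in range(1, max_iter + 1):
            P = np.clip(Q @ F, 1e-15, 1 - 1e-15)
            ll_new = _loglik(Gr, Ga, P)
            trace.append(ll_new)
            if np.isfinite(ll) and abs(ll_new - ll) <= tol * abs(ll):
                converged = True
                break
            ll = ll_new
            B = Ga / (1 - P)
            AmB = Gr / P - B
            # F update: expected ref-allele draws over total draws per (k, l)
            QtB = Q.T @ B
            numF = F * (Q.T @ AmB + QtB)
            denF = numF + (1 - F) * QtB
            F_new = np.where(denF > 0, numF / np.maximum(denF, 1e-300), 0.5)
            Q = Q * (AmB @ F.T + B.sum(axis=1)[:, None]) / denom
            Q[no_calls] = 1.0 / K
            Q /= Q.sum(axis=1, keepdims=True)
            F = np.clip(F_new, EPS, 1 - EPS)
        names = [f"C{k + 1}" for k in range(K)]
        fit = FitResult(
            Q=AncestryProportions(list(gm.samples), names, Q),
            F=AlleleFrequencies(names, list(gm.loci), F),
            loglik=trace[-1],
            n_iter=it,
            converged=converged,
            loglik_trace=trace,
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def cross_validation_error(
    gm: GenotypeMatrix,
    K: int,
    n_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 600,
) -> float:
    """Entry-wise cross-validated genotype prediction error for a given K.

    Non-missing entries are partitioned into ``n_folds`` masks; each fold is
    hidden, the unsupervised model refit, and the hidden genotypes predicted
    as ``2 * sum_k q_ik f_kl``.  Returns the mean squared prediction error
    averaged over folds — the quantity minimised when choosing K.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    obs = np.argwhere(gm.G != MISSING)
    order = rng.permutation(len(obs))
    folds = np.array_split(obs[order], n_folds)
    errors = []
    for f, fold in enumerate(folds):
        G_masked = gm.G.copy()
        G_masked[fold[:, 0], fold[:, 1]] = MISSING
        masked_gm = GenotypeMatrix(
            samples=list(gm.samples), loci=list(gm.loci),
            G=G_masked, pop_labels=gm.pop_labels,
        )
        fit = unsupervised_admixture(
            masked_gm, K, seed=int(rng.integers(2**31)),
            tol=tol, max_iter=max_iter,
        )
        pred = 2.0 * (fit.Q.Q @ fit.F.F)
        truth = gm.G[fold[:, 0], fold[:, 1]].astype(float)
        errors.append(float(np.mean((truth - pred[fold[:, 0], fold[:, 1]]) ** 2)))
    return float(np.mean(errors))


def choose_k(
    gm: GenotypeMatrix,
    k_values: list[int],
    n_folds: int = 5,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 600,
) -> int:
    """K with the lowest cross-validation error; ties go to the smaller K.

    Fold assignment is shared across candidate K values so the comparison
    is paired.
    """
    if not k_values:
        raise ValueError("k_values must be non-empty")
    best_k, best_err = None, np.inf
    for k in sorted(k_values):
        err = cross_validation_error(gm, k, n_folds=n_folds, seed=seed,
                                     tol=tol, max_iter=max_iter)
        if err < best_err:
            best_k, best_err = k, err
    return best_k


def align_clusters(Q: AncestryProportions, pop_labels: list[str]) -> np.ndarray:
    """Resolve label switching: match clusters to populations.

    Returns ``perm`` such that ``perm[p]`` is the cluster index assigned to
    the *p*-th population (populations in order of first appearance in
    ``pop_labels``), maximising the total mean own-cluster membership —
    an optimal assignment on the K x K mean-membership matrix.
    ``Q.Q[:, perm]`` then puts population *p*'s cluster in column *p*.
    """
    pops = list(dict.fromkeys(pop_labels))
    K = len(Q.ancestries)
    if len(pops) != K:
        raise ValueError(f"{len(pops)} distinct labels but K={K} clusters")
    labels = np.asarray(pop_labels)
    M = np.vstack([Q.Q[labels == pop].mean(axis=0) for pop in pops])
    rows, cols = linear_sum_assignment(-M)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm
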