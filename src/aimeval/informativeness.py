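"""Marker informativeness: pairwise F_ST, locus-specific branch length (LSBL),
panel summaries and LSBL-balanced AIM selection.

F_ST uses the Weir & Cockerham (1984) two-population theta, which accounts
for finite sample sizes and observed heterozygosity.  LSBL decomposes the
three pairwise distances among populations (a, b, c) into per-population
branch lengths:

    branch_a = (d_ab + d_ac - d_bc) / 2      (cyclically for b and c)

so a locus's branch for population *a* measures allele-frequency change
specific to *a*.  Negative branches (possible with noisy distance
estimates) are clamped to zero, with a flag, since tree branch lengths are
nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PanelDefinition

__all__ = [
    "FstResult",
    "LSBLBranches",
    "LSBLTable",
    "PanelLSBLSummary",
    "pairwise_fst",
    "lsbl",
    "lsbl_table",
    "panel_lsbl_summary",
    "select_aims_lsbl",
]


class FstResult(NamedTuple):
    """Per-locus Weir–Cockerham theta plus the overall multi-locus estimate."""

    loci: list[str]
    per_locus: np.ndarray  # NaN where not estimable
    overall: float


def pairwise_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> FstResult:
    """Weir–Cockerham (1984) theta between two labelled populations.

    Per-locus values are the ratio ``a / (a + b + c)`` of the WC variance
    components; the overall value is the standard multi-locus ratio of
    summed components.  Loci with fewer than two called samples in either
    population are excluded (NaN per locus, left out of the sums); per-locus
    estimates may be negative and are reported as computed — clamping
    happens at the LSBL stage.
    """
    if gm.pop_labels is None:
        raise ValueError("genotype matrix has no population labels")
    labels = np.asarray(gm.pop_labels)
    rows = []
    for pop in (pop_a, pop_b):
        r = np.flatnonzero(labels == pop)
        if r.size == 0:
            raise ValueError(f"population {pop!r} not present")
        rows.append(r)

    # per-population called counts, allele frequencies, het frequencies
    n = np.empty((2, gm.n_loci))
    p = np.empty((2, gm.n_loci))
    h = np.empty((2, gm.n_loci))
    for i, r in enumerate(rows):
        sub = gm.G[r]
        called = sub != MISSING
        n[i] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(called, sub, 0).sum(axis=0) / (2 * n[i])
            h[i] = (sub == 1).sum(axis=0) / n[i]

    ok = (n >= 2).all(axis=0)
    r_pops = 2.0
    nbar = n.mean(axis=0)
    nsum = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r_pops - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r_pops - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r_pops - 1) / r_pops * s2 - hbar / 4)
            / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r_pops - 1) / r_pops * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(ok & (denom != 0), a / np.where(denom == 0, 1, denom),
                         np.nan)
    overall_num = np.nansum(np.where(ok, a, 0.0))
    overall_den = np.nansum(np.where(ok, denom, 0.0))
    overall = float(overall_num / overall_den) if overall_den != 0 else float("nan")
    return FstResult(list(gm.loci), theta, overall)


class LSBLBranches(NamedTuple):
    branch_a: np.ndarray | float
    branch_b: np.ndarray | float
    branch_c: np.ndarray | float
    clamped: np.ndarray | bool


def lsbl(d_ab, d_ac, d_bc, clamp: bool = True) -> LSBLBranches:
    """Decompose three pairwise distances into per-population branch lengths.

    Accepts scalars or arrays.  With ``clamp`` (default), negative branches
    are set to 0 and flagged; additivity ``branch_a + branch_b == d_ab``
    holds exactly pre-clamping.
    """
    d_ab = np.asarray(d_ab, dtype=float)
    d_ac = np.asarray(d_ac, dtype=float)
    d_bc = np.asarray(d_bc, dtype=float)
    a = (d_ab + d_ac - d_bc) / 2
    b = (d_ab + d_bc - d_ac) / 2
    c = (d_ac + d_bc - d_ab) / 2
    clamped = (a < 0) | (b < 0) | (c < 0)
    if clamp:
        a, b, c = (np.maximum(x, 0.0) for x in (a, b, c))
    if a.ndim == 0:
        return LSBLBranches(float(a), float(b), float(c), bool(clamped))
    return LSBLBranches(a, b, c, clamped)


@dataclass
class LSBLTable:
    """Per-locus, per-branch LSBL values for three populations."""

    loci: list[str]
    branches: list[str]
    values: np.ndarray  # L x 3, clamped nonnegative
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.loci), len(self.branches)):
            raise ValueError("values shape inconsistent with labels")
        if np.any(self.values < 0):
            raise ValueError("LSBL values must be nonnegative after clamping")


def lsbl_table(gm: GenotypeMatrix, pops: tuple[str, str, str]) -> LSBLTable:
    """Per-locus LSBL for three populations from pairwise WC F_ST."""
    pa, pb, pc = pops
    d_ab = pairwise_fst(gm, pa, pb).per_locus
    d_ac = pairwise_fst(gm, pa, pc).per_locus
    d_bc = pairwise_fst(gm, pb, pc).per_locus
    res = lsbl(d_ab, d_ac, d_bc)
    values = np.column_stack([res.branch_a, res.branch_b, res.branch_c])
    usable = ~np.isnan(values).any(axis=1)
    return LSBLTable(
        loci=[l for l, u in zip(gm.loci, usable) if u],
        branches=[pa, pb, pc],
        values=values[usable],
        n_clamped=int(np.asarray(res.clamped)[usable].sum()),
    )


@dataclass
class PanelLSBLSummary:
    """Accumulated and average LSBL per branch for one panel.

    "Average LSBL" is the accumulated LSBL standardised by the number of
    AIMs actually scored (the effective panel size, when some panel loci
    are absent from the table).
    """

    panel: str
    branches: list[str]
    accumulated: np.ndarray
    average: np.ndarray
    size: int
    missing_loci: list[str]


def panel_lsbl_summary(table: LSBLTable, panel: PanelDefinition) -> PanelLSBLSummary:
    """Sum and standardise per-branch LSBL over a panel's loci."""
    pos = {l: j for j, l in enumerate(table.loci)}
    present = [l for l in panel.loci if l in pos]
    missing = [l for l in panel.loci if l not in pos]
    if not present:
        raise ValueError(f"panel {panel.name!r} shares no loci with the table")
    acc = table.values[[pos[l] for l in present]].sum(axis=0)
    return PanelLSBLSummary(
        panel=panel.name, branches=list(table.branches),
        accumulated=acc, average=acc / len(present),
        size=len(present), missing_loci=missing,
    )


def select_aims_lsbl(table: LSBLTable, n_aims: int,
                     name: str | None = None) -> PanelDefinition:
    """Greedy selection of AIMs with balanced cumulative LSBL per branch.

    Repeatedly find the branch with the smallest accumulated LSBL so far
    and add the unused locus with the largest LSBL on that branch.  Ties —
    both between branches and between loci — are broken toward the smaller
    index, for determinism.  The resulting per-branch totals differ
    pairwise by at most the largest selected single-locus value.
    """
    L, K = table.values.shape
    if n_aims > L:
        raise ValueError(f"n_aims={n_aims} exceeds the {L} scored loci")
    if n_aims < 1:
        raise ValueError("n_aims must be >= 1")
    acc = np.zeros(K)
    used = np.zeros(L, dtype=bool)
    chosen: list[int] = []
    vals = table.values
    for _ in range(n_aims):
        branch = int(np.argmin(acc))  # argmin: ties to the smaller index
        masked = np.where(used, -np.inf, vals[:, branch])
        j = int(np.argmax(masked))
        used[j] = True
        chosen.append(j)
        acc += vals[j]
    return PanelDefinition(
        name=name or f"lsbl_balanced_{n_aims}",
        loci=[table.loci[j] for j in chosen],
    )
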