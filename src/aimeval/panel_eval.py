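"""Panel-accuracy experiments: random-SNP resampling, pre-designed panel
evaluation, sample-size bootstrap, and error quantification.

The evaluation logic: ancestry estimated from the full marker set is the
reference ("genome ancestry"); a panel's quality is how tightly its
estimates concentrate around that reference.  Random panels of decreasing
size trace how accuracy degrades with coverage; the error of a panel is
the RMS deviation of its per-individual estimates about the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ancestry_model import (
    AlleleFrequencies,
    AncestryProportions,
    supervised_ancestry,
)
from .genotype_io import GenotypeMatrix, PanelDefinition, filter_by_call_rate, subset_by_panel

__all__ = [
    "EvalSummary",
    "ErrorReport",
    "SampleSizeSummary",
    "genome_ancestry_reference",
    "rsnp_resampling",
    "evaluate_panel",
    "panel_error",
    "sample_size_experiment",
    "size_error_correlation",
]


@dataclass
class EvalSummary:
    """One summary row: a population group x an ancestry component.

    All location/spread fields are percentages.  ``n_replicates`` counts
    resampling replicates when the summary is over replicates, or
    individuals when a single fit is summarised across individuals.
    """

    group: str
    ancestry: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    minimum: float
    maximum: float
    panel_size: int
    n_replicates: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be nonnegative")
        if not (self.minimum - 1e-9 <= self.ci_low <= self.mean + 1e-9
                <= self.ci_high + 2e-9 <= self.maximum + 2e-9):
            raise ValueError(
                "summary ordering violated: need min <= ci_low <= mean "
                "<= ci_high <= max"
            )


@dataclass
class ErrorReport:
    """Per-ancestry RMS error of a panel's estimates about the reference.

    Errors are on the proportion scale (0..1); multiply by 100 for
    percentage points.
    """

    panel: str
    size: int
    errors: dict[str, float] = field(default_factory=dict)
    admixed: bool = False

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.errors.values()):
            raise ValueError("errors must be nonnegative")


@dataclass
class SampleSizeSummary:
    """Mean-of-means and bootstrap interval for one group x subsample size."""

    group: str
    ancestry: str
    size: int
    mean: float
    ci_low: float
    ci_high: float
    n_subsamples: int


def genome_ancestry_reference(
    gm: GenotypeMatrix, freqs: AlleleFrequencies, **fit_kwargs
) -> AncestryProportions:
    """Supervised ancestry from the full marker set — the truth proxy that
    every panel estimate is compared against."""
    return supervised_ancestry(gm, freqs, **fit_kwargs).Q


def _summary(values: np.ndarray, group: str, ancestry: str,
             panel_size: int) -> EvalSummary:
    """Percent-scale summary of a vector of proportion-scale values."""
    v = np.asarray(values, dtype=float) * 100.0
    lo, hi = np.percentile(v, [2.5, 97.5])
    return EvalSummary(
        group=group, ancestry=ancestry,
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
        ci_low=float(lo), ci_high=float(hi),
        minimum=float(v.min()), maximum=float(v.max()),
        panel_size=panel_size, n_replicates=int(v.size),
    )


def _focal_components(group: str, ancestries: list[str]) -> list[str]:
    """Own ancestry for a labelled source population; all components for
    groups (e.g. admixed hybrids) without a matching ancestry label."""
    return [group] if group in ancestries else list(ancestries)


def rsnp_resampling(
    gm: GenotypeMatrix,
    freqs: AlleleFrequencies,
    panel_sizes: list[int],
    n_reps: int = 500,
    seed: int = 0,
    **fit_kwargs,
) -> list[EvalSummary]:
    """Random-SNP panels of each size, redrawn ``n_reps`` times.

    For each replicate, loci are sampled without replacement, supervised
    ancestry is estimated, and the population mean of the focal component
    is recorded; summaries (mean, SD, percentile 95% CI, range — all in
    percent) are over replicates.
    """
    if gm.pop_labels is None:
        raise ValueError("genotype matrix has no population labels")
    L = gm.n_loci
    for size in panel_sizes:
        if not 1 <= size <= L:
            raise ValueError(f"panel size {size} outside [1, {L}]")
    rng = np.random.default_rng(seed)
    labels = np.asarray(gm.pop_labels)
    groups = list(dict.fromkeys(gm.pop_labels))
    anc = list(freqs.pops)
    summaries: list[EvalSummary] = []
    for size in panel_sizes:
        # rec[(group, ancestry)] -> per-replicate population means
        rec: dict[tuple[str, str], list[float]] = {
            (g, a): [] for g in groups for a in _focal_components(g, anc)
        }
        for _ in range(n_reps):
            idx = rng.choice(L, size=size, replace=False)
            sub = gm.take_loci(sorted(idx))
            Q = supervised_ancestry(sub, freqs, **fit_kwargs).Q.Q
            for g in groups:
                rows = labels == g
                for a in _focal_components(g, anc):
                    rec[(g, a)].append(float(Q[rows, anc.index(a)].mean()))
        for (g, a), vals in rec.items():
            summaries.append(_summary(np.asarray(vals), g, a, size))
    return summaries


def evaluate_panel(
    gm: GenotypeMatrix,
    freqs: AlleleFrequencies,
    panel: PanelDefinition,
    **fit_kwargs,
) -> list[EvalSummary]:
    """One supervised fit on a panel's loci, summarised across individuals.

    The effective (intersected) panel size is recorded on every row.
    """
    if gm.pop_labels is None:
        raise ValueError("genotype matrix has no population labels")
    sub, _missing = subset_by_panel(gm, panel)
    Q = supervised_ancestry(sub, freqs, **fit_kwargs).Q.Q
    labels = np.asarray(gm.pop_labels)
    anc = list(freqs.pops)
    summaries = []
    for g in dict.fromkeys(gm.pop_labels):
        rows = labels == g
        for a in _focal_components(g, anc):
            summaries.append(
                _summary(Q[rows, anc.index(a)], g, a, sub.n_loci)
            )
    return summaries


def panel_error(
    panel_Q: AncestryProportions,
    reference_Q: AncestryProportions,
    panel: str = "panel",
    size: int = 0,
    admixed: bool = False,
) -> ErrorReport:
    """RMS deviation of panel estimates about the reference, per ancestry.

    This is the "standard deviation regarding genome ancestry": the root
    mean squared difference between panel and reference proportions,
    component by component.
    """
    if panel_Q.samples != reference_Q.samples:
        raise ValueError("panel and reference cover different samples")
    if panel_Q.ancestries != reference_Q.ancestries:
        raise ValueError("ancestry components differ (align clusters first)")
    diff = panel_Q.Q - reference_Q.Q
    rms = np.sqrt((diff**2).mean(axis=0))
    return ErrorReport(
        panel=panel, size=size,
        errors={a: float(e) for a, e in zip(panel_Q.ancestries, rms)},
        admixed=admixed,
    )


def sample_size_experiment(
    gm: GenotypeMatrix,
    freqs: AlleleFrequencies,
    panel: PanelDefinition,
    sizes: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40),
    n_subsamples: int = 1000,
    seed: int = 0,
    min_call: float = 0.9,
    **fit_kwargs,
) -> list[SampleSizeSummary]:
    """How population-mean ancestry estimates vary with sample size.

    Profiles below the call-rate threshold are removed first.  Ancestry is
    estimated once on the panel's loci; then, per population and per size,
    ``n_subsamples`` subsets of individuals are drawn without replacement,
    the subset mean of the own-ancestry component recorded, and the mean of
    means plus the percentile (2.5, 97.5) bootstrap interval reported (in
    percent).
    """
    if gm.pop_labels is None:
        raise ValueError("genotype matrix has no population labels")
    filtered = filter_by_call_rate(gm, min_call)
    sub, _ = subset_by_panel(filtered, panel)
    Q = supervised_ancestry(sub, freqs, **fit_kwargs).Q.Q
    labels = np.asarray(filtered.pop_labels)
    anc = list(freqs.pops)
    rng = np.random.default_rng(seed)
    out: list[SampleSizeSummary] = []
    for g in dict.fromkeys(filtered.pop_labels):
        rows = np.flatnonzero(labels == g)
        for a in _focal_components(g, anc):
            vals = Q[rows, anc.index(a)]
            for size in sizes:
                if size > rows.size:
                    raise ValueError(
                        f"subsample size {size} exceeds the {rows.size} "
                        f"filtered profiles of {g!r}"
                    )
                means = np.array([
                    rng.choice(vals, size=size, replace=False).mean()
                    for _ in range(n_subsamples)
                ]) * 100.0
                lo, hi = np.percentile(means, [2.5, 97.5])
                out.append(SampleSizeSummary(
                    group=g, ancestry=a, size=size,
                    mean=float(means.mean()), ci_low=float(lo),
                    ci_high=float(hi), n_subsamples=n_subsamples,
                ))
    return out


def size_error_correlation(reports: list[ErrorReport]) -> dict[str, float]:
    """Pearson correlation between panel size and estimation error.

    Returned per ancestry component plus a ``"pooled"`` entry over all
    (size, error) pairs.  Constant inputs give NaN with a warning (the
    correlation is undefined).
    """
    if len(reports) < 3 or len({r.size for r in reports}) < 3:
        raise ValueError("need >= 3 reports with distinct panel sizes")
    ancestries = list(reports[0].errors)
    out: dict[str, float] = {}
    pooled_x: list[float] = []
    pooled_y: list[float] = []
    for a in ancestries:
        x = np.array([r.size for r in reports], dtype=float)
        y = np.array([r.errors[a] for r in reports], dtype=float)
        pooled_x.extend(x)
        pooled_y.extend(y)
        out[a] = _pearson(x, y, a)
    out["pooled"] = _pearson(np.array(pooled_x), np.array(pooled_y), "pooled")
    return out


def _pearson(x: np.ndarray, y: np.ndarray, label: str) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            f"correlation undefined for {label!r} (constant input)", UserWarning
        )
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
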