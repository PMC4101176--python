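"""Genotype containers and text-format I/O.

Genotypes are stored as counts of a per-locus reference allele (0, 1 or 2),
with :data:`MISSING` (-1) marking no-calls.  Two plain-text dialects are
supported: the PLINK PED/MAP text layout and a simple TSV matrix with one
row per sample.  AIM panels are plain lists of locus identifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PanelDefinition",
    "PanelSubset",
    "read_genotypes",
    "write_genotypes",
    "read_panel",
    "write_panel",
    "filter_by_call_rate",
    "subset_by_panel",
]

#: Sentinel for a missing genotype.  Deliberately not 0 — 0 is a valid count.
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of reference-allele counts.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``G``.
    loci
        Locus identifiers, one per column of ``G``; must be unique.
    G
        ``(n_samples, n_loci)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    pop_labels
        Optional per-sample population label (same length as ``samples``).
    """

    samples: list[str]
    loci: list[str]
    G: np.ndarray
    pop_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int16)
        if self.G.ndim != 2:
            raise ValueError("G must be 2-dimensional")
        n, l = self.G.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but G has {n} rows")
        if l != len(self.loci):
            raise ValueError(f"{len(self.loci)} loci but G has {l} columns")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus identifiers must be unique")
        bad = ~np.isin(self.G, list(_VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.G[i, j]} at sample "
                f"{self.samples[i]!r}, locus {self.loci[j]!r}"
            )
        if self.pop_labels is not None and len(self.pop_labels) != n:
            raise ValueError("pop_labels length must match number of samples")

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_loci(self) -> int:
        return self.G.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing entries."""
        return self.G == MISSING

    def call_rates(self) -> np.ndarray:
        """Per-sample fraction of non-missing genotypes."""
        if self.n_loci == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask().mean(axis=1)

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=list(self.loci),
            G=self.G[idx, :],
            pop_labels=None
            if self.pop_labels is None
            else [self.pop_labels[i] for i in idx],
        )

    def take_loci(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[j] for j in idx],
            G=self.G[:, idx],
            pop_labels=None if self.pop_labels is None else list(self.pop_labels),
        )


@dataclass
class PanelDefinition:
    """An ordered AIM panel: a name and a list of locus identifiers."""

    name: str
    loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("panel must contain at least one locus")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("panel locus identifiers must be unique")

    def __len__(self) -> int:
        return len(self.loci)


class PanelSubset(NamedTuple):
    """Result of applying a panel to a genotype matrix."""

    genotypes: GenotypeMatrix
    missing_loci: list[str]


def _ped_paths(path: str | Path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".ped":
        return p, p.with_suffix(".map")
    if p.suffix == ".map":
        return p.with_suffix(".ped"), p
    return p.with_suffix(".ped"), p.with_suffix(".map")


def _read_ped_map(path: str | Path) -> GenotypeMatrix:
    ped_path, map_path = _ped_paths(path)
    loci: list[str] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 4:
                raise ValueError(
                    f"{map_path}: line {lineno}: expected 4 columns "
                    f"(chrom, id, cM, bp), got {len(tok)}"
                )
            loci.append(tok[1])
    n_loci = len(loci)

    samples: list[str] = []
    pop_labels: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 6 or (len(tok) - 6) % 2 != 0:
                raise ValueError(
                    f"{ped_path}: line {lineno}: malformed PED record "
                    f"({len(tok)} fields)"
                )
            if (len(tok) - 6) // 2 != n_loci:
                raise ValueError(
                    f"{ped_path}: line {lineno}: {(len(tok) - 6) // 2} loci "
                    f"but MAP declares {n_loci}"
                )
            pop_labels.append(tok[0])
            samples.append(tok[1])
            allele_rows.append(tok[6:])

    n = len(samples)
    G = np.full((n, n_loci), MISSING, dtype=np.int16)
    # reference allele per locus: first non-missing allele in file order
    ref = [None] * n_loci
    for i in range(n):
        row = allele_rows[i]
        for j in range(n_loci):
            a, b = row[2 * j], row[2 * j + 1]
            if a == "0" or b == "0":
                continue
            if ref[j] is None:
                ref[j] = a
            G[i, j] = (a == ref[j]) + (b == ref[j])
    return GenotypeMatrix(samples=samples, loci=loci, G=G, pop_labels=pop_labels)


def _read_tsv_matrix(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: TSV matrix needs sample, population and "
                         "at least one locus column")
    loci = list(df.columns[2:])
    body = df.iloc[:, 2:].to_numpy(dtype=float)
    G = np.where(np.isnan(body), MISSING, body).astype(np.int16)
    return GenotypeMatrix(
        samples=df.iloc[:, 0].astype(str).tolist(),
        loci=loci,
        G=G,
        pop_labels=df.iloc[:, 1].astype(str).tolist(),
    )


def read_genotypes(path: str | Path, dialect: str = "tsv_matrix") -> GenotypeMatrix:
    """Read a genotype matrix from disk.

    Parameters
    ----------
    path
        For ``ped_map``, the ``.ped`` file (the ``.map`` file is found by
        suffix substitution); for ``tsv_matrix``, the TSV file.
    dialect
        ``"ped_map"`` or ``"tsv_matrix"``.

    Notes
    -----
    In the PED dialect the reference allele of each locus is the first
    allele observed in file order; ``0 0`` (or any half-missing pair)
    becomes :data:`MISSING`.  Any consistent allele coding yields identical
    admixture likelihoods up to relabelling.
    """
    if dialect == "ped_map":
        return _read_ped_map(path)
    if dialect == "tsv_matrix":
        return _read_tsv_matrix(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(gm: GenotypeMatrix, path: str | Path,
                    dialect: str = "tsv_matrix") -> None:
    """Write a genotype matrix in the named dialect.

    The PED dialect writes the reference allele as ``A`` and the alternate
    as ``B`` (heterozygotes as ``A B``); a re-read reproduces the coding
    whenever each locus's first called genotype carries at least one
    reference allele — an unavoidable limitation of PED, which does not
    record which allele the counts refer to.
    """
    if dialect == "tsv_matrix":
        labels = gm.pop_labels if gm.pop_labels is not None else ["NA"] * gm.n_samples
        body = gm.G.astype(object)
        body[gm.G == MISSING] = "NA"
        df = pd.DataFrame(body, columns=gm.loci)
        df.insert(0, "population", labels)
        df.insert(0, "sample", gm.samples)
        df.to_csv(path, sep="\t", index=False)
        return
    if dialect == "ped_map":
        ped_path, map_path = _ped_paths(path)
        with open(map_path, "w") as fh:
            for j, locus in enumerate(gm.loci):
                fh.write(f"1\t{locus}\t0\t{j + 1}\n")
        pair = {0: "B B", 1: "A B", 2: "A A", MISSING: "0 0"}
        labels = gm.pop_labels if gm.pop_labels is not None else ["FAM"] * gm.n_samples
        with open(ped_path, "w") as fh:
            for i, sid in enumerate(gm.samples):
                alleles = " ".join(pair[int(g)] for g in gm.G[i])
                fh.write(f"{labels[i]} {sid} 0 0 0 -9 {alleles}\n")
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def read_panel(path: str | Path, name: str | None = None) -> PanelDefinition:
    """Read a panel file: one locus ID per line, ``#`` lines ignored."""
    p = Path(path)
    loci = []
    with open(p) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            loci.append(line)
    return PanelDefinition(name=name or p.stem, loci=loci)


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# panel: {panel.name}\n")
        for locus in panel.loci:
            fh.write(locus + "\n")


def filter_by_call_rate(gm: GenotypeMatrix, min_call: float) -> GenotypeMatrix:
    """Drop samples whose call rate falls below ``min_call``.

    Mirrors the standard quality filter for AIM-panel studies: profiles with
    more than ``1 - min_call`` missing data are removed (the conventional
    threshold is 0.9, i.e. >10% missing).  Sample order is preserved.
    """
    if not 0.0 <= min_call <= 1.0:
        raise ValueError("min_call must be in [0, 1]")
    keep = np.flatnonzero(gm.call_rates() >= min_call)
    if keep.size == 0:
        warnings.warn("call-rate filter removed every sample", UserWarning)
    if keep.size == gm.n_samples:
        return gm
    return gm.take_samples(keep)


def subset_by_panel(gm: GenotypeMatrix, panel: PanelDefinition) -> PanelSubset:
    """Restrict a genotype matrix to the loci of a panel, in panel order.

    Returns the subset together with the panel loci absent from ``gm``
    (panels are routinely only partially contained in a given dataset).
    Raises ``ValueError`` when no panel locus is present.
    """
    pos = {locus: j for j, locus in enumerate(gm.loci)}
    present = [locus for locus in panel.loci if locus in pos]
    absent = [locus for locus in panel.loci if locus not in pos]
    if not present:
        raise ValueError(
            f"panel {panel.name!r} shares no loci with the genotype matrix"
        )
    return PanelSubset(gm.take_loci([pos[l] for l in present]), absent)
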