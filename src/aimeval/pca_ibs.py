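"""Identity-by-state similarity and 2-D PCA for structural checks.

IBS similarity between two diploid genotypes counts shared alleles: a pair
of identical genotypes shares both alleles (1.0), genotypes differing by
one allele copy share one (0.5), and opposite homozygotes share none (0.0).
"Two-dimensional PCA on IBS values" is realised as classical
multidimensional scaling of the dissimilarity ``1 - IBS`` (the standard
MDS-on-IBS construction): double-centre the squared distances, take the
top eigenpairs, and fix each component's sign so its largest-magnitude
loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["SimilarityMatrix", "ibs_matrix", "pca_from_ibs"]

#: Pairs with fewer jointly called loci than this are flagged as unreliable.
MIN_JOINT_LOCI: int = 10


@dataclass
class SimilarityMatrix:
    """Symmetric N x N similarity in [0, 1] with unit self-similarity."""

    samples: list[str]
    S: np.ndarray
    low_overlap: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.samples)
        if self.S.shape != (n, n):
            raise ValueError("S must be N x N")
        if not np.allclose(self.S, self.S.T, equal_nan=True):
            raise ValueError("S must be symmetric")
        finite = np.isfinite(self.S)
        if np.any(self.S[finite] < -1e-9) or np.any(self.S[finite] > 1 + 1e-9):
            raise ValueError("similarities must lie in [0, 1]")


def ibs_matrix(gm: GenotypeMatrix) -> SimilarityMatrix:
    """Pairwise IBS similarity over jointly called loci.

    ``S_ij = (loci sharing both alleles + 0.5 * loci sharing one) /
    jointly called loci`` — equivalently the mean of ``1 - |g_i - g_j| / 2``.
    Pairs with fewer than :data:`MIN_JOINT_LOCI` jointly called loci are
    flagged in ``low_overlap`` (NaN similarity when zero joint loci).
    """
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    G = gm.G.astype(float)
    called = gm.G != MISSING
    N = gm.n_samples
    S = np.empty((N, N))
    joint_counts = np.empty((N, N))
    for i in range(N):
        joint = called[i] & called
        d = np.abs(np.where(joint, G[i] - G, 0.0)).sum(axis=1)
        cnt = joint.sum(axis=1)
        joint_counts[i] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            S[i] = np.where(cnt > 0, 1.0 - d / (2.0 * np.maximum(cnt, 1)), np.nan)
    np.fill_diagonal(S, 1.0)
    low = joint_counts < MIN_JOINT_LOCI
    np.fill_diagonal(low, False)
    return SimilarityMatrix(list(gm.samples), S, low_overlap=low)


def pca_from_ibs(sim: SimilarityMatrix, n_components: int = 2) -> np.ndarray:
    """Classical MDS coordinates from an IBS similarity matrix.

    Returns ``(N, n_components)`` coordinates ordered by decreasing
    eigenvalue; components with nonpositive eigenvalues come out as zeros.
    """
    N = len(sim.samples)
    if not 1 <= n_components <= N:
        raise ValueError("n_components must lie in [1, N]")
    if not np.allclose(sim.S, sim.S.T, equal_nan=True):
        raise ValueError("similarity matrix must be symmetric")
    if np.isnan(sim.S).any():
        raise ValueError("similarity matrix contains NaN (zero-overlap pairs)")
    D2 = (1.0 - sim.S) ** 2
    J = np.eye(N) - np.ones((N, N)) / N
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:n_components]
    coords = np.zeros((N, n_components))
    for c, idx in enumerate(order):
        lam = evals[idx]
        if lam <= 0:
            continue
        v = evecs[:, idx]
        if v[np.argmax(np.abs(v))] < 0:  # deterministic sign convention
            v = -v
        coords[:, c] = v * np.sqrt(lam)
    return coords
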