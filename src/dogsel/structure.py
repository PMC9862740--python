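"""Population structure: identity-by-state distances and classical MDS.

IBS similarity between two diploids is the allele-sharing fraction over
markers non-missing in both, ``mean((2 - |d_i - d_j|) / 2)`` on dosages;
distance is one minus that.  Classical (Torgerson) MDS double-centers the
squared distance matrix and takes the top eigenpairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import MISSING, GenotypePanel

__all__ = ["DistanceMatrix", "MdsResult", "ibs_distance", "classical_mds"]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0,1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with id list")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0,1]")
        self.values = v


@dataclass
class MdsResult:
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # top k, descending


def ibs_distance(panel: GenotypePanel) -> DistanceMatrix:
    """Pairwise 1 - IBS-similarity with pairwise-complete missing handling."""
    n = panel.n_samples
    D = np.zeros((n, n))
    dos = panel.dosage.astype(np.int16)
    ok = panel.dosage != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {panel.samples[i].id},{panel.samples[j].id} share no called markers"
                )
            sim = float((2 - np.abs(dos[i, both] - dos[j, both])).sum()) / (2 * m)
            D[i, j] = D[j, i] = 1.0 - sim
    return DistanceMatrix(ids=panel.sample_ids(), values=D)


def classical_mds(dist: DistanceMatrix, k: int = 2) -> MdsResult:
    """Torgerson MDS of a distance matrix.

    Coordinates are eigenvector * sqrt(eigenvalue) for the top ``k`` positive
    eigenvalues; each component's sign is fixed so its largest-magnitude
    loading is positive (a convention that does not depend on sample order).
    ``k`` beyond the positive-eigenvalue count is truncated with a warning.
    """
    D = dist.values
    n = D.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-10).sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating MDS from k={k}", stacklevel=2
        )
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for c in range(k):
        if coords[np.argmax(np.abs(coords[:, c])), c] < 0:
            coords[:, c] = -coords[:, c]
    return MdsResult(coordinates=coords, eigenvalues=evals[:k])
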