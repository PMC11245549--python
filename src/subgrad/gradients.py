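"""Laplacian-eigenmap functional gradients and Procrustes alignment.

A sparsified FC matrix is turned into a voxel-by-voxel affinity (clipped
cosine similarity of FC rows), embedded with the eigenvectors of the
symmetric normalized graph Laplacian (random-walk back-transform, trivial
eigenpair dropped), and individual embeddings are aligned to a group
template by orthogonal Procrustes.  The first component (FG1) orders
voxels along the dominant axis of connectivity variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from subgrad.connectivity import FCMatrix


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative voxel x voxel affinity with unit diagonal."""

    values: np.ndarray
    kernel: str = "cosine_clipped"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("affinity matrix must be square")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("affinity matrix must be symmetric")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientSet:
    """Per-subject or group embedding: components, spectrum, variance."""

    components: np.ndarray        # voxels x K; FG1 = column 0
    eigenvalues: np.ndarray       # K nontrivial normalized-Laplacian eigenvalues
    variance_explained: np.ndarray
    aligned_to: str | None = None

    @property
    def n_voxels(self) -> int:
        return self.components.shape[0]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def fg(self, index: int = 1) -> np.ndarray:
        """1-based gradient accessor: fg(1) is FG1."""
        return self.components[:, index - 1]


def cosine_affinity(fc: FCMatrix, allow_unsparsified: bool = False) -> AffinityMatrix:
    """Clipped cosine similarity between FC rows.

    Entry (u, v) = max(0, cos(row_u, row_v)); negative similarities are
    clipped to zero so the affinity defines a nonnegative graph.
    """
    if not fc.sparsified and not allow_unsparsified:
        raise ValueError(
            "FC matrix is not sparsified; pass allow_unsparsified=True to override"
        )
    norms = np.linalg.norm(fc.values, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"all-zero FC rows for voxels {bad.tolist()}")
    unit = fc.values / norms[:, None]
    cos = unit @ unit.T
    np.clip(cos, 0.0, 1.0, out=cos)
    cos = 0.5 * (cos + cos.T)
    np.fill_diagonal(cos, 1.0)
    return AffinityMatrix(values=cos)


def variance_explained(eigenvalues: np.ndarray) -> np.ndarray:
    """Proportions from spectral weights w_k = max(0, 1 - lambda_k).

    The normalized-Laplacian eigenvalue lambda_k maps to the affinity
    operator's spectral energy 1 - lambda_k; proportions are these weights
    normalized to sum to 1 and are non-increasing for an ascending spectrum.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0) or np.any(lam > 2 + 1e-12):
        raise ValueError("eigenvalues must lie in (0, 2]")
    w = np.maximum(0.0, 1.0 - lam)
    total = w.sum()
    if total == 0:
        raise ValueError("degenerate spectrum: all spectral weights are zero")
    return w / total


class LaplacianEigenmaps(BaseEstimator):
    """Spectral embedding of an affinity graph.

    Eigen-decomposition of the symmetric normalized Laplacian
    L = I - D^(-1/2) W D^(-1/2); the trivial (lambda = 0) pair is dropped,
    the next ``n_components`` eigenvectors are back-transformed by
    D^(-1/2) (random-walk convention), scaled to unit norm, and signed so
    the largest-magnitude loading is positive.

    Parameters
    ----------
    n_components : number of nontrivial gradients to keep (default 10).
    dense_threshold : below this voxel count a full dense solver is used;
        above it a shift-invert sparse Lanczos solver.
    tol : eigensolver tolerance and the connectivity threshold on the
        second-smallest eigenvalue.
    """

    def __init__(
        self, n_components: int = 10, dense_threshold: int = 500, tol: float = 1e-10
    ):
        self.n_components = n_components
        self.dense_threshold = dense_threshold
        self.tol = tol

    def fit(self, affinity: AffinityMatrix | np.ndarray):
        if isinstance(affinity, np.ndarray):
            affinity = AffinityMatrix(values=affinity)
        W = affinity.values
        n = W.shape[0]
        if self.n_components >= n - 1:
            raise ValueError("n_components must be < n_voxels - 1")
        deg = W.sum(axis=1)
        if np.any(deg <= 0):
            raise ValueError("graph has an isolated voxel (zero degree)")
        dm12 = 1.0 / np.sqrt(deg)
        L = -dm12[:, None] * W * dm12[None, :]
        np.fill_diagonal(L, L.diagonal() + 1.0)
        L = 0.5 * (L + L.T)

        k = self.n_components + 1
        if n <= self.dense_threshold:
            lam, vec = scipy.linalg.eigh(L, subset_by_index=[0, k - 1])
        else:
            # shift just below 0: L is singular at 0, so shift-invert there
            # would factorize a singular matrix
            lam, vec = scipy.sparse.linalg.eigsh(
                scipy.sparse.csr_matrix(L), k=k, sigma=-0.01, which="LM", tol=self.tol
            )
            order = np.argsort(lam)
            lam, vec = lam[order], vec[:, order]
        if lam[1] < 1e-10:
            raise ValueError(
                "affinity graph is disconnected (repeated zero eigenvalue); "
                "relax the sparsification threshold"
            )
        lam = lam[1:]
        vec = vec[:, 1:]
        comp = dm12[:, None] * vec
        comp /= np.linalg.norm(comp, axis=0, keepdims=True)
        # deterministic sign: largest-magnitude loading positive
        for j in range(comp.shape[1]):
            idx = np.argmax(np.abs(comp[:, j]))
            if comp[idx, j] < 0:
                comp[:, j] *= -1
        lam = np.minimum(lam, 2.0)
        self.eigenvalues_ = lam
        self.components_ = comp
        try:
            self.variance_explained_ = variance_explained(lam)
        except ValueError:
            # fully degenerate spectrum (e.g. a complete graph): the
            # embedding is still returned, with proportions flagged NaN
            self.variance_explained_ = np.full(lam.shape, np.nan)
        return self

    def fit_transform(self, affinity) -> GradientSet:
        self.fit(affinity)
        return GradientSet(
            components=self.components_,
            eigenvalues=self.eigenvalues_,
            variance_explained=self.variance_explained_,
        )


def laplacian_eigenmap(aff: AffinityMatrix, n_components: int) -> GradientSet:
    """Functional wrapper over :class:`LaplacianEigenmaps`."""
    return LaplacianEigenmaps(n_components=n_components).fit_transform(aff)


class ProcrustesAlignment(BaseEstimator):
    """Orthogonal Procrustes alignment to a reference embedding.

    Finds the orthogonal matrix R (rotation + reflection; no scaling, no
    translation beyond column centering) minimizing the Frobenius distance
    of X R to the reference, and applies it to the uncentered input.
    """

    def __init__(self, reference_id: str = "group"):
        self.reference_id = reference_id

    def fit(self, reference: GradientSet | np.ndarray):
        ref = reference.components if isinstance(reference, GradientSet) else reference
        self.reference_ = np.asarray(ref, dtype=float)
        return self

    def transform(self, individual: GradientSet | np.ndarray) -> GradientSet:
        is_set = isinstance(individual, GradientSet)
        X = individual.components if is_set else np.asarray(individual, dtype=float)
        Y = self.reference_
        if X.shape != Y.shape:
            raise ValueError(
                f"shape mismatch: individual {X.shape} vs reference {Y.shape}"
            )
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        U, _, Vt = np.linalg.svd(Xc.T @ Yc)
        R = U @ Vt
        aligned = X @ R
        if is_set:
            return replace(individual, components=aligned, aligned_to=self.reference_id)
        return GradientSet(
            components=aligned,
            eigenvalues=np.array([]),
            variance_explained=np.array([]),
            aligned_to=self.reference_id,
        )


def procrustes_align(individual: GradientSet, reference: GradientSet) -> GradientSet:
    """Functional wrapper over :class:`ProcrustesAlignment`."""
    return ProcrustesAlignment().fit(reference).transform(individual)


def orient_to_axis(gradients: GradientSet, coordinate: np.ndarray) -> GradientSet:
    """Fix component signs so each correlates positively with a coordinate.

    Used at group level (first lattice/mm axis by convention); individuals
    inherit signs through Procrustes alignment.
    """
    comp = gradients.components.copy()
    for j in range(comp.shape[1]):
        rho = spearmanr(comp[:, j], coordinate).statistic
        if np.isfinite(rho) and rho < 0:
            comp[:, j] *= -1
    return replace(gradients, components=comp)
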