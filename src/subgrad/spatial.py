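"""Spatially-autocorrelation-aware map comparison.

Voxelwise maps are compared by Spearman correlation, with significance
assessed against Moran-spectrum-randomization (MSR) surrogates: the map is
projected onto the eigenvectors of the doubly-centered spatial weight
matrix (Moran eigenvectors), and surrogates randomize coefficient signs —
rotating within eigenvalue-degenerate subspaces — while preserving each
eigenvector's squared power.  Surrogates therefore preserve the map's
mean, variance and Moran's I, giving a null distribution that respects
spatial autocorrelation instead of assuming exchangeable voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata, spearmanr, ttest_ind

from subgrad.simulate import Geometry


@dataclass
class SpatialWeightMatrix:
    """Nonnegative symmetric voxel x voxel weights with zero diagonal."""

    values: np.ndarray
    construction: str = "knn_inverse_distance"
    k: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        W = self.values
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.max(np.abs(W - W.T)) > 1e-10:
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if W.min() < 0:
            raise ValueError("weights must be nonnegative")
        if np.any(W.sum(axis=1) == 0):
            raise ValueError("every voxel needs at least one positive weight")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def build_spatial_weights(geometry: Geometry, k: int = 26) -> SpatialWeightMatrix:
    """Inverse-distance weights to each voxel's k nearest neighbours.

    Euclidean distances in millimetre coordinates; the matrix is
    symmetrized by the elementwise maximum.  k = 26 spans the full 3-D
    lattice neighbourhood by default.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = geometry.coords_mm
    n = coords.shape[0]
    k = min(k, n - 1)
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=k + 1)
    dist, idx = dist[:, 1:], idx[:, 1:]          # drop self-match
    if np.any(dist == 0):
        raise ValueError("duplicate voxel coordinates (zero distance)")
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    W[rows, idx.ravel()] = 1.0 / dist.ravel()
    W = np.maximum(W, W.T)
    return SpatialWeightMatrix(values=W, construction="knn_inverse_distance", k=k)


def moran_i(voxel_map: np.ndarray, W: SpatialWeightMatrix) -> float:
    """Classical Moran's I = (N / S0) (z' W z) / (z' z), z centered."""
    x = np.asarray(voxel_map, dtype=float)
    if x.std() == 0:
        raise ValueError("Moran's I undefined for a constant map")
    z = x - x.mean()
    Wv = W.values
    s0 = Wv.sum()
    return float(len(x) / s0 * (z @ Wv @ z) / (z @ z))


def _moran_basis(W: SpatialWeightMatrix, degeneracy_tol: float = 1e-8):
    """Moran eigenvectors of the doubly-centered weight matrix.

    Eigenvectors spanning the constant direction are removed so surrogate
    randomization cannot shift the map mean; degenerate eigenvalues are
    grouped for within-subspace rotation.
    """
    Wv = W.values
    n = Wv.shape[0]
    ones = np.full(n, 1.0 / np.sqrt(n))
    M = Wv - Wv.mean(axis=0)
    M = M - M.mean(axis=1, keepdims=True)
    M = 0.5 * (M + M.T)
    eigval, eigvec = np.linalg.eigh(M)

    # drop the basis direction aligned with the constant vector
    overlap = np.abs(eigvec.T @ ones)
    scale = max(1.0, np.max(np.abs(eigval)))
    groups = []
    keep_vecs = []
    keep_vals = []
    start = 0
    while start < n:
        stop = start + 1
        while stop < n and abs(eigval[stop] - eigval[start]) <= degeneracy_tol * scale:
            stop += 1
        block = eigvec[:, start:stop]
        if np.max(overlap[start:stop]) > 1e-6:
            # orthogonalize the block against the constant direction
            block = block - ones[:, None] * (ones @ block)
            q, r = np.linalg.qr(block)
            keep = np.abs(np.diag(r)) > 1e-10
            block = q[:, keep]
        if block.shape[1]:
            groups.append((len(keep_vals), len(keep_vals) + block.shape[1]))
            keep_vecs.append(block)
            keep_vals.extend([eigval[start]] * block.shape[1])
        start = stop
    V = np.hstack(keep_vecs)
    return V, np.array(keep_vals), groups


class MoranSpectrum:
    """Precomputed Moran eigenvector basis for repeated randomization.

    Building the basis costs one dense eigen-decomposition; surrogate
    stacks and spatial-null tests against a fixed weight matrix then reuse
    it, which matters when many maps share a lattice.
    """

    def __init__(self, W: SpatialWeightMatrix, degeneracy_tol: float = 1e-8):
        self.W = W
        self.basis_, self.eigenvalues_, self.groups_ = _moran_basis(
            W, degeneracy_tol
        )

    def surrogates(
        self, voxel_map: np.ndarray, n_surrogates: int, seed: int = 0
    ) -> np.ndarray:
        if n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        x = np.asarray(voxel_map, dtype=float)
        if x.shape[0] != self.W.n_voxels:
            raise ValueError("map and weight matrix must share the voxel count")
        rng = np.random.default_rng(seed)
        V = self.basis_
        mean = x.mean()
        coef = V.T @ (x - mean)
        # any power outside the retained basis rides along unchanged
        resid = (x - mean) - V @ coef
        singles = np.array(
            [lo for lo, hi in self.groups_ if hi - lo == 1], dtype=int
        )
        multis = [(lo, hi) for lo, hi in self.groups_ if hi - lo > 1]
        C = np.tile(coef, (n_surrogates, 1))
        if singles.size:
            signs = rng.choice([-1.0, 1.0], size=(n_surrogates, singles.size))
            C[:, singles] *= signs
        for lo, hi in multis:
            d = hi - lo
            for s in range(n_surrogates):
                q, _ = np.linalg.qr(rng.standard_normal((d, d)))
                C[s, lo:hi] = q @ coef[lo:hi]
        return mean + C @ V.T + resid


def msr_surrogates(
    voxel_map: np.ndarray,
    W: SpatialWeightMatrix | MoranSpectrum,
    n_surrogates: int,
    seed: int = 0,
    degeneracy_tol: float = 1e-8,
) -> np.ndarray:
    """Moran-spectrum-randomization surrogate maps (singleton variant).

    Returns an (n_surrogates, n_voxels) stack preserving the original
    mean, variance, per-eigenvector squared power (up to rotations within
    degenerate subspaces) and hence Moran's I.
    """
    spectrum = W if isinstance(W, MoranSpectrum) else MoranSpectrum(W, degeneracy_tol)
    return spectrum.surrogates(voxel_map, n_surrogates, seed=seed)


def spearman_similarity(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Spearman rank correlation with average-rank ties."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be 1-D and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 voxels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Spearman correlation undefined for a constant map")
    return float(spearmanr(a, b).statistic)


def p_moran(
    map_x: np.ndarray,
    map_y: np.ndarray,
    W: SpatialWeightMatrix | MoranSpectrum,
    n_surrogates: int = 1000,
    seed: int = 0,
    tail: str = "two",
) -> dict:
    """Spearman correlation with an MSR spatial null.

    Surrogates randomize ``map_x`` (conditioning on ``map_y``); the
    default two-tailed p is (#{|null| >= |rho|} + 1) / (n + 1); ``tail =
    'greater'`` gives the one-tailed proportion of null correlations at or
    above the observed one.
    """
    rho = spearman_similarity(map_x, map_y)
    surr = msr_surrogates(map_x, W, n_surrogates, seed=seed)
    ry = rankdata(map_y)
    rs = rankdata(surr, axis=1)
    ry_c = ry - ry.mean()
    rs_c = rs - rs.mean(axis=1, keepdims=True)
    null = (rs_c @ ry_c) / (
        np.linalg.norm(rs_c, axis=1) * np.linalg.norm(ry_c)
    )
    if tail == "two":
        p = (np.sum(np.abs(null) >= abs(rho)) + 1) / (n_surrogates + 1)
    elif tail == "greater":
        p = (np.sum(null >= rho) + 1) / (n_surrogates + 1)
    else:
        raise ValueError("tail must be 'two' or 'greater'")
    return {"rho": rho, "p": float(p), "n_surrogates": n_surrogates, "tail": tail}


def kinship_similarity_test(
    similarities_by_group: dict[str, np.ndarray],
    group_pairs: list[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], dict]:
    """Welch two-sample two-tailed t-tests between kinship groups."""
    groups = {k: np.asarray(v, dtype=float) for k, v in similarities_by_group.items()}
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
    if group_pairs is None:
        names = list(groups)
        group_pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
    out = {}
    for a, b in group_pairs:
        t, p = ttest_ind(groups[a], groups[b], equal_var=False)
        out[(a, b)] = {"t_stat": float(t), "p": float(p)}
    return out
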