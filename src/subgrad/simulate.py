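"""Synthetic twin cohorts, voxel geometries and heritable phenotypes.

Every downstream stage of the package is exercised on data produced here,
with planted ground truth: a 1-D unimodal-to-transmodal hierarchy axis on a
voxel lattice, additive-genetic / common-environment / unique-environment
(A/C/E) variance fractions per voxel, time series whose subcortico-cortical
connectivity embeds the planted axis, and trait pairs with a prescribed
genetic correlation.

The classical twin assumptions apply throughout: monozygotic (MZ) pairs
share their additive-genetic component exactly, dizygotic (DZ) and
full-sibling (SIB) pairs share it with correlation 0.5, any co-resident
family shares the common-environment component, and the unique-environment
component is independent across subjects.  Families are restricted to pairs
or singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ZYGOSITIES = ("MZ", "DZ", "SIB", "SINGLETON")

# Covariate distributions (documented constants; cohort-summary scale):
# adult twin samples span early adulthood, head motion is right-skewed.
AGE_RANGE_YEARS = (22.0, 37.0)
MOTION_LOGNORMAL_MU = np.log(0.12)   # mean framewise displacement ~0.13 mm
MOTION_LOGNORMAL_SIGMA = 0.4

# Width of the Gaussian coupling kernel on the [0, 1] hierarchy axis.
GRADIENT_KERNEL_WIDTH = 0.15


@dataclass(frozen=True)
class Geometry:
    """Voxel lattice with a planted hierarchy axis and network labels.

    ``voxel_coords`` are integer lattice indices (n_voxels, 3) linearised
    with the first axis fastest-varying; millimetre coordinates are the
    affine image of those indices.  ``hierarchy_axis`` is the planted
    unimodal-to-transmodal coordinate in [0, 1], increasing along the first
    lattice axis.  Cortical ROIs carry their own network labels so that the
    winner-take-all parcellation has a ground truth to recover.
    """

    shape: tuple[int, int, int]
    voxel_coords: np.ndarray
    affine: np.ndarray
    network_labels: np.ndarray
    hierarchy_axis: np.ndarray
    cortical_roi_count: int
    cortical_network_labels: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.voxel_coords.shape[0]

    @property
    def coords_mm(self) -> np.ndarray:
        """Millimetre coordinates: affine applied to lattice indices."""
        homog = np.c_[self.voxel_coords, np.ones(self.n_voxels)]
        return (homog @ self.affine.T)[:, :3]


@dataclass
class TwinCohort:
    """Subject table: id, family, zygosity, age, sex, motion.

    MZ/DZ/SIB members share a ``family_id`` in groups of exactly two;
    singletons are their own family.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "family_id", "zygosity", "age", "sex", "motion"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("subject_id values must be unique")
        bad = set(self.table["zygosity"]) - set(ZYGOSITIES)
        if bad:
            raise ValueError(f"unknown zygosity codes: {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def pairs(self, zygosity: str) -> np.ndarray:
        """Positional (i, j) index pairs for one zygosity group."""
        sub = self.table.reset_index(drop=True)
        rows = sub.index[sub["zygosity"] == zygosity]
        out = []
        for fam, grp in sub.loc[rows].groupby("family_id", sort=True):
            idx = grp.index.to_numpy()
            if len(idx) != 2:
                raise ValueError(
                    f"family {fam} has {len(idx)} {zygosity} members; pairs required"
                )
            out.append(idx)
        return np.array(out, dtype=int).reshape(-1, 2)

    def singletons(self) -> np.ndarray:
        sub = self.table.reset_index(drop=True)
        return sub.index[sub["zygosity"] == "SINGLETON"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TwinCohort":
        return cls(pd.read_csv(path))


@dataclass
class PhenotypeMaps:
    """Subjects x voxels phenotype matrix entering the ACE model."""

    values: np.ndarray
    trait_name: str = "trait"
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a subjects x voxels matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype values must be finite")

    def standardize(self) -> "PhenotypeMaps":
        """Per-voxel z-scoring (population moments, so variance is exactly 1)."""
        v = self.values
        sd = v.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("cannot standardize a zero-variance voxel")
        out = (v - v.mean(axis=0)) / sd
        return replace(self, values=out, standardized=True)


@dataclass(frozen=True)
class ACEProfile:
    """Ground-truth per-voxel variance fractions; a2 + c2 + e2 = 1."""

    a2: np.ndarray
    c2: np.ndarray
    e2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("a2", "c2", "e2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        total = self.a2 + self.c2 + self.e2
        if np.max(np.abs(total - 1.0)) > 1e-12:
            raise ValueError("a2 + c2 + e2 must equal 1 at every voxel")

    @classmethod
    def constant(cls, a2: float, c2: float, n_voxels: int) -> "ACEProfile":
        e2 = 1.0 - a2 - c2
        return cls(
            a2=np.full(n_voxels, a2),
            c2=np.full(n_voxels, c2),
            e2=np.full(n_voxels, e2),
        )


@dataclass
class SimulatedTimeseries:
    """Per-subject voxel x time and cortical-ROI x time series."""

    voxel_ts: np.ndarray          # (n_subjects, n_voxels, T)
    roi_ts: np.ndarray            # (n_subjects, n_rois, T)
    roi_axis_coords: np.ndarray   # latent ROI coordinate u_r in [0, 1]


def make_geometry(
    shape: tuple[int, int, int],
    n_networks: int,
    seed: int,
    n_cortical_rois: int = 50,
    voxel_size_mm: float = 2.0,
) -> Geometry:
    """Build a lattice geometry with a planted hierarchy axis.

    The hierarchy axis increases monotonically along the first lattice axis
    and network labels partition voxels into contiguous slabs along it.
    Cortical ROI network labels are drawn so every network gets >= 1 ROI.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError("shape must be three positive lattice dimensions")
    n_voxels = int(np.prod(shape))
    if n_voxels < 2:
        raise ValueError("geometry needs at least 2 voxels")
    if not 2 <= n_networks <= 7:
        raise ValueError("n_networks must be in 2..7")
    if n_cortical_rois < n_networks:
        raise ValueError("need at least one cortical ROI per network")

    # first axis fastest-varying linearisation
    coords = np.stack(
        np.unravel_index(np.arange(n_voxels), shape, order="F"), axis=1
    ).astype(int)
    nx = shape[0]
    if nx > 1:
        axis = coords[:, 0] / (nx - 1)
    else:
        axis = np.zeros(n_voxels)
    labels = np.minimum((axis * n_networks).astype(int), n_networks - 1) + 1

    # cortical networks mirror the hierarchy: ROIs are indexed along the
    # latent [0, 1] coordinate, so contiguous label slabs give each network
    # >= 1 ROI and make the subcortical parcellation recover the planted axis
    u = (
        np.arange(n_cortical_rois) / (n_cortical_rois - 1)
        if n_cortical_rois > 1
        else np.zeros(1)
    )
    cort = np.minimum((u * n_networks).astype(int), n_networks - 1) + 1

    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return Geometry(
        shape=shape,
        voxel_coords=coords,
        affine=affine,
        network_labels=labels,
        hierarchy_axis=axis,
        cortical_roi_count=n_cortical_rois,
        cortical_network_labels=cort,
    )


def simulate_twin_cohort(
    n_mz: int, n_dz: int, n_sib: int, n_unrelated: int, seed: int
) -> TwinCohort:
    """Sample a cohort of MZ/DZ/SIB pairs plus singletons.

    Pair members share family id and age (twins are born together; the
    sibling age gap is ignored as immaterial to the variance model); sex is
    Bernoulli(0.5) per subject and motion is log-normal per subject.
    """
    counts = (n_mz, n_dz, n_sib, n_unrelated)
    if any(c < 0 for c in counts):
        raise ValueError("pair/singleton counts must be nonnegative")
    n_subjects = 2 * (n_mz + n_dz + n_sib) + n_unrelated
    if n_subjects < 2:
        raise ValueError("cohort needs at least 2 subjects")

    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    fid = 0

    def new_subject(family: str, zyg: str, age: float) -> None:
        nonlocal sid
        sid += 1
        rows.append(
            {
                "subject_id": f"S{sid:05d}",
                "family_id": family,
                "zygosity": zyg,
                "age": age,
                "sex": int(rng.integers(0, 2)),
                "motion": float(
                    rng.lognormal(MOTION_LOGNORMAL_MU, MOTION_LOGNORMAL_SIGMA)
                ),
            }
        )

    for zyg, n_pairs in (("MZ", n_mz), ("DZ", n_dz), ("SIB", n_sib)):
        for _ in range(n_pairs):
            fid += 1
            age = float(rng.uniform(*AGE_RANGE_YEARS))
            family = f"F{fid:05d}"
            new_subject(family, zyg, age)
            new_subject(family, zyg, age)
    for _ in range(n_unrelated):
        fid += 1
        age = float(rng.uniform(*AGE_RANGE_YEARS))
        new_subject(f"F{fid:05d}", "SINGLETON", age)

    return TwinCohort(pd.DataFrame(rows))


def _twin_structured_normals(
    cohort: TwinCohort, n_voxels: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (g, f, e) standard-normal component matrices with twin structure.

    g: shared exactly within MZ pairs, correlation 0.5 within DZ/SIB pairs
    (g = sqrt(0.5) g_shared + sqrt(0.5) g_unique, so the marginal variance is
    exactly 1); f: shared within any family; e: independent.
    """
    n = cohort.n_subjects
    g = np.empty((n, n_voxels))
    f = np.empty((n, n_voxels))
    e = rng.standard_normal((n, n_voxels))

    for i, j in cohort.pairs("MZ"):
        shared = rng.standard_normal(n_voxels)
        g[i] = shared
        g[j] = shared
        fam = rng.standard_normal(n_voxels)
        f[i] = fam
        f[j] = fam
    for zyg in ("DZ", "SIB"):
        for i, j in cohort.pairs(zyg):
            shared = rng.standard_normal(n_voxels)
            g[i] = np.sqrt(0.5) * shared + np.sqrt(0.5) * rng.standard_normal(n_voxels)
            g[j] = np.sqrt(0.5) * shared + np.sqrt(0.5) * rng.standard_normal(n_voxels)
            fam = rng.standard_normal(n_voxels)
            f[i] = fam
            f[j] = fam
    for i in cohort.singletons():
        g[i] = rng.standard_normal(n_voxels)
        f[i] = rng.standard_normal(n_voxels)
    return g, f, e


def simulate_heritable_maps(
    cohort: TwinCohort,
    geometry: Geometry,
    profile: ACEProfile,
    seed: int,
    trait_name: str = "trait",
) -> PhenotypeMaps:
    """Voxelwise phenotypes with planted A/C/E variance fractions.

    y_iv = sqrt(a2_v) g_iv + sqrt(c2_v) f_iv + sqrt(e2_v) eps_iv with the
    components of :func:`_twin_structured_normals`; marginal variance is 1,
    expected MZ cross-pair correlation a2 + c2, DZ/SIB 0.5 a2 + c2.
    """
    if profile.a2.shape[0] != geometry.n_voxels:
        raise ValueError("ACE profile must cover every voxel of the geometry")
    rng = np.random.default_rng(seed)
    g, f, e = _twin_structured_normals(cohort, geometry.n_voxels, rng)
    values = (
        np.sqrt(profile.a2) * g + np.sqrt(profile.c2) * f + np.sqrt(profile.e2) * e
    )
    return PhenotypeMaps(values=values, trait_name=trait_name)


def simulate_timeseries(
    cohort: TwinCohort,
    geometry: Geometry,
    timepoints: int,
    coupling_strength: float,
    noise_sd: float,
    heritable_shift: float,
    seed: int,
    kernel_width: float = GRADIENT_KERNEL_WIDTH,
    shift_profile: tuple[float, float, float] = (0.5, 0.2, 0.3),
) -> SimulatedTimeseries:
    """Time series whose subcortico-cortical FC embeds the planted axis.

    Each cortical ROI r carries a latent coordinate u_r evenly spaced in
    [0, 1] and an i.i.d. N(0,1) latent signal s_r(t).  Voxel v of subject i
    sees  coupling_strength * sum_r K(axis_v + delta_i * heritable_shift,
    u_r) s_r(t) + noise,  with K a Gaussian bump of width ``kernel_width``
    in |axis - u_r| and delta_i a per-subject heritable scalar drawn with
    the twin structure of :func:`simulate_heritable_maps` under
    ``shift_profile``.  The FC rows therefore vary smoothly along the
    hierarchy axis and the first Laplacian eigenmap recovers its ordering.
    """
    if timepoints < 10:
        raise ValueError("timepoints must be >= 10")
    if coupling_strength < 0:
        raise ValueError("coupling_strength must be nonnegative")
    rng = np.random.default_rng(seed)
    n_sub = cohort.n_subjects
    n_vox = geometry.n_voxels
    n_roi = geometry.cortical_roi_count

    u = np.linspace(0.0, 1.0, n_roi)
    latent = rng.standard_normal((n_sub, n_roi, timepoints))

    # child seed keeps delta reproducible yet distinct from the latent draws
    delta = _scalar_heritable_trait(
        cohort, shift_profile, seed=int(rng.integers(2**31))
    )

    voxel_ts = np.empty((n_sub, n_vox, timepoints))
    roi_ts = np.empty((n_sub, n_roi, timepoints))
    axis = geometry.hierarchy_axis
    for i in range(n_sub):
        pos = axis + delta[i] * heritable_shift
        K = np.exp(-((pos[:, None] - u[None, :]) ** 2) / (2.0 * kernel_width**2))
        voxel_ts[i] = coupling_strength * (K @ latent[i])
        roi_ts[i] = latent[i]
        if noise_sd > 0:
            voxel_ts[i] += noise_sd * rng.standard_normal((n_vox, timepoints))
            roi_ts[i] = roi_ts[i] + noise_sd * rng.standard_normal(
                (n_roi, timepoints)
            )
    return SimulatedTimeseries(voxel_ts=voxel_ts, roi_ts=roi_ts, roi_axis_coords=u)


def _single_voxel_geometry() -> Geometry:
    """Internal 2-voxel stub used to draw scalar heritable traits."""
    g = make_geometry((2, 1, 1), 2, seed=0, n_cortical_rois=2)
    return g


def _scalar_heritable_trait(
    cohort: TwinCohort, profile: tuple[float, float, float], seed: int
) -> np.ndarray:
    prof = ACEProfile.constant(profile[0], profile[1], 2)
    maps = simulate_heritable_maps(cohort, _single_voxel_geometry(), prof, seed)
    return maps.values[:, 0]


def smooth_random_map(
    geometry: Geometry, scale_mm: float, seed: int
) -> np.ndarray:
    """Spatially autocorrelated random map: kernel-smoothed white noise.

    White noise on the voxel lattice convolved with a Gaussian kernel of
    bandwidth ``scale_mm`` (millimetres), then standardized.  Serves as a
    generic smooth test map with a broad spatial-frequency spectrum.
    """
    rng = np.random.default_rng(seed)
    coords = geometry.coords_mm
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    K = np.exp(-d2 / (2.0 * scale_mm**2))
    x = K @ rng.standard_normal(geometry.n_voxels)
    return (x - x.mean()) / x.std()


def simulate_coupled_traits(
    cohort: TwinCohort, h2x: float, h2y: float, rg: float, seed: int
) -> tuple[PhenotypeMaps, PhenotypeMaps]:
    """Two standardized traits with genetic correlation rg.

    Trait additive-genetic components share correlation ``rg``; the
    environmental (here purely unique) components are independent across
    traits, so the expected cross-trait cross-twin covariance carries the
    genetic signal only.
    """
    for name, h2 in (("h2x", h2x), ("h2y", h2y)):
        if not 0.0 <= h2 <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if abs(rg) > 1.0:
        raise ValueError("rg must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    n = cohort.n_subjects
    g1, _, _ = _twin_structured_normals(cohort, 1, rng)
    g2, _, _ = _twin_structured_normals(cohort, 1, rng)
    g1, g2 = g1[:, 0], g2[:, 0]
    gx = g1
    gy = rg * g1 + np.sqrt(max(0.0, 1.0 - rg**2)) * g2
    ex = rng.standard_normal(n)
    ey = rng.standard_normal(n)
    x = np.sqrt(h2x) * gx + np.sqrt(1.0 - h2x) * ex
    y = np.sqrt(h2y) * gy + np.sqrt(1.0 - h2y) * ey
    return (
        PhenotypeMaps(x[:, None], trait_name="trait_x"),
        PhenotypeMaps(y[:, None], trait_name="trait_y"),
    )
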