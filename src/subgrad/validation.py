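"""Self-validation studies on synthetic data with known ground truth.

Each function runs one study end-to-end at documented problem sizes —
parameter recovery, test calibration, planted-structure recovery — and
returns the measured quantities.  The acceptance test suite asserts the
expected properties on these numbers and ``scripts/acceptance.py`` reports
them; both drive exactly the same computations.

All randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import stats

import subgrad as sg
from subgrad.classifier import pair_distance_matrix
from subgrad.genetics import ACEModel
from subgrad.gradients import cosine_affinity
from subgrad.spatial import MoranSpectrum


def _child_seed(seed: int, offset: int) -> int:
    return (seed * 1000003 + offset) % (2**31)


def ace_recovery_study(seed: int, n_voxels: int = 20) -> dict:
    """Recover a2 = 0.5, c2 = 0.2, e2 = 0.3 at 2000 MZ + 2000 DZ pairs.

    ``n_voxels`` independent phenotype draws share one cohort; the study
    reports the mean voxelwise ML heritability, its deviation from the
    Falconer moment estimate, and the worst h2+c2+e2 identity error.
    """
    cohort = sg.simulate_twin_cohort(2000, 2000, 0, 0, seed=_child_seed(seed, 1))
    geom = sg.make_geometry((n_voxels, 1, 1), 2, seed=0, n_cortical_rois=4)
    profile = sg.ACEProfile.constant(0.5, 0.2, n_voxels)
    maps = sg.simulate_heritable_maps(cohort, geom, profile,
                                      seed=_child_seed(seed, 2))
    model = ACEModel().fit(maps.values, cohort)

    mz, dz = cohort.pairs("MZ"), cohort.pairs("DZ")
    falc = []
    for v in range(n_voxels):
        y = maps.values[:, v]
        rmz = np.corrcoef(y[mz[:, 0]], y[mz[:, 1]])[0, 1]
        rdz = np.corrcoef(y[dz[:, 0]], y[dz[:, 1]])[0, 1]
        falc.append(2.0 * (rmz - rdz) * y.var())
    return {
        "mean_h2": float(model.h2_.mean()),
        "identity_error": float(
            np.max(np.abs(model.h2_ + model.c2_ + model.e2_ - 1.0))
        ),
        "falconer_gap": float(np.max(np.abs(model.var_a_ - np.array(falc)))),
        "n": n_voxels,
    }


def lrt_calibration_study(seed: int, n_sims: int = 2000) -> dict:
    """Type-I error of the 50:50-mixture LRT under a2 = 0, c2 = 0.3.

    ``n_sims`` independent null phenotypes on a 300 MZ + 300 DZ cohort;
    reports the rejection rate at alpha = 0.05.
    """
    cohort = sg.simulate_twin_cohort(300, 300, 0, 0, seed=_child_seed(seed, 3))
    geom = sg.make_geometry((n_sims, 1, 1), 2, seed=0, n_cortical_rois=4)
    profile = sg.ACEProfile.constant(0.0, 0.3, n_sims)
    maps = sg.simulate_heritable_maps(cohort, geom, profile,
                                      seed=_child_seed(seed, 4))
    model = ACEModel().fit(maps.values, cohort)
    return {
        "rejection_rate": float(np.mean(model.p_lrt_ < 0.05)),
        "n": n_sims,
    }


def rg_recovery_study(seed: int) -> dict:
    """Recover rg = 0.7 between traits with h2 = (0.5, 0.4), 3000+3000 pairs."""
    cohort = sg.simulate_twin_cohort(3000, 3000, 0, 0, seed=_child_seed(seed, 5))
    x, y = sg.simulate_coupled_traits(cohort, 0.5, 0.4, 0.7,
                                      seed=_child_seed(seed, 6))
    fit = sg.fit_bivariate_ace(x.values[:, 0], y.values[:, 0], cohort)
    identity = sg.genetic_correlation(fit.h_xy, fit.h2_x, fit.h2_y)
    return {
        "rg_hat": float(fit.rg),
        "rg_identity_error": float(abs(fit.rg - identity)),
        "n": cohort.n_subjects,
    }


def gradient_recovery_study(seed: int, n_voxels: int = 500,
                            n_rois: int = 50) -> dict:
    """Recover the planted 1-D hierarchy axis as FG1 from low-noise series."""
    geom = sg.make_geometry((n_voxels, 1, 1), 7, seed=_child_seed(seed, 7),
                            n_cortical_rois=n_rois)
    cohort = sg.simulate_twin_cohort(1, 1, 0, 0, seed=_child_seed(seed, 7))
    ts = sg.simulate_timeseries(
        cohort, geom, timepoints=300, coupling_strength=1.0, noise_sd=0.05,
        heritable_shift=0.0, seed=_child_seed(seed, 8),
    )
    fc = sg.fisher_z(sg.compute_fc(ts.voxel_ts[0], ts.roi_ts[0]))
    grads = sg.laplacian_eigenmap(
        cosine_affinity(sg.threshold_top_fraction(fc, 0.10)), 10
    )
    rho = stats.spearmanr(grads.fg(1), geom.hierarchy_axis).statistic
    return {"abs_spearman": float(abs(rho)), "n": n_voxels}


def procrustes_study(seed: int, n_voxels: int = 200, k: int = 10) -> dict:
    """Realign an orthogonally transformed copy of a reference embedding."""
    rng = np.random.default_rng(_child_seed(seed, 9))
    ref, _ = np.linalg.qr(rng.standard_normal((n_voxels, k)))
    Q, _ = np.linalg.qr(rng.standard_normal((k, k)))
    ref_set = sg.GradientSet(ref, np.linspace(0.1, 0.5, k), np.full(k, 1 / k))
    rotated = sg.GradientSet(ref @ Q, ref_set.eigenvalues,
                             ref_set.variance_explained)
    aligned = sg.procrustes_align(rotated, ref_set)
    return {
        "frobenius_error": float(np.linalg.norm(aligned.components - ref)),
        "n": n_voxels,
    }


def classifier_planted_study(seed: int, n_pairs: int = 150,
                             n_voxels: int = 500, n_repetitions: int = 5,
                             n_perm: int = 100) -> dict:
    """Planted-signal twin-pair classification with a permutation null.

    A fifth of the voxels carry a2 = 0.9 (zero elsewhere); MZ within-pair
    distances are stochastically smaller there.  Subject maps are scaled to
    unit norm, as eigenmap gradients are.  A coarse power-of-two grid
    (step 2 in the exponent) keeps the tuned-SVM study tractable.
    """
    X, y, planted = _planted_pair_features(seed, n_pairs, n_voxels)
    svm = sg.TwinPairSVM(
        n_repetitions=n_repetitions, grid_exponents=(-5.0, 5.0, 2.0),
        seed=_child_seed(seed, 12),
    ).fit(X, y)
    perm_p = sg.permutation_test(
        X, y, svm.mean_accuracy_, n_perm=n_perm, seed=_child_seed(seed, 13),
        grid_exponents=(-5.0, 5.0, 2.0),
    )
    pattern = svm.haufe_pattern_
    concentration = float(
        np.abs(pattern[planted]).mean() / np.abs(pattern[~planted]).mean()
    )
    return {
        "mean_accuracy": float(svm.mean_accuracy_),
        "roc_auc": float(svm.roc_auc_),
        "permutation_p": float(perm_p),
        "haufe_concentration": concentration,
        "n_perm": n_perm,
        "n": 2 * n_pairs,
    }


def _planted_pair_features(seed: int, n_pairs: int, n_voxels: int,
                           a2_planted: float = 0.9):
    geom = sg.make_geometry((n_voxels, 1, 1), 7, seed=0, n_cortical_rois=10)
    cohort = sg.simulate_twin_cohort(n_pairs, n_pairs, 0, 0,
                                     seed=_child_seed(seed, 10))
    rng = np.random.default_rng(_child_seed(seed, 11))
    planted = np.zeros(n_voxels, bool)
    planted[rng.choice(n_voxels, n_voxels // 5, replace=False)] = True
    a2 = np.where(planted, a2_planted, 0.0)
    profile = sg.ACEProfile(a2=a2, c2=np.zeros(n_voxels), e2=1.0 - a2)
    maps = sg.simulate_heritable_maps(cohort, geom, profile,
                                      seed=_child_seed(seed, 11))
    vals = maps.values / np.sqrt(n_voxels)
    X = np.vstack([
        pair_distance_matrix(vals, cohort.pairs("MZ")),
        pair_distance_matrix(vals, cohort.pairs("DZ")),
    ])
    y = np.r_[np.zeros(n_pairs, int), np.ones(n_pairs, int)]
    return X, y, planted


def classifier_null_study(seed: int, n_pairs_ci: int = 300,
                          n_pairs_perm: int = 150, n_repetitions: int = 10,
                          n_perm: int = 19) -> dict:
    """Chance-level behaviour with every voxel's heritability removed.

    The accuracy confidence interval uses 300 pairs per class — large
    enough that the finite-sample pessimistic bias of tuned
    cross-validated accuracy is negligible against the CI width — while
    the permutation check runs at 150 pairs per class, where observed and
    null accuracies share whatever small-sample bias remains.
    """
    X, y, _ = _planted_pair_features(seed, n_pairs_ci, 500, a2_planted=0.0)
    svm = sg.TwinPairSVM(
        n_repetitions=n_repetitions, grid_exponents=(-5.0, 5.0, 2.0),
        seed=_child_seed(seed, 14),
    ).fit(X, y)
    acc = svm.accuracies_
    se = acc.std(ddof=1) / np.sqrt(len(acc))
    tcrit = stats.t.ppf(0.975, len(acc) - 1)
    Xp, yp, _ = _planted_pair_features(seed, n_pairs_perm, 500, a2_planted=0.0)
    svm_p = sg.TwinPairSVM(
        n_repetitions=2, grid_exponents=(-5.0, 5.0, 2.0),
        seed=_child_seed(seed, 15),
    ).fit(Xp, yp)
    perm_p = sg.permutation_test(
        Xp, yp, svm_p.mean_accuracy_, n_perm=n_perm,
        seed=_child_seed(seed, 16), grid_exponents=(-5.0, 5.0, 2.0),
    )
    return {
        "mean_accuracy": float(acc.mean()),
        "ci_low": float(acc.mean() - tcrit * se),
        "ci_high": float(acc.mean() + tcrit * se),
        "permutation_p": float(perm_p),
        "n": 2 * n_pairs_ci,
    }


def moran_preservation_study(seed: int) -> dict:
    """Surrogate invariants on a 10 x 10 x 5 lattice, 100 surrogates."""
    geom = sg.make_geometry((10, 10, 5), 7, seed=0, n_cortical_rois=10)
    W = sg.build_spatial_weights(geom, k=26)
    x = sg.smooth_random_map(geom, 4.0, seed=_child_seed(seed, 17))
    surr = sg.msr_surrogates(x, W, 100, seed=_child_seed(seed, 18))
    i0 = sg.moran_i(x, W)
    i_dev = max(abs(sg.moran_i(s, W) - i0) for s in surr)
    return {
        "variance_error": float(np.max(np.abs(surr.var(axis=1) - x.var()))),
        "mean_error": float(np.max(np.abs(surr.mean(axis=1) - x.mean()))),
        "moran_i_deviation": float(i_dev),
        "n": geom.n_voxels,
    }


def moran_calibration_study(seed: int, n_trials: int = 1000,
                            n_surrogates: int = 99) -> dict:
    """Rejection rate of the spatial null for independent smooth maps."""
    geom = sg.make_geometry((10, 10, 5), 7, seed=0, n_cortical_rois=10)
    W = sg.build_spatial_weights(geom, k=26)
    spectrum = MoranSpectrum(W)
    rej = 0
    for t in range(n_trials):
        a = sg.smooth_random_map(geom, 4.0, seed=_child_seed(seed, 100 + 2 * t))
        b = sg.smooth_random_map(geom, 4.0,
                                 seed=_child_seed(seed, 101 + 2 * t))
        res = sg.p_moran(a, b, spectrum, n_surrogates=n_surrogates,
                         seed=_child_seed(seed, 19) + t)
        rej += res["p"] < 0.05
    return {"rejection_rate": rej / n_trials, "n": n_trials}


def pipeline_determinism_study(seed: int, outdir) -> dict:
    """Run the demo pipeline twice; byte-compare every artifact."""
    from subgrad.pipeline import RunConfig, run_pipeline

    outdir = Path(outdir)
    cfg = RunConfig(
        seed=_child_seed(seed, 20), n_reps=10, n_perm=10, n_repetitions=3,
        timepoints=150,
    )
    checks, stages = [], []
    for run in ("a", "b"):
        run_pipeline(cfg, outdir / run)
        manifest = json.loads((outdir / run / "manifest.json").read_text())
        checks.append(manifest["checksums"])
        stages.append(len(manifest["completed_stages"]))
    return {
        "identical_reruns": bool(checks[0] == checks[1]),
        "n_artifacts": len(checks[0]),
        "completed_stages": min(stages),
    }
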