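"""ACE estimation, LRT, FDR, covariate GLM, bootstrap, bivariate rG."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import subgrad as sg
from subgrad.genetics import ACEModel, BivariateACEModel


def _falconer(y, cohort):
    """Independent oracle: A_hat = 2 (rMZ - rDZ) in phenotypic-variance units."""
    mz, dz = cohort.pairs("MZ"), cohort.pairs("DZ")
    rmz = np.corrcoef(y[mz[:, 0]], y[mz[:, 1]])[0, 1]
    rdz = np.corrcoef(y[dz[:, 0]], y[dz[:, 1]])[0, 1]
    return 2.0 * (rmz - rdz) * y.var()


class TestLRTPvalue:
    def test_boundary_mass_gives_one(self):
        assert sg.lrt_pvalue(5.0, 5.0) == 1.0
        assert sg.lrt_pvalue(4.0, 5.0) == 1.0  # negative statistic clamps to 0

    def test_half_chi_square_quantiles(self):
        # chi2_1 upper-0.10 quantile 2.706 -> mixture p 0.05
        assert sg.lrt_pvalue(2.706 / 2, 0.0) == pytest.approx(0.05, abs=1e-4)
        # chi2_1 upper-0.05 quantile 3.841 -> mixture p 0.025
        assert sg.lrt_pvalue(3.841 / 2, 0.0) == pytest.approx(0.025, abs=1e-4)


class TestFdrBH:
    def test_all_pass_step_up(self):
        flags, q = sg.fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert flags.all()

    def test_none_pass(self):
        flags, _ = sg.fdr_bh([0.05, 0.5, 0.9], q=0.05)
        assert not flags.any()

    def test_single_small_p(self):
        flags, q = sg.fdr_bh([0.04], q=0.05)
        assert flags[0] and q[0] == pytest.approx(0.04)

    def test_q_monotone_and_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1.0, size=50)
        _, q = sg.fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_empty_input(self):
        flags, q = sg.fdr_bh([])
        assert flags.size == 0 and q.size == 0


class TestResidualize:
    def test_phenotype_in_design_space_vanishes(self, small_cohort):
        design = sg.build_covariates(small_cohort)
        age = design["age"].to_numpy()
        resid = sg.residualize_nuisance(age, design)
        assert np.max(np.abs(resid)) < 1e-10

    def test_orthogonal_phenotype_unchanged(self, small_cohort):
        design = sg.build_covariates(small_cohort)
        X = design.to_numpy()
        rng = np.random.default_rng(2)
        y = rng.standard_normal(small_cohort.n_subjects)
        y -= X @ np.linalg.lstsq(X, y, rcond=None)[0]
        resid = sg.residualize_nuisance(y, design)
        np.testing.assert_allclose(resid, y, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, small_cohort):
        design = sg.build_covariates(small_cohort, include_motion=True)
        rng = np.random.default_rng(3)
        y = 2.0 * design["age"].to_numpy() + rng.standard_normal(
            small_cohort.n_subjects
        )
        resid = sg.residualize_nuisance(y, design)
        assert np.max(np.abs(design.to_numpy().T @ resid)) < 1e-8

    def test_noise_variance_recovered(self):
        c = sg.simulate_twin_cohort(0, 0, 0, 3000, seed=4)
        design = sg.build_covariates(c, terms=("age", "sex"))
        rng = np.random.default_rng(4)
        noise = rng.standard_normal(c.n_subjects)
        y = 2.0 * design["age"].to_numpy() + noise
        resid = sg.residualize_nuisance(y, design)
        assert resid.var() == pytest.approx(noise.var(), rel=0.05)

    def test_collinear_design_rejected(self, small_cohort):
        design = sg.build_covariates(small_cohort)
        dup = design.copy()
        dup["age_copy"] = dup["age"]
        with pytest.raises(ValueError):
            sg.residualize_nuisance(
                np.zeros(small_cohort.n_subjects), dup
            )


class TestFitACE:
    def test_recovery_and_falconer_agreement(self, big_pair_cohort):
        g = sg.make_geometry((2, 1, 1), 2, seed=0)
        prof = sg.ACEProfile.constant(0.5, 0.2, 2)
        m = sg.simulate_heritable_maps(big_pair_cohort, g, prof, seed=170)
        fit = sg.fit_ace(m.values[:, 0], big_pair_cohort)
        assert fit.h2 == pytest.approx(0.5, abs=0.08)
        assert fit.h2 + fit.c2 + fit.e2 == pytest.approx(1.0, abs=1e-10)
        falconer_a = _falconer(m.values[:, 0], big_pair_cohort)
        assert fit.var_a == pytest.approx(falconer_a, abs=0.05)

    def test_null_phenotype_estimates_near_zero(self, big_pair_cohort):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(big_pair_cohort.n_subjects)
        fit = sg.fit_ace(y, big_pair_cohort)
        assert fit.h2 < 0.05

    def test_unbiased_at_interior_parameters(self):
        # mean of h2-hat over replicate simulations at a2 = 0.4
        c = sg.simulate_twin_cohort(500, 500, 0, 0, seed=6)
        g = sg.make_geometry((2, 1, 1), 2, seed=0)
        prof = sg.ACEProfile.constant(0.4, 0.1, 2)
        n_sims = 200
        maps = sg.simulate_heritable_maps(
            c,
            sg.make_geometry((n_sims, 1, 1), 2, seed=0),
            sg.ACEProfile.constant(0.4, 0.1, n_sims),
            seed=66,
        )
        model = ACEModel().fit(maps.values, c)
        assert model.h2_.mean() == pytest.approx(0.4, abs=0.03)
        np.testing.assert_allclose(model.h2_ + model.c2_ + model.e2_, 1.0,
                                   atol=1e-10)

    def test_constant_phenotype_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="variance"):
            sg.fit_ace(np.ones(small_cohort.n_subjects), small_cohort)

    def test_pair_floor_enforced(self):
        c = sg.simulate_twin_cohort(5, 5, 0, 0, seed=7)
        with pytest.raises(ValueError, match="pairs"):
            sg.fit_ace(np.arange(c.n_subjects, dtype=float), c)

    def test_sib_pairs_pool_with_dz(self):
        c = sg.simulate_twin_cohort(60, 0, 60, 0, seed=8)
        g = sg.make_geometry((2, 1, 1), 2, seed=0)
        prof = sg.ACEProfile.constant(0.6, 0.0, 2)
        m = sg.simulate_heritable_maps(c, g, prof, seed=8)
        fit = sg.fit_ace(m.values[:, 0], c)
        assert 0.0 <= fit.h2 <= 1.0


class TestFamilySubsample:
    def test_deterministic_and_shaped(self, small_geometry):
        c = sg.simulate_twin_cohort(30, 30, 0, 0, seed=9)
        prof = sg.ACEProfile.constant(0.5, 0.1, small_geometry.n_voxels)
        m = sg.simulate_heritable_maps(c, small_geometry, prof, seed=9)
        labels = small_geometry.network_labels
        kw = dict(n_reps=3, seed=1, min_pairs=5)
        a = sg.family_subsample_distribution(m, c, labels, **kw)
        b = sg.family_subsample_distribution(m, c, labels, **kw)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (3, 7)

    def test_too_few_families_rejected(self, line_geometry):
        c = sg.simulate_twin_cohort(1, 1, 0, 0, seed=10)
        prof = sg.ACEProfile.constant(0.5, 0.1, line_geometry.n_voxels)
        m = sg.simulate_heritable_maps(c, line_geometry, prof, seed=10)
        with pytest.raises(ValueError):
            sg.family_subsample_distribution(
                m, c, line_geometry.network_labels, n_reps=2, seed=1
            )


class TestNetworkContrast:
    def test_constant_input_gives_zero_statistics(self):
        out = sg.network_contrast(np.full((10, 7), 0.3), [1, 2], [4, 5, 6, 7])
        assert out["F_stat"] == 0.0 and out["t_stat"] == 0.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(11)
        boot = rng.normal(0.2, 0.01, size=(1000, 7))
        boot[:, 3:] += 0.1
        out = sg.network_contrast(boot, [1, 2], [4, 5, 6, 7])
        assert out["p_t"] < 1e-6 and out["t_stat"] > 0

    def test_null_p_values_uniform(self):
        # under exchangeable columns the t-test p is uniform across seeds
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            boot = rng.normal(0.2, 0.02, size=(40, 7))
            ps.append(sg.network_contrast(boot, [1, 2], [4, 5, 6, 7])["p_t"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBivariateACE:
    def test_identical_traits_unit_rg(self, small_cohort):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(small_cohort.n_subjects)
        fit = sg.fit_bivariate_ace(x, x, small_cohort, min_pairs=5)
        assert fit.rg == pytest.approx(1.0, abs=1e-6)
        fit_neg = sg.fit_bivariate_ace(x, -x, small_cohort, min_pairs=5)
        assert fit_neg.rg == pytest.approx(-1.0, abs=1e-6)

    def test_rg_arithmetic_identity(self):
        assert sg.genetic_correlation(0.3, 0.36, 0.25) == pytest.approx(1.0)

    def test_fit_satisfies_rg_identity(self):
        c = sg.simulate_twin_cohort(300, 300, 0, 0, seed=13)
        x, y = sg.simulate_coupled_traits(c, 0.6, 0.5, 0.4, seed=13)
        fit = sg.fit_bivariate_ace(x.values[:, 0], y.values[:, 0], c)
        assert fit.rg == pytest.approx(
            sg.genetic_correlation(fit.h_xy, fit.h2_x, fit.h2_y), abs=1e-6
        )
        assert abs(fit.rg) <= 1 + 1e-8

    def test_zero_rg_recovered(self):
        c = sg.simulate_twin_cohort(3000, 3000, 0, 0, seed=5)
        x, y = sg.simulate_coupled_traits(c, 0.5, 0.4, 0.0, seed=5)
        fit = sg.fit_bivariate_ace(x.values[:, 0], y.values[:, 0], c)
        assert abs(fit.rg) < 0.1

    def test_psd_blocks(self):
        c = sg.simulate_twin_cohort(300, 300, 0, 0, seed=14)
        x, y = sg.simulate_coupled_traits(c, 0.5, 0.5, -0.6, seed=14)
        fit = sg.fit_bivariate_ace(x.values[:, 0], y.values[:, 0], c)
        for block in (fit.genetic_cov, fit.common_cov, fit.unique_cov):
            assert np.min(np.linalg.eigvalsh(block)) >= -1e-10
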