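"""Generators: geometry, cohorts, heritable phenotypes, coupled traits."""

import io

import numpy as np
import pytest

import subgrad as sg


class TestMakeGeometry:
    def test_line_axis_and_slab_labels(self, line_geometry):
        g = line_geometry
        np.testing.assert_allclose(g.hierarchy_axis, [0, 1 / 3, 2 / 3, 1])
        np.testing.assert_array_equal(g.network_labels, [1, 1, 2, 2])

    def test_single_voxel_rejected(self):
        with pytest.raises(ValueError):
            sg.make_geometry((1, 1, 1), 2, seed=0)

    def test_seed_determinism(self):
        a = sg.make_geometry((10, 10, 10), 7, seed=1)
        b = sg.make_geometry((10, 10, 10), 7, seed=1)
        np.testing.assert_array_equal(a.network_labels, b.network_labels)
        np.testing.assert_array_equal(a.hierarchy_axis, b.hierarchy_axis)
        np.testing.assert_array_equal(
            a.cortical_network_labels, b.cortical_network_labels
        )

    def test_axis_monotone_and_labels_contiguous(self, small_geometry):
        g = small_geometry
        order = np.argsort(g.voxel_coords[:, 0], kind="stable")
        axis_sorted = g.hierarchy_axis[order]
        assert np.all(np.diff(axis_sorted) >= 0)
        # slab labels are non-decreasing along the axis
        lab_by_axis = g.network_labels[np.argsort(g.hierarchy_axis, kind="stable")]
        assert np.all(np.diff(lab_by_axis) >= 0)
        assert set(g.cortical_network_labels) == set(range(1, 8))

    def test_mm_coords_are_affine_image(self, small_geometry):
        g = small_geometry
        np.testing.assert_allclose(g.coords_mm, g.voxel_coords * 2.0)


class TestSimulateTwinCohort:
    def test_pair_structure(self):
        c = sg.simulate_twin_cohort(1, 1, 0, 0, seed=1)
        assert c.n_subjects == 4
        assert c.table["family_id"].nunique() == 2
        assert sorted(c.table["zygosity"]) == ["DZ", "DZ", "MZ", "MZ"]
        for zyg in ("MZ", "DZ"):
            i, j = c.pairs(zyg)[0]
            assert c.table.loc[i, "age"] == c.table.loc[j, "age"]

    def test_singletons_only(self):
        c = sg.simulate_twin_cohort(0, 0, 0, 3, seed=1)
        assert c.n_subjects == 3
        assert c.table["family_id"].nunique() == 3

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            sg.simulate_twin_cohort(0, 0, 0, 0, seed=1)

    def test_byte_identical_rerun(self):
        bufs = []
        for _ in range(2):
            c = sg.simulate_twin_cohort(125, 74, 0, 0, seed=7)
            assert c.n_subjects == 398
            buf = io.StringIO()
            c.to_csv(buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]


class TestSimulateHeritableMaps:
    def test_pure_genetic_maps_identical_within_mz(self, small_geometry):
        c = sg.simulate_twin_cohort(20, 20, 0, 0, seed=2)
        prof = sg.ACEProfile.constant(1.0, 0.0, small_geometry.n_voxels)
        m = sg.simulate_heritable_maps(c, small_geometry, prof, seed=2)
        for i, j in c.pairs("MZ"):
            np.testing.assert_allclose(m.values[i], m.values[j])

    def test_pure_environment_uncorrelated_within_mz(self, line_geometry):
        c = sg.simulate_twin_cohort(2000, 0, 0, 0, seed=3)
        prof = sg.ACEProfile.constant(0.0, 0.0, line_geometry.n_voxels)
        m = sg.simulate_heritable_maps(c, line_geometry, prof, seed=3)
        p = c.pairs("MZ")
        r = np.corrcoef(m.values[p[:, 0], 0], m.values[p[:, 1], 0])[0, 1]
        assert abs(r) < 0.05

    def test_twin_correlations_match_ace_expectation(self, line_geometry):
        c = sg.simulate_twin_cohort(5000, 5000, 0, 0, seed=11)
        prof = sg.ACEProfile.constant(0.5, 0.2, line_geometry.n_voxels)
        m = sg.simulate_heritable_maps(c, line_geometry, prof, seed=11)
        for zyg, expect in (("MZ", 0.7), ("DZ", 0.45)):
            p = c.pairs(zyg)
            for v in range(line_geometry.n_voxels):
                r = np.corrcoef(m.values[p[:, 0], v], m.values[p[:, 1], v])[0, 1]
                assert abs(r - expect) < 0.03
        assert np.all(np.abs(m.values.var(axis=0) - 1.0) < 0.05)

    def test_invalid_profile_rejected(self, line_geometry):
        with pytest.raises(ValueError):
            sg.ACEProfile(
                a2=np.full(4, 0.5), c2=np.full(4, 0.5), e2=np.full(4, 0.5)
            )

    def test_seed_determinism_and_sensitivity(self, line_geometry, small_cohort):
        prof = sg.ACEProfile.constant(0.4, 0.1, line_geometry.n_voxels)
        a = sg.simulate_heritable_maps(small_cohort, line_geometry, prof, seed=5)
        b = sg.simulate_heritable_maps(small_cohort, line_geometry, prof, seed=5)
        d = sg.simulate_heritable_maps(small_cohort, line_geometry, prof, seed=6)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, d.values)

    def test_standardize_exact_moments(self, line_geometry, small_cohort):
        prof = sg.ACEProfile.constant(0.4, 0.1, line_geometry.n_voxels)
        m = sg.simulate_heritable_maps(small_cohort, line_geometry, prof, seed=5)
        z = m.standardize()
        assert z.standardized
        assert np.max(np.abs(z.values.mean(axis=0))) < 1e-8
        assert np.max(np.abs(z.values.var(axis=0) - 1.0)) < 1e-8


class TestSimulateTimeseries:
    def test_too_few_timepoints_rejected(self, line_geometry, small_cohort):
        with pytest.raises(ValueError):
            sg.simulate_timeseries(
                small_cohort, line_geometry, timepoints=5,
                coupling_strength=1.0, noise_sd=0.1, heritable_shift=0.0, seed=1,
            )

    def test_seed_determinism(self, line_geometry):
        c = sg.simulate_twin_cohort(1, 1, 0, 0, seed=1)
        kw = dict(timepoints=20, coupling_strength=1.0, noise_sd=0.2,
                  heritable_shift=0.1)
        a = sg.simulate_timeseries(c, line_geometry, seed=4, **kw)
        b = sg.simulate_timeseries(c, line_geometry, seed=4, **kw)
        np.testing.assert_array_equal(a.voxel_ts, b.voxel_ts)
        np.testing.assert_array_equal(a.roi_ts, b.roi_ts)

    def test_zero_coupling_gives_noise_fc_without_crashing(self, small_geometry):
        c = sg.simulate_twin_cohort(1, 1, 0, 0, seed=2)
        ts = sg.simulate_timeseries(
            c, small_geometry, timepoints=60, coupling_strength=0.0,
            noise_sd=1.0, heritable_shift=0.0, seed=2,
        )
        fc = sg.compute_fc(ts.voxel_ts[0], ts.roi_ts[0])
        assert abs(fc.values.mean()) < 0.05


class TestSimulateCoupledTraits:
    def test_perfect_genetic_overlap_gives_identical_traits(self, small_cohort):
        x, y = sg.simulate_coupled_traits(small_cohort, 1.0, 1.0, 1.0, seed=4)
        np.testing.assert_allclose(x.values, y.values)

    def test_out_of_range_rg_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            sg.simulate_coupled_traits(small_cohort, 0.5, 0.5, 1.5, seed=4)

    def test_genetic_cross_twin_covariance_carries_rg(self):
        # cov(x_twin1, y_twin2) = rho_g * rg * sqrt(h2x h2y) in this design
        c = sg.simulate_twin_cohort(4000, 0, 0, 0, seed=5)
        x, y = sg.simulate_coupled_traits(c, 0.5, 0.4, 0.7, seed=5)
        p = c.pairs("MZ")
        cross = np.cov(x.values[p[:, 0], 0], y.values[p[:, 1], 0])[0, 1]
        assert abs(cross - 0.7 * np.sqrt(0.5 * 0.4)) < 0.05


def test_smooth_random_map_is_standardized_and_deterministic(small_geometry):
    a = sg.smooth_random_map(small_geometry, 3.0, seed=1)
    b = sg.smooth_random_map(small_geometry, 3.0, seed=1)
    np.testing.assert_array_equal(a, b)
    assert abs(a.mean()) < 1e-12 and abs(a.std() - 1.0) < 1e-12
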