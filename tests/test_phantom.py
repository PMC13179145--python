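"""Phantom geometry, signal model, noise, cohorts and grading surrogate."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

import ivdquant as iq
from ivdquant.phantom import (
    ConfigurationError,
    DiscSpec,
    superellipse_area_mm2,
    superellipse_chord_mean_factor,
    DISC_EXPONENT,
)


def one_level_spec(**overrides):
    spec = iq.PhantomSpec(
        grid_shape=(64, 64), spacing_mm=(1.0, 1.0),
        discs={"L5/S1": DiscSpec(
            center_px=(32, 32), width_mm=30.0, height_mm=10.0,
            slice_first=2, slice_last=4,
        )},
        region_t2_ms={"L5/S1": (40.0, 90.0, 100.0, 90.0, 40.0)},
        vertebra_heights_mm={}, vertebra_centers_px={},
        **overrides,
    )
    return spec


class TestGeometry:
    def test_one_level_polygons_have_requested_extent(self):
        spec = one_level_spec()
        geo = iq.make_disc_geometry(spec)
        assert geo.slices["L5/S1"] == [2, 3, 4]
        minx, _, maxx, _ = geo.polygons["L5/S1"].bounds
        assert (maxx - minx) * spec.spacing_mm[1] == pytest.approx(30.0, abs=1.0)

    def test_zero_slice_extent_rejected(self):
        spec = one_level_spec()
        spec.discs["L5/S1"].slice_last = 1  # < slice_first
        with pytest.raises(ConfigurationError, match="slice extent"):
            iq.make_disc_geometry(spec)

    def test_geometry_exceeding_grid_names_level(self):
        spec = one_level_spec()
        spec.discs["L5/S1"].width_mm = 200.0
        with pytest.raises(ConfigurationError, match="L5/S1"):
            iq.make_disc_geometry(spec)

    def test_default_seven_levels_disjoint(self, default_spec, default_geometry):
        levels = list(default_geometry.polygons)
        assert len(levels) == 7
        # brute-force pairwise intersection check
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                inter = default_geometry.polygons[a].intersection(
                    default_geometry.polygons[b]
                )
                assert inter.area == 0.0

    def test_rasterized_area_matches_analytic_within_boundary_row(
        self, default_spec, default_geometry
    ):
        for level, mask in default_geometry.masks.items():
            analytic = default_geometry.analytic_area_mm2[level]
            poly = default_geometry.polygons[level]
            boundary_row = poly.length * max(default_spec.spacing_mm)
            assert abs(mask.area_mm2 - analytic) < boundary_row


class TestSignalModel:
    def test_noiseless_voxels_match_closed_form(self):
        spec = one_level_spec()
        stack, truth = iq.simulate_multiecho(spec)
        geo = iq.make_disc_geometry(spec)
        part = geo.partitions["L5/S1"]
        te = stack.echo_times_ms
        for region, t2 in zip(range(1, 6), (40.0, 90.0, 100.0, 90.0, 40.0)):
            sel = part == region
            vals = stack.data[3][sel, :]
            expected = 1000.0 * np.exp(-te / t2)
            assert np.allclose(vals, expected[None, :], rtol=1e-12)

    def test_first_echo_value_closed_form(self):
        spec = one_level_spec()
        spec.region_t2_ms = {"L5/S1": (100.0,) * 5}
        stack, _ = iq.simulate_multiecho(spec)
        geo = iq.make_disc_geometry(spec)
        inside = geo.masks["L5/S1"].mask
        assert stack.data[2][inside, 0] == pytest.approx(
            1000.0 * np.exp(-0.1575), abs=1e-9
        )

    def test_seed_determinism_and_divergence(self):
        kw = dict(noise_model="gaussian", noise_sigma=5.0)
        a1, _ = iq.simulate_multiecho(one_level_spec(seed=7, **kw))
        a2, _ = iq.simulate_multiecho(one_level_spec(seed=7, **kw))
        b, _ = iq.simulate_multiecho(one_level_spec(seed=8, **kw))
        assert np.array_equal(a1.data, a2.data)
        assert not np.array_equal(a1.data, b.data)

    def test_gaussian_noise_region_means_converge(self):
        spec = one_level_spec(noise_model="gaussian", noise_sigma=5.0, seed=5)
        stack, _ = iq.simulate_multiecho(spec)
        geo = iq.make_disc_geometry(spec)
        inside = geo.masks["L5/S1"].mask
        part = geo.partitions["L5/S1"]
        sel = part == 3  # central nucleus, T2=100
        n_vox = sel.sum() * 3  # 3 slices
        assert n_vox >= 100
        te = stack.echo_times_ms
        for e, t in enumerate(te):
            observed = np.mean([stack.data[s][sel, e] for s in (2, 3, 4)])
            expected = 1000.0 * np.exp(-t / 100.0)
            assert abs(observed - expected) < 3 * 5.0 / np.sqrt(n_vox)

    def test_fewer_than_three_echoes_rejected(self):
        spec = one_level_spec(echo_times_ms=(15.75, 36.75))
        with pytest.raises(ConfigurationError, match="3 echo times"):
            iq.simulate_multiecho(spec)


class TestT2w:
    def test_nucleus_and_annulus_intensities(self):
        spec = one_level_spec(nucleus_intensity=200.0, annulus_intensity=100.0)
        geo = iq.make_disc_geometry(spec)
        stack = iq.simulate_t2w(spec, geo)
        part = geo.partitions["L5/S1"]
        img = stack.data[3, :, :, 0]
        assert np.all(img[np.isin(part, (2, 3, 4))] == 200.0)
        assert np.all(img[np.isin(part, (1, 5))] == 100.0)

    def test_equal_intensities_give_uniform_disc(self):
        spec = one_level_spec(nucleus_intensity=150.0, annulus_intensity=150.0)
        geo = iq.make_disc_geometry(spec)
        stack = iq.simulate_t2w(spec, geo)
        inside = geo.masks["L5/S1"].mask
        assert np.all(stack.data[3][inside, 0] == 150.0)

    def test_negative_intensity_rejected(self):
        spec = one_level_spec(nucleus_intensity=-5.0)
        with pytest.raises(ConfigurationError, match="intensities"):
            iq.simulate_t2w(spec)

    def test_rician_noise_sd_in_bright_regions(self):
        spec = one_level_spec(
            noise_model="rician", noise_sigma=2.0, seed=9,
            nucleus_intensity=200.0, annulus_intensity=100.0,
        )
        geo = iq.make_disc_geometry(spec)
        stack = iq.simulate_t2w(spec, geo)
        part = geo.partitions["L5/S1"]
        sel = np.isin(part, (2, 3, 4))
        vals = np.concatenate([stack.data[s][sel, 0] for s in (2, 3, 4)])
        # at SNR 100 the Rician magnitude is ~Gaussian with the channel SD
        assert vals.std() == pytest.approx(2.0, rel=0.15)


class TestVertebral:
    def test_truth_heights_recorded(self, default_spec):
        stack, traces, heights = iq.simulate_vertebral(default_spec)
        assert heights["L5"] == pytest.approx(27.0)
        assert any(t.level == "S1" for t in traces)

    def test_height_ratio_expectation(self):
        assert iq.height_ratio(10.0, 28.0) == pytest.approx(10 / 28, abs=1e-6)

    def test_reproducible_with_seed(self, default_spec):
        s1, _, _ = iq.simulate_vertebral(default_spec)
        s2, _, _ = iq.simulate_vertebral(default_spec)
        assert np.array_equal(s1.data, s2.data)


class TestSuperellipse:
    def test_area_reduces_to_ellipse(self):
        # n=2 is an ellipse: A = pi a b
        assert superellipse_area_mm2(30.0, 10.0, 2.0) == pytest.approx(
            np.pi * 15 * 5, rel=1e-9
        )

    def test_chord_factor_full_axis_ellipse(self):
        # mean vertical chord of an ellipse over the full axis = (pi/4) h
        factor = superellipse_chord_mean_factor(2.0, k=20001, tail_fraction=0.0)
        assert factor == pytest.approx(np.pi / 4, abs=1e-4)


class TestPfirrmann:
    def test_extreme_bands(self):
        assert iq.assign_pfirrmann(150.0) == 1
        assert iq.assign_pfirrmann(20.0) == 5

    def test_monotone_over_t2_grid(self):
        t2 = np.linspace(150.0, 10.0, 300)  # decreasing hydration
        grades = iq.assign_pfirrmann(t2)
        assert np.all(np.diff(grades) >= 0)
        shuffled = np.random.default_rng(0).permutation(t2)
        regraded = iq.assign_pfirrmann(np.sort(shuffled)[::-1])
        assert np.array_equal(regraded, grades)

    def test_grades_in_range(self):
        grades = iq.assign_pfirrmann(np.linspace(1.0, 200.0, 100))
        assert set(np.unique(grades)) <= {1, 2, 3, 4, 5}


class TestCohort:
    def test_zero_beta_zero_noise_recovers_zero(self):
        cspec = iq.CohortSpec(seed=2, beta={}, covariate_effects={})
        cspec.residual_sd = {k: 0.0 for k in cspec.residual_sd}
        cohort, truth = iq.generate_cohort(cspec)
        merged = truth.merge(cohort, on="participant")
        tab = merged[merged["level"] == "L5/S1"]
        res = iq.fit_ols(tab["t2_ms"], tab["bpaq_total"])
        assert res.beta == pytest.approx(0.0, abs=1e-10)

    def test_planted_beta_recovered_exactly_without_noise(self):
        cspec = iq.CohortSpec(
            seed=3, beta={("t2", "L5/S1"): -0.3}, covariate_effects={}
        )
        cspec.residual_sd = {k: 0.0 for k in cspec.residual_sd}
        cohort, truth = iq.generate_cohort(cspec)
        merged = truth.merge(cohort, on="participant")
        tab = merged[merged["level"] == "L5/S1"]
        res = iq.fit_ols(tab["t2_ms"], tab["bpaq_total"])
        assert res.beta == pytest.approx(-0.30, abs=1e-9)
        other = merged[merged["level"] == "L1/L2"]
        res0 = iq.fit_ols(other["t2_ms"], other["bpaq_total"])
        assert res0.beta == pytest.approx(0.0, abs=1e-10)

    def test_bpaq_moments_converge_to_spec(self):
        from scipy.stats import truncnorm
        cspec = iq.CohortSpec(seed=4)
        cspec.male.n = cspec.female.n = 4000
        cohort, _ = iq.generate_cohort(cspec)
        male = cohort[cohort["sex"] == "male"]["bpaq_total"]
        loc, scale = 16.97, 17.66
        a = -loc / scale
        expected_mean = truncnorm.mean(a, np.inf, loc=loc, scale=scale)
        expected_sd = truncnorm.std(a, np.inf, loc=loc, scale=scale)
        se = expected_sd / np.sqrt(len(male))
        assert abs(male.mean() - expected_mean) < 3 * se
        assert abs(male.std() - expected_sd) < 3 * expected_sd / np.sqrt(
            2 * (len(male) - 1)
        )

    def test_scores_nonnegative_and_sex_recorded(self):
        cohort, truth = iq.generate_cohort(iq.CohortSpec(seed=5))
        assert (cohort["bpaq_total"] >= 0).all()
        assert set(cohort["sex"]) == {"male", "female"}
        assert len(truth) == len(cohort) * 7

    def test_nonpositive_n_rejected(self):
        cspec = iq.CohortSpec(seed=1)
        cspec.male.n = 0
        with pytest.raises(ConfigurationError, match="n must be > 0"):
            iq.generate_cohort(cspec)

    def test_determinism(self):
        c1, t1 = iq.generate_cohort(iq.CohortSpec(seed=6))
        c2, t2 = iq.generate_cohort(iq.CohortSpec(seed=6))
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_ci_coverage_of_planted_effect(self):
        # planted L5/S1 effect; nominal-level CI coverage over replicates
        hits = 0
        n_rep = 300
        for rep in range(n_rep):
            cspec = iq.CohortSpec(
                seed=10_000 + rep,
                beta={("t2", "L5/S1"): -0.3},
                covariate_effects={},
            )
            cohort, truth = iq.generate_cohort(cspec)
            merged = truth.merge(cohort, on="participant")
            tab = merged[merged["level"] == "L5/S1"]
            res = iq.fit_ols(tab["t2_ms"], tab["bpaq_total"])
            if res.ci_low <= -0.3 <= res.ci_high:
                hits += 1
        # 3 sigma band around 0.95 for 300 replicates
        assert abs(hits / n_rep - 0.95) < 3 * np.sqrt(0.95 * 0.05 / n_rep)


class TestGroundTruthLedger:
    def test_volume_consistent_with_areas(self, noiseless_stack):
        _, truth = noiseless_stack
        for level, lt in truth.levels.items():
            expected = sum(lt.slice_areas_mm2) * 4.5 / 1000.0
            assert lt.volume_cm3 == pytest.approx(expected, rel=1e-12)

    def test_grades_in_ledger_valid(self, noiseless_stack):
        _, truth = noiseless_stack
        assert all(1 <= lt.pfirrmann <= 5 for lt in truth.levels.values())

    def test_truth_frame_has_all_levels(self, noiseless_stack):
        _, truth = noiseless_stack
        frame = truth.to_frame()
        assert set(frame["level"]) == set(iq.LEVELS)
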