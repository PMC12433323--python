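"""Gompertz growth law, cohort generation, histology counts."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares

import xenogrowth as xg
from xenogrowth.errors import ValidationError
from xenogrowth.synthetic_data import (
    DEFAULT_SCHEDULE,
    CohortDesign,
    StrainGrowthParams,
    generate_cohort,
    generate_histology,
    growth_trajectory,
    preset,
    selected_cohort_design,
)


def noiseless(name):
    return preset(name, aspect_sd=0.0, noise_cv=0.0, effect_cv=0.0)


class TestGrowthTrajectory:
    def test_inflection_identity(self):
        p = preset("nsg")
        assert growth_trajectory(p, p.lag) == pytest.approx(p.v_max / math.e, rel=1e-12)

    def test_asymptote(self):
        p = preset("nsg")
        t_far = p.lag + 15 / p.k
        assert growth_trajectory(p, t_far) == pytest.approx(p.v_max, rel=1e-6)

    def test_numerical_derivative_at_inflection(self):
        p = preset("nsgs")
        h = 1e-6
        num = (growth_trajectory(p, p.lag + h) - growth_trajectory(p, p.lag - h)) / (2 * h)
        assert num == pytest.approx(p.k * p.v_max / math.e, rel=1e-6)

    def test_strictly_increasing_and_sigmoidal(self):
        for name in ("nsg", "nsgs", "nude"):
            p = preset(name)
            t = np.linspace(0, 60, 400)
            v = growth_trajectory(p, t)
            assert (np.diff(v) > 0).all()
            # slow early phase, then accelerating growth after day 20
            assert growth_trajectory(p, 15) < 0.3 * growth_trajectory(p, 41)
            assert growth_trajectory(p, 25) - growth_trajectory(p, 20) > (
                growth_trajectory(p, 15) - growth_trajectory(p, 10)
            )

    def test_measurement_start_anchor(self):
        for name in ("nsg", "nsgs", "nude"):
            assert growth_trajectory(preset(name), 10) == pytest.approx(0.05, rel=1e-10)

    def test_presets_hit_calibration_volumes(self):
        for name, target in (("nsg", 0.80), ("nsgs", 0.51), ("nude", 0.40)):
            assert growth_trajectory(preset(name), 41) == pytest.approx(target, rel=1e-12)

    def test_preset_ordering_after_day_30(self):
        t = np.linspace(30, 41, 23)
        v_nsg = growth_trajectory(preset("nsg"), t)
        v_nsgs = growth_trajectory(preset("nsgs"), t)
        v_nude = growth_trajectory(preset("nude"), t)
        assert (v_nsg > v_nsgs).all() and (v_nsgs > v_nude).all()

    def test_parameter_recovery_from_noiseless_trajectory(self):
        truth = preset("nsg")
        days = np.asarray(DEFAULT_SCHEDULE, float)
        v = growth_trajectory(truth, days)

        def resid(theta):
            vm, k, lag = theta
            return np.log(vm) - np.exp(-k * (days - lag)) - np.log(v)

        sol = least_squares(resid, x0=[1.0, 0.05, 30.0], method="lm")
        assert sol.x[0] == pytest.approx(truth.v_max, rel=1e-4)
        assert sol.x[1] == pytest.approx(truth.k, rel=1e-4)
        assert sol.x[2] == pytest.approx(truth.lag, rel=1e-4)


class TestGenerateCohort:
    def test_noiseless_roundtrip_exact(self):
        design = CohortDesign(strains=(noiseless("nsg"),), seed=1, n_mice_per_strain=1)
        table = generate_cohort(design)
        sizes = xg.measurements_to_sizes(table)
        expected = growth_trajectory(noiseless("nsg"), sizes["day"].to_numpy(float))
        np.testing.assert_allclose(sizes["volume_cm3"], expected, rtol=1e-12)

    def test_same_seed_identical_tables(self):
        d = xg.default_design(seed=9)
        pd.testing.assert_frame_equal(generate_cohort(d), generate_cohort(d))

    def test_different_seeds_differ(self):
        t1 = generate_cohort(xg.default_design(seed=1))
        t2 = generate_cohort(xg.default_design(seed=2))
        assert not t1[["a_cm", "b_cm", "c_cm"]].equals(t2[["a_cm", "b_cm", "c_cm"]])

    def test_schema_and_row_count(self, tested_cohort):
        assert list(tested_cohort.columns) == list(xg.geometry.CALIPER_COLUMNS)
        assert len(tested_cohort) == 3 * 2 * len(DEFAULT_SCHEDULE)
        xg.geometry.validate_caliper_table(tested_cohort)

    def test_large_sample_day41_mean_matches_analytic(self):
        # mean-one multiplicative noise at every stage keeps the expected
        # reconstructed volume equal to the Gompertz mean
        design = CohortDesign(
            strains=(preset("nsg"),), seed=4, n_mice_per_strain=1000,
            schedule=(38, 41),
        )
        sizes = xg.measurements_to_sizes(generate_cohort(design))
        day41 = sizes[sizes.day == 41]["volume_cm3"]
        se = day41.std(ddof=1) / np.sqrt(len(day41))
        assert day41.mean() == pytest.approx(0.80, abs=3 * se)

    def test_group_assignment_staggered(self):
        design = selected_cohort_design(seed=6)
        table = generate_cohort(design)
        counts = table.groupby("group")["mouse_id"].nunique()
        assert sorted(counts) == [8] * 6
        assert table["strain"].eq("nsg").all()

    def test_group_sizes_must_sum(self):
        with pytest.raises(ValidationError, match="sum"):
            CohortDesign(strains=(preset("nsg"),), seed=1, n_mice_per_strain=4,
                         group_sizes=(3, 3))

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValidationError, match="schedule"):
            CohortDesign(strains=(preset("nsg"),), seed=1, schedule=())


class TestGenerateHistology:
    def test_extreme_probabilities(self):
        zero = generate_histology(20, 500, 0.0, 1.0, seed=3)
        control = zero[zero.treatment == "0W"]
        treated = zero[zero.treatment == "30W"]
        assert (control.n_strong_positive == 0).all()
        assert (treated.n_strong_positive == treated.n_total).all()

    def test_pooled_fraction_near_planted(self):
        df = generate_histology(200, 1000, 0.17, 0.31, seed=8)
        control = df[df.treatment == "0W"]
        pooled = control.n_strong_positive.sum() / control.n_total.sum()
        tol = 3 * np.sqrt(0.17 * 0.83 / control.n_total.sum())
        assert pooled == pytest.approx(0.17, abs=tol)

    def test_determinism_and_validity(self):
        d1 = generate_histology(30, 800, 0.2, 0.4, seed=11)
        d2 = generate_histology(30, 800, 0.2, 0.4, seed=11)
        pd.testing.assert_frame_equal(d1, d2)
        assert (d1.n_strong_positive <= d1.n_total).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationError):
            generate_histology(10, 100, -0.1, 0.5, seed=1)


class TestPipelineRoundTrip:
    def test_spline_recovers_noiseless_gompertz_within_2_percent(self):
        design = CohortDesign(
            strains=tuple(noiseless(s) for s in ("nsg", "nsgs", "nude")), seed=2
        )
        sizes = xg.measurements_to_sizes(generate_cohort(design))
        grid = np.linspace(12, 40, 57)
        for name in ("nsg", "nsgs", "nude"):
            fit = xg.fit_spline(xg.GrowthSeries.from_sizes(sizes, name, "volume"))
            fitted = xg.evaluate(fit, grid)
            truth = growth_trajectory(noiseless(name), grid)
            rel = np.abs(fitted - truth) / truth
            assert rel.max() <= 0.02, (name, rel.max())
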