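"""Apoptotic index (Nsr), top-k hot-spot averaging, tiling, arm comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import xenogrowth as xg
from xenogrowth.apoptosis import (
    percent_increase,
    region_nsr,
    tile_section,
    top_k_index,
    treatment_report,
)
from xenogrowth.errors import ValidationError


def region_frame(nsrs, section_id="s1", treatment="0W", nt=1000):
    return pd.DataFrame(
        {
            "section_id": section_id,
            "region_id": [f"r{i:02d}" for i in range(len(nsrs))],
            "treatment": treatment,
            "n_strong_positive": [int(round(x * nt)) for x in nsrs],
            "n_total": nt,
        }
    )


class TestRegionNsr:
    @pytest.mark.parametrize(
        "nsp,nt,expected", [(0, 500, 0.0), (170, 1000, 0.17), (31, 100, 0.31)]
    )
    def test_ratio(self, nsp, nt, expected):
        assert region_nsr(nsp, nt) == pytest.approx(expected)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            region_nsr(1, 0)
        with pytest.raises(ValidationError):
            region_nsr(5, 4)


class TestTopKIndex:
    def test_top_three_of_four(self):
        idx = top_k_index(region_frame([0.1, 0.2, 0.3, 0.4]), k=3)
        assert idx.nsr_top_k_mean == pytest.approx(0.3)
        assert set(idx.region_ids_used) == {"r01", "r02", "r03"}

    def test_fewer_regions_than_k_warns_and_uses_all(self):
        with pytest.warns(UserWarning, match="only 2"):
            idx = top_k_index(region_frame([0.1, 0.3]), k=3)
        assert idx.nsr_top_k_mean == pytest.approx(0.2)
        assert len(idx.region_ids_used) == 2

    def test_all_equal(self):
        idx = top_k_index(region_frame([0.25] * 5), k=3)
        assert idx.nsr_top_k_mean == pytest.approx(0.25)

    def test_permutation_invariance(self, rng):
        nsrs = list(rng.uniform(0, 0.5, size=8))
        base = top_k_index(region_frame(nsrs), k=3).nsr_top_k_mean
        perm = [nsrs[i] for i in rng.permutation(8)]
        df = region_frame(perm)
        df["region_id"] = [f"q{i}" for i in rng.permutation(8)]
        assert top_k_index(df, k=3).nsr_top_k_mean == pytest.approx(base)

    @settings(deadline=None, max_examples=40)
    @given(
        counts=st.lists(st.integers(0, 100), min_size=3, max_size=8),
        bump=st.integers(1, 50),
        which=st.integers(0, 7),
    )
    def test_monotone_in_any_region_count(self, counts, bump, which):
        which %= len(counts)
        nt = 100
        df = region_frame([c / nt for c in counts], nt=nt)
        before = top_k_index(df, k=3).nsr_top_k_mean
        df2 = df.copy()
        df2.loc[which, "n_strong_positive"] = min(counts[which] + bump, nt)
        after = top_k_index(df2, k=3).nsr_top_k_mean
        assert after >= before - 1e-12

    def test_empty_regions_excluded_with_warning(self):
        df = region_frame([0.1, 0.2, 0.3])
        df.loc[3] = ["s1", "r99", "0W", 0, 0]
        with pytest.warns(UserWarning, match="Nt = 0"):
            idx = top_k_index(df, k=3)
        assert idx.nsr_top_k_mean == pytest.approx(0.2)

    def test_no_valid_regions_rejected(self):
        df = region_frame([])
        with pytest.raises(ValidationError):
            top_k_index(df, k=3)


class TestPercentIncrease:
    def test_study_worked_example(self):
        raw, rounded = percent_increase(0.17, 0.31)
        assert rounded == 82
        assert raw == pytest.approx(82.3529, abs=1e-3)

    def test_no_change_and_decrease(self):
        assert percent_increase(0.25, 0.25)[1] == 0
        assert percent_increase(0.20, 0.10)[1] == -50

    def test_zero_control_rejected(self):
        with pytest.raises(ValidationError):
            percent_increase(0.0, 0.3)


class TestTileSection:
    def test_exact_tiling(self):
        grid = tile_section((1000, 1000), (500, 500))
        assert len(grid) == 4
        assert not grid["partial"].any()

    def test_partial_edge_regions_flagged(self):
        grid = tile_section((1000, 750), (500, 500))
        assert len(grid) == 4
        assert grid["partial"].sum() == 2
        # clipped heights on the partial row
        partial = grid[grid["partial"]]
        assert ((partial["y1"] - partial["y0"]) == 250).all()

    def test_single_region(self):
        grid = tile_section((500, 500), (500, 500))
        assert len(grid) == 1 and not grid["partial"].iloc[0]

    def test_region_larger_than_section_rejected(self):
        with pytest.raises(ValidationError):
            tile_section((400, 400), (500, 500))

    def test_tiles_cover_section_without_overlap(self):
        grid = tile_section((1250, 980), (500, 500))
        area = ((grid["x1"] - grid["x0"]) * (grid["y1"] - grid["y0"])).sum()
        assert area == pytest.approx(1250 * 980)


class TestTreatmentReport:
    def test_two_arm_report_reproduces_planted_increase(self):
        control = region_frame([0.10, 0.15, 0.17, 0.17, 0.17], "sec-c", "0W")
        treated = region_frame([0.20, 0.25, 0.31, 0.31, 0.31], "sec-t", "30W")
        rep = treatment_report(pd.concat([control, treated]), control_label="0W")
        assert rep["index_by_treatment"]["0W"] == pytest.approx(0.17)
        assert rep["index_by_treatment"]["30W"] == pytest.approx(0.31)
        assert rep["percent_increase_vs_control"]["30W"]["percent"] == 82

    def test_three_arms_give_two_increases(self):
        arms = [
            region_frame([0.1, 0.1, 0.1], "s0", "0W"),
            region_frame([0.2, 0.2, 0.2], "s1", "15W"),
            region_frame([0.3, 0.3, 0.3], "s2", "30W"),
        ]
        rep = treatment_report(pd.concat(arms), control_label="0W")
        assert set(rep["percent_increase_vs_control"]) == {"15W", "30W"}
        assert rep["percent_increase_vs_control"]["30W"]["percent"] == 200

    def test_single_arm_warns_without_increase(self):
        with pytest.warns(UserWarning, match="single treatment arm"):
            rep = treatment_report(region_frame([0.1, 0.2, 0.3]), control_label="0W")
        assert rep["percent_increase_vs_control"] == {}

    def test_pipeline_recovers_planted_fractions(self):
        counts = xg.generate_histology(
            n_regions=60, cells_per_region=800,
            p_strong_control=0.17, p_strong_treated=0.31, seed=5,
        )
        rep = treatment_report(counts, control_label="0W")
        # top-3 of 60 binomial regions overshoots the planted p slightly;
        # binomial SE at Nt=800 is ~0.013 per region
        assert rep["index_by_treatment"]["0W"] == pytest.approx(0.17, abs=0.05)
        assert rep["index_by_treatment"]["30W"] == pytest.approx(0.31, abs=0.05)
        assert rep["index_by_treatment"]["30W"] > rep["index_by_treatment"]["0W"]
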