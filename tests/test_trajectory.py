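"""Baselines, distances, normalisation, AUCs and trajectory summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import resiliome as r
from resiliome.trajectory import (
    SubjectExcludedError,
    auc_standardised,
    compute_raw_distances,
    max_perturbation,
    max_resilience,
    normalise_distances,
)
from tests.conftest import make_distance_frame


class TestSelectBaseline:
    @pytest.mark.parametrize(
        "days,expected",
        [
            ([-15, -7, -1, 1, 4], -1),
            ([-15, -7, 1, 4], -7),
            ([-15, 1, 4], -15),
        ],
    )
    def test_preference_order(self, days, expected):
        assert r.select_baseline(days) == expected

    def test_no_pretreatment_sample_excludes_subject(self):
        with pytest.raises(SubjectExcludedError):
            r.select_baseline([1, 4, 10])


class TestScalarChange:
    def test_no_change(self):
        assert r.scalar_change(7.0, 7.0, "identity") == 0.0
        assert r.scalar_change(7.0, 7.0, "log10") == 0.0

    def test_tenfold_increase_is_plus_one_log(self):
        assert r.scalar_change(100.0, 10.0, "log10") == pytest.approx(1.0)

    def test_richness_change_on_natural_scale(self):
        assert r.scalar_change(300.0, 250.0, "identity") == 50.0

    def test_nonpositive_under_log_is_missing(self):
        assert math.isnan(r.scalar_change(0.0, 10.0, "log10"))


def brute_force_spearman(a, b):
    """Rank-enumeration Spearman for tie-free vectors (independent oracle)."""
    n = len(a)
    ra = [sorted(a).index(x) + 1 for x in a]
    rb = [sorted(b).index(x) + 1 for x in b]
    d2 = sum((x - y) ** 2 for x, y in zip(ra, rb))
    return 1 - 6 * d2 / (n * (n * n - 1))


class TestStructureDistance:
    def test_identical_profiles_have_zero_distance(self):
        p = pd.Series({"a": 1.0, "b": 2.0, "c": 5.0})
        s, d = r.structure_distance(p, p)
        assert s == pytest.approx(1.0)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_rank_reversal_also_has_zero_distance(self):
        a = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        b = pd.Series({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        s, d = r.structure_distance(a, b)
        assert s == pytest.approx(-1.0)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_matches_rank_enumeration_oracle(self):
        a = [10.0, 20.0, 30.0, 40.0]
        b = [40.0, 10.0, 20.0, 30.0]
        expected_s = brute_force_spearman(a, b)  # = -0.2
        idx = list("wxyz")
        s, d = r.structure_distance(pd.Series(a, idx), pd.Series(b, idx))
        assert s == pytest.approx(expected_s)
        assert d == pytest.approx(1 - expected_s**2)

    def test_shared_absences_are_excluded_from_support(self):
        a = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0, "z1": 0.0, "z2": 0.0})
        b = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "z1": 0.0, "z2": 0.0})
        s, _ = r.structure_distance(a, b)
        assert s == pytest.approx(-1.0)  # zeros would otherwise dilute the reversal

    def test_small_support_is_missing(self):
        a = pd.Series({"a": 1.0, "b": 2.0})
        s, d = r.structure_distance(a, a)
        assert math.isnan(s) and math.isnan(d)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        idx = [f"f{i}" for i in range(8)]
        a = pd.Series(rng.integers(0, 50, 8).astype(float), idx)
        b = pd.Series(rng.integers(0, 50, 8).astype(float), idx)
        s1, d1 = r.structure_distance(a, b)
        s2, d2 = r.structure_distance(b, a)
        if not math.isnan(s1):
            assert s1 == pytest.approx(s2)
            assert 0.0 <= d1 <= 1.0
            # strictly monotone transform fixing zero preserves ranks
            s3, d3 = r.structure_distance(a**1.7, b**1.7)
            assert s3 == pytest.approx(s1)
            assert d3 == pytest.approx(d1)


class TestAucStandardised:
    def test_null_normalised_series_equals_window_length(self):
        pts = pd.DataFrame(
            {
                "nominal_day": [1, 4, 10],
                "collection_time": [2.0, 5.0, 12.0],
                "value": [1.0, 1.0, 1.0],
            }
        )
        # constant 1 through an actual day-10 time of 12: raw 12, scaled to 10
        assert auc_standardised(pts, 10, "normalised_distance") == pytest.approx(10.0)

    def test_triangle_area_of_signed_changes(self):
        pts = pd.DataFrame(
            {
                "nominal_day": [4, 10],
                "collection_time": [5.0, 10.0],
                "value": [2.0, 0.0],
            }
        )
        assert auc_standardised(pts, 10, "signed_change") == pytest.approx(10.0)

    def test_hand_trapezoid_with_collection_delay(self):
        pts = pd.DataFrame(
            {
                "nominal_day": [2, 10],
                "collection_time": [2.0, 9.5],
                "value": [3.0, 1.0],
            }
        )
        # anchor 0 at t=0: trapezoids 3 + 15 = 18, standardised by 10/9.5
        assert auc_standardised(pts, 10, "signed_change") == pytest.approx(
            18 * 10 / 9.5
        )

    def test_window_restricts_points(self):
        pts = pd.DataFrame(
            {
                "nominal_day": [4, 30],
                "collection_time": [4.0, 30.0],
                "value": [1.0, 9.0],
            }
        )
        only_d4 = auc_standardised(pts, 10, "signed_change")
        assert only_d4 == pytest.approx((1.0 / 2 * 4.0) * 10 / 4.0)

    def test_empty_window_is_missing(self):
        pts = pd.DataFrame(
            {"nominal_day": [15], "collection_time": [15.0], "value": [1.0]}
        )
        assert math.isnan(auc_standardised(pts, 10, "signed_change"))


class TestExtremes:
    def test_max_perturbation_takes_window_max(self):
        df = make_distance_frame(
            [(1, 1.0, 0, 0, 0.5), (4, 4.0, 0, 0, 3.0), (7, 7.0, 0, 0, 1.0)]
        )
        assert max_perturbation(df) == 3.0

    def test_late_points_do_not_count_as_perturbation(self):
        df = make_distance_frame([(15, 15.0, 0, 0, 9.9)])
        assert math.isnan(max_perturbation(df))

    def test_all_equal_distances(self):
        df = make_distance_frame([(d, d, 0, 0, 0.7) for d in (1, 4, 10)])
        assert max_perturbation(df) == 0.7

    def test_max_resilience_takes_late_min(self):
        df = make_distance_frame(
            [(15, 15.0, 0, 0, 2.0), (30, 30.0, 0, 0, 0.8), (90, 90.0, 0, 0, 1.1)]
        )
        assert max_resilience(df) == 0.8

    def test_single_late_point(self):
        df = make_distance_frame([(90, 90.0, 0, 0, 1.4)])
        assert max_resilience(df) == 1.4

    def test_early_points_do_not_count_as_resilience(self):
        df = make_distance_frame([(10, 10.0, 0, 0, 0.1)])
        assert math.isnan(max_resilience(df))


def raw_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "variable",
            "nominal_day",
            "collection_time",
            "baseline_day",
            "change",
            "raw_distance",
        ],
    )


class TestNormalisation:
    def test_division_by_pretreatment_mean(self):
        raw = raw_frame(
            [
                ("s1", "v", -7, -7.0, -1, 2.0, 2.0),
                ("s1", "v", -15, -15.0, -1, -4.0, 4.0),
                ("s1", "v", 4, 4.0, -1, 6.0, 6.0),
            ]
        )
        out = normalise_distances(raw)
        d4 = out[out["nominal_day"] == 4].iloc[0]
        assert d4["normalised_distance"] == pytest.approx(2.0)
        assert d4["normaliser_source"] == "own_pretreatment"

    def test_cohort_median_fallback(self):
        rows = []
        for subj, div in (("s1", 1.0), ("s2", 2.0), ("s3", 3.0)):
            rows.append((subj, "v", -7, -7.0, -1, div, div))
            rows.append((subj, "v", 4, 4.0, -1, 5.0, 5.0))
        rows.append(("s4", "v", 4, 4.0, -1, 5.0, 5.0))  # no pre-treatment visits
        out = normalise_distances(raw_frame(rows))
        s4 = out[(out["subject_id"] == "s4") & (out["nominal_day"] == 4)].iloc[0]
        assert s4["normaliser"] == 2.0
        assert s4["normaliser_source"] == "cohort_median"
        assert s4["normalised_distance"] == pytest.approx(2.5)

    def test_zero_normaliser_gives_missing(self):
        raw = raw_frame(
            [
                ("s1", "v", -7, -7.0, -1, 0.0, 0.0),
                ("s1", "v", 4, 4.0, -1, 6.0, 6.0),
            ]
        )
        log = []
        out = normalise_distances(raw, log=log)
        assert out["normalised_distance"].isna().all()
        assert any("zero_normaliser" in line for line in log)

    def test_baseline_day_excluded_from_divisor(self):
        # baseline fell back to -7, so only -15 feeds the divisor
        raw = raw_frame(
            [
                ("s1", "v", -15, -15.0, -7, 3.0, 3.0),
                ("s1", "v", 4, 4.0, -7, 6.0, 6.0),
            ]
        )
        out = normalise_distances(raw)
        assert out[out["nominal_day"] == 4]["normalised_distance"].iloc[0] == 2.0

    def test_self_normalisation_identity_on_simulated_cohort(self, small_cohort):
        raw = compute_raw_distances(
            small_cohort["samples"], small_cohort["scalars"], small_cohort["profiles"]
        )
        out = normalise_distances(raw)
        pre = out[out["nominal_day"].isin([-7, -15])]
        for (subj, var), grp in pre.groupby(["subject_id", "variable"]):
            if len(grp) == 2 and grp["normalised_distance"].notna().all():
                assert grp["normalised_distance"].mean() == pytest.approx(
                    1.0, abs=1e-9
                )


class TestCohortDrivers:
    def test_distances_cover_all_panel_variables(self, small_cohort, small_bundle):
        assert small_bundle.distances["variable"].nunique() == 17
        assert (small_bundle.distances["raw_distance"].dropna() >= 0).all()
        structures = small_bundle.distances[
            small_bundle.distances["variable"].str.endswith("_structure")
        ]
        d = structures["raw_distance"].dropna()
        assert ((d >= 0) & (d <= 1)).all()

    def test_excluded_subject_is_logged(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["a_d1", "a_d4"],
                "subject_id": ["a", "a"],
                "arm": ["x", "x"],
                "nominal_day": [1, 4],
                "collection_time": [1.0, 4.0],
            }
        )
        scalars = pd.DataFrame(
            {
                "sample_id": ["a_d1", "a_d4"],
                "variable": ["bacterial_counts"] * 2,
                "value": [1.0, 2.0],
            }
        )
        log = []
        out = compute_raw_distances(samples, scalars, log=log)
        assert len(out) == 0
        assert any("no_pretreatment_sample" in line for line in log)
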