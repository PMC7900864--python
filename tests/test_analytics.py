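import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vespre.analytics import (
    clinical_table,
    filter_by_missingness,
    kaiser_factor_screen,
    logfold_matrix,
    optics_reachability,
    simulate_factor_cohort,
    smoothness_score,
    summarize_cohort,
)


class TestSummaries:
    def test_constant_column_sd_zero(self):
        df = pd.DataFrame({"x": [5.0] * 10})
        s = summarize_cohort(df, {"x": "mean_sd"})
        assert s.table.loc["x", "sd"] == 0.0

    def test_median_iqr_small_closed_form(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5]})
        s = summarize_cohort(df, {"x": "median_iqr"})
        row = s.table.loc["x"]
        assert (row["median"], row["q1"], row["q3"]) == (3, 2, 4)

    def test_binary_outcome_integer_percent(self):
        # 49 deaths of 549 -> 9%
        df = pd.DataFrame({"died": [1] * 49 + [0] * 500})
        s = summarize_cohort(df, {"died": "binary"})
        assert s.table.loc["died", "count"] == 49
        assert s.table.loc["died", "percent"] == 9

    def test_missing_variable_raises(self):
        with pytest.raises(KeyError, match="ghost"):
            summarize_cohort(pd.DataFrame({"x": [1]}), {"ghost": "mean_sd"})


class TestMissingnessFilter:
    def test_twenty_three_of_twenty_nine_retained(self):
        n = 100
        data = {f"low{i}": [1.0] * 90 + [np.nan] * 10 for i in range(23)}
        data.update({f"high{i}": [1.0] * 70 + [np.nan] * 30 for i in range(6)})
        retained = filter_by_missingness(pd.DataFrame(data), 0.25)
        assert len(retained) == 23
        assert all(c.startswith("low") for c in retained)

    def test_complete_table_fully_retained(self):
        df = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        assert filter_by_missingness(df) == ["a", "b"]

    def test_exact_threshold_excluded(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, np.nan]})  # exactly 25%
        assert filter_by_missingness(df, 0.25) == []


class TestLogFold:
    def test_all_median_values_give_zero_matrix(self):
        df = pd.DataFrame({"m": [7.0, 7.0, 7.0]})
        lf = logfold_matrix(df)
        assert (lf.values["m"] == 0.0).all()

    def test_sixteen_fold_is_four(self):
        df = pd.DataFrame({"m": [1.0, 1.0, 1.0, 16.0]})
        lf = logfold_matrix(df)
        assert lf.values["m"].iloc[3] == pytest.approx(4.0)

    def test_clip_stores_raw_and_bounds_display(self):
        df = pd.DataFrame({"m": [1.0, 1.0, 1.0, 64.0]})
        lf = logfold_matrix(df, clip=4.0)
        assert lf.values["m"].iloc[3] == pytest.approx(6.0)
        assert lf.clipped["m"].iloc[3] == 4.0

    def test_missing_cells_stay_missing(self):
        df = pd.DataFrame({"m": [1.0, np.nan, 4.0]})
        lf = logfold_matrix(df)
        assert np.isnan(lf.values["m"].iloc[1])

    def test_column_medians_map_to_zero(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.lognormal(size=(41, 5)),
                          columns=[f"m{i}" for i in range(5)])
        lf = logfold_matrix(df)
        assert np.allclose(lf.values.median(), 0.0)

    def test_non_positive_value_names_cell(self):
        df = pd.DataFrame({"bad": [1.0, -2.0]}, index=["p1", "p2"])
        with pytest.raises(ValueError, match="p2.*bad"):
            logfold_matrix(df)


class TestFactorScreen:
    def test_identity_correlation_retains_nothing(self):
        corr = pd.DataFrame(np.eye(6))
        assert kaiser_factor_screen(corr).n_retained == 0  # strict > 1

    def test_rank_one_correlation(self):
        corr = pd.DataFrame(np.ones((23, 23)))
        res = kaiser_factor_screen(corr)
        assert res.n_retained == 1
        assert res.eigenvalues[0] == pytest.approx(23.0)

    def test_five_block_design_recovers_five(self):
        df = simulate_factor_cohort(549, 23, 5, loading=0.7, seed=123)
        assert kaiser_factor_screen(df).n_retained == 5

    def test_constant_column_raises_with_names(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            kaiser_factor_screen(df)

    def test_loadings_shape_and_scale(self):
        df = simulate_factor_cohort(200, 6, 2, seed=4)
        res = kaiser_factor_screen(df)
        assert res.loadings.shape == (6, 6)
        # column sum of squared loadings equals the eigenvalue
        ss = (res.loadings ** 2).sum(axis=0).to_numpy()
        assert np.allclose(ss, res.eigenvalues)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(3, 12))
    def test_eigenvalue_sum_equals_variable_count(self, seed, p):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(50, p)))
        res = kaiser_factor_screen(df)
        assert abs(res.eigenvalues.sum() - p) < 1e-8

    def test_pairwise_complete_handles_missingness(self):
        df = simulate_factor_cohort(500, 8, 2, seed=11)
        rng = np.random.default_rng(0)
        mask = rng.random(df.shape) < 0.1
        df = df.mask(mask)
        assert kaiser_factor_screen(df).n_retained == 2


class TestOptics:
    def test_two_points_forced_profile(self):
        pts = np.array([[0.0], [3.0]])
        prof = optics_reachability(pts, min_pts=2)
        assert list(prof.order) == [0, 1]
        assert np.isinf(prof.reachability[0])
        assert prof.reachability[1] == pytest.approx(3.0)

    def test_first_position_always_undefined(self):
        rng = np.random.default_rng(2)
        prof = optics_reachability(rng.normal(size=(15, 2)), min_pts=3)
        assert np.isinf(prof.reachability[0])

    def test_order_is_permutation_and_reach_bounded_below(self):
        rng = np.random.default_rng(3)
        prof = optics_reachability(rng.normal(size=(20, 3)), min_pts=4)
        assert sorted(prof.order) == list(range(20))
        # reachability from any predecessor is at least its core distance,
        # hence at least the smallest core distance overall
        finite = np.isfinite(prof.reachability)
        assert (prof.reachability[finite] >= prof.core_distances.min() - 1e-12).all()

    def test_min_pts_below_two_rejected(self):
        with pytest.raises(ValueError):
            optics_reachability(np.zeros((5, 2)), min_pts=1)

    @pytest.mark.parametrize("seed", range(25))
    def test_profile_matches_independent_reference(self, seed):
        """Random instances with n <= 25 must reproduce the ordering and
        reachability of an independent OPTICS implementation exactly."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 26))
        d = int(rng.integers(1, 4))
        mp = int(rng.integers(2, 6))
        pts = rng.normal(size=(n, d))
        mine = optics_reachability(pts, min_pts=mp)
        ref = sklearn_cluster.OPTICS(min_samples=mp, max_eps=np.inf).fit(pts)
        assert np.array_equal(mine.order, ref.ordering_)
        ref_reach = ref.reachability_[ref.ordering_]
        both_inf = np.isinf(mine.reachability) & np.isinf(ref_reach)
        assert np.allclose(mine.reachability[~both_inf], ref_reach[~both_inf])
        assert np.allclose(mine.core_distances, ref.core_distances_)


class TestSmoothness:
    def profile(self, reach):
        from vespre.analytics import ReachabilityProfile
        r = np.asarray(reach, dtype=float)
        return ReachabilityProfile(order=np.arange(len(r)), reachability=r,
                                   core_distances=np.zeros(len(r)),
                                   min_pts=2, eps=np.inf)

    def test_constant_profile_scores_zero_partitioning(self):
        score, rec = smoothness_score(self.profile([np.inf, 1.0, 1.0, 1.0, 1.0]))
        assert score == 0.0 and rec == "partitioning"

    def test_alternating_profile_scores_above_constant(self):
        alternating, _ = smoothness_score(
            self.profile([np.inf, 1.0, 5.0, 1.0, 5.0, 1.0, 5.0]))
        constant, _ = smoothness_score(self.profile([np.inf, 1.0, 1.0, 1.0]))
        assert alternating > constant

    def test_all_undefined_profile_raises(self):
        with pytest.raises(ValueError):
            smoothness_score(self.profile([np.inf, np.inf, np.inf]))

    def test_separated_clusters_score_above_uniform_blob(self):
        # 3 well-separated Gaussians vs a single uniform blob, same n and a
        # fixed seed protocol: jaggedness must rank the clustered geometry
        # above the structureless one.
        rng = np.random.default_rng(42)
        n = 90
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        clustered = np.vstack([
            rng.normal(c, 0.5, size=(n // 3, 2)) for c in centers])
        uniform = rng.uniform(0.0, 1.0, size=(n, 2))
        s_clustered, rec_clustered = smoothness_score(
            optics_reachability(clustered, min_pts=5))
        s_uniform, rec_uniform = smoothness_score(
            optics_reachability(uniform, min_pts=5))
        assert s_clustered > s_uniform
        assert rec_clustered == "hierarchical"
        assert rec_uniform == "partitioning"


class TestClinicalTable:
    def test_first_in_window_wide_values(self, cohort_small):
        tbl = clinical_table(cohort_small.events)
        assert "platelets" in tbl.columns
        assert len(tbl) > 0
        enc = tbl.index[0]
        ev = cohort_small.events
        first = ev[(ev["encounter_id"] == enc) & (ev["code"] == "platelets")
                   & (ev["t_minutes"] < 360)].sort_values("t_minutes")
        if len(first):
            assert tbl.loc[enc, "platelets"] == pytest.approx(
                float(first["value"].iloc[0]))
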