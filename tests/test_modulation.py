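"""Event pairing, Wilcoxon signed-rank, IQR grouping, KDE and quantile
regression, each checked against an independent small-n oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from firerecov.errors import DataError
from firerecov.modulation import (
    GROUP_FASTER_E1,
    GROUP_FASTER_E2,
    GROUP_MIDDLE,
    bin_prefire,
    kde_bivariate,
    pair_events,
    pinball_loss,
    quantile_regression,
    select_extreme_diffs,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(diffs):
    """Exact two-sided p by enumerating every sign assignment of |d| ranks."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    n = len(ranks)
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs or w >= total - w_obs:
            count += 1
    return count / 2 ** n


def _fits_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["pixel_id", "event", "b", "a_rel", "y_pre", "valid",
                 "landcover"],
    )


class TestPairEvents:
    def test_b_diff_arithmetic(self):
        fits = _fits_frame([
            (0, 1, 0.05, 0.5, -0.1, True, "NL"),
            (0, 2, 0.06, 0.6, -0.2, True, "NL"),
            (1, 1, 0.04, 0.4, -0.1, True, "NL"),
            (1, 2, 0.04, 0.4, -0.1, True, "NL"),
        ])
        pairs = pair_events(fits)
        assert pairs.set_index("pixel_id").loc[0, "b_diff"] == pytest.approx(0.01)
        assert pairs.set_index("pixel_id").loc[1, "b_diff"] == 0.0

    def test_both_valid_rule_drops_half_valid_pixels_literal_keeps_them(self):
        fits = _fits_frame([
            (0, 1, 0.05, 0.5, -0.1, True, "NL"),
            (0, 2, 0.06, 0.6, -0.2, False, "NL"),
            (1, 1, 0.04, 0.4, -0.1, False, "NL"),
            (1, 2, 0.05, 0.4, -0.1, False, "NL"),
        ])
        assert len(pair_events(fits, "both_valid")) == 0
        literal = pair_events(fits, "literal_both_fail")
        assert literal["pixel_id"].tolist() == [0]

    def test_duplicate_pixel_event_rows_are_rejected(self):
        fits = _fits_frame([
            (0, 1, 0.05, 0.5, -0.1, True, "NL"),
            (0, 1, 0.05, 0.5, -0.1, True, "NL"),
        ])
        with pytest.raises(DataError):
            pair_events(fits)

    def test_injected_difference_is_recovered_in_the_mean(self):
        rng = np.random.default_rng(10)
        b1 = rng.uniform(0.03, 0.12, 200)
        rows = []
        for i, b in enumerate(b1):
            rows.append((i, 1, b, 0.5, -0.1, True, "NL"))
            rows.append((i, 2, b + 0.005, 0.5, -0.1, True, "NL"))
        pairs = pair_events(_fits_frame(rows))
        assert pairs["b_diff"].mean() == pytest.approx(0.005, abs=1e-12)


class TestWilcoxon:
    def test_all_positive_six_differences_give_exact_p(self):
        res = wilcoxon_signed_rank(np.array([1, 2, 3, 4, 5, 6.0]))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)

    def test_antisymmetric_sample_sits_at_the_null_centre(self):
        res = wilcoxon_signed_rank(np.array([-1, 1, -2, 2, -3, 3.0]))
        assert res.p_value == pytest.approx(1.0)

    def test_zero_differences_are_dropped(self):
        res = wilcoxon_signed_rank(np.array([0, 0, 1, 2, 3, 4, 5, 6.0]))
        assert res.n_nonzero == 6
        assert res.p_value == pytest.approx(2 / 64)

    def test_all_zero_is_degenerate_with_p_one(self):
        res = wilcoxon_signed_rank(np.zeros(10))
        assert res.degenerate
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.2, 1.0, 11), 1)  # rounding creates ties
        d = d[d != 0]
        res = wilcoxon_signed_rank(d)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_exact_p_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 1.0, 14)
        ours = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, method="exact", alternative="two-sided")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_tracks_the_exact_p(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.6, 1.0, 12)
        exact = wilcoxon_signed_rank(d, exact_max_n=25)
        approx = wilcoxon_signed_rank(d, exact_max_n=5)
        assert approx.method == "normal"
        assert abs(exact.p_value - approx.p_value) < 0.02

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-9, 9).filter(lambda v: v != 0),
                    min_size=5, max_size=10))
    def test_exact_p_is_a_valid_probability_and_matches_enumeration(self, d):
        res = wilcoxon_signed_rank(np.array(d, float))
        assert 0 < res.p_value <= 1
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)


class TestExtremeDiffs:
    def _pairs(self, diffs, cat="NL"):
        return pd.DataFrame({
            "pixel_id": np.arange(len(diffs)),
            "b_diff": diffs,
            "landcover": cat,
        })

    def test_symmetric_ranks_select_bottom_and_top_quartiles(self):
        diffs = np.arange(1, 101, dtype=float) - 50.5  # -49.5 .. 49.5
        out = select_extreme_diffs(self._pairs(diffs))
        assert (out["group"] == GROUP_FASTER_E1).sum() == 25
        assert (out["group"] == GROUP_FASTER_E2).sum() == 25
        assert set(out[out.group == GROUP_FASTER_E1]["b_diff"]) == set(diffs[:25])
        assert set(out[out.group == GROUP_FASTER_E2]["b_diff"]) == set(diffs[-25:])

    def test_sign_guard_keeps_positive_diffs_out_of_the_slower_group(self):
        diffs = np.arange(1, 101, dtype=float)  # all positive
        out = select_extreme_diffs(self._pairs(diffs))
        assert (out["group"] == GROUP_FASTER_E1).sum() == 0

    def test_degenerate_distribution_selects_nothing(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = select_extreme_diffs(self._pairs(np.full(20, 0.01)))
        assert (out["group"] == GROUP_MIDDLE).all()

    def test_group_sizes_match_sort_and_slice_oracle(self):
        rng = np.random.default_rng(6)
        diffs = rng.normal(0, 0.01, 83)
        out = select_extreme_diffs(self._pairs(diffs))
        q25, q75 = np.quantile(diffs, [0.25, 0.75])
        srt = np.sort(diffs)
        lo = srt[(srt < q25) & (srt < 0)]
        hi = srt[(srt > q75) & (srt > 0)]
        assert (out["group"] == GROUP_FASTER_E1).sum() == len(lo)
        assert (out["group"] == GROUP_FASTER_E2).sum() == len(hi)

    def test_groups_partition_the_pair_set(self):
        rng = np.random.default_rng(7)
        pairs = pd.concat([
            self._pairs(rng.normal(0, 0.01, 40), "NL"),
            self._pairs(rng.normal(0, 0.02, 40), "Shb"),
        ], ignore_index=True)
        pairs["pixel_id"] = np.arange(len(pairs))
        out = select_extreme_diffs(pairs)
        assert out["group"].isin([GROUP_FASTER_E1, GROUP_FASTER_E2,
                                  GROUP_MIDDLE]).all()
        assert len(out) == len(pairs)


class TestKde:
    def test_tight_cluster_centroid_is_the_cluster_mean(self):
        rng = np.random.default_rng(8)
        pts = rng.normal([0.5, 0.06], [0.01, 0.002], (60, 2))
        _, _, _, centroid = kde_bivariate(pts)
        np.testing.assert_allclose(centroid, pts.mean(axis=0), rtol=1e-12)

    def test_density_integrates_to_one_on_the_grid(self):
        rng = np.random.default_rng(9)
        pts = np.column_stack([rng.uniform(0, 1, 80), rng.uniform(0, 0.2, 80)])
        gx, gy, dens, _ = kde_bivariate(pts)
        riemann = dens.sum() * (gx[1] - gx[0]) * (gy[1] - gy[0])
        assert 0.99 <= riemann <= 1.01

    def test_two_cluster_centroid_is_the_weighted_mean(self):
        rng = np.random.default_rng(10)
        c1 = rng.normal([0.2, 0.03], 0.005, (30, 2))
        c2 = rng.normal([0.8, 0.10], 0.005, (60, 2))
        pts = np.vstack([c1, c2])
        _, _, _, centroid = kde_bivariate(pts)
        expected = (30 * c1.mean(axis=0) + 60 * c2.mean(axis=0)) / 90
        np.testing.assert_allclose(centroid, expected, rtol=1e-12)

    def test_degenerate_axis_gets_a_bandwidth_floor(self):
        pts = np.column_stack([np.full(20, 0.5), np.linspace(0.01, 0.1, 20)])
        with pytest.warns(UserWarning, match="zero variance"):
            _, _, dens, _ = kde_bivariate(pts)
        assert np.isfinite(dens).all()

    def test_too_few_points_are_rejected(self):
        with pytest.raises(DataError):
            kde_bivariate(np.ones((5, 2)))


class TestQuantileRegression:
    def test_collinear_points_give_the_common_slope_for_any_tau(self):
        x = np.linspace(0, 1, 30)
        y = 0.02 + 0.08 * x
        for tau in (0.01, 0.5, 0.99):
            fit = quantile_regression(x, y, tau)
            assert fit.slope == pytest.approx(0.08, abs=1e-9)
            assert fit.pinball_loss == pytest.approx(0.0, abs=1e-9)

    def test_median_regression_recovers_the_slope_under_symmetric_noise(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, 400)
        y = 0.03 + 0.05 * x + rng.normal(0, 0.01, 400)
        fit = quantile_regression(x, y, 0.5)
        assert fit.slope == pytest.approx(0.05, abs=0.01)

    @pytest.mark.parametrize("tau", [0.01, 0.5, 0.99])
    def test_pinball_loss_beats_every_two_point_line(self, tau):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 1, 40)
        y = 0.02 + 0.06 * x + rng.normal(0, 0.02, 40)
        fit = quantile_regression(x, y, tau)
        for i in range(40):
            for j in range(i + 1, 40):
                if x[i] == x[j]:
                    continue
                slope = (y[j] - y[i]) / (x[j] - x[i])
                intercept = y[i] - slope * x[i]
                assert fit.pinball_loss <= pinball_loss(x, y, intercept, slope,
                                                        tau) + 1e-9

    def test_matches_statsmodels_median_regression(self):
        from statsmodels.regression.quantile_regression import QuantReg

        rng = np.random.default_rng(13)
        x = rng.uniform(0, 1, 120)
        y = 0.02 + 0.07 * x + rng.normal(0, 0.015, 120)
        fit = quantile_regression(x, y, 0.5)
        ref = QuantReg(y, np.column_stack([np.ones_like(x), x])).fit(q=0.5)
        # both must reach the same optimum of the same convex objective
        ours = fit.pinball_loss
        theirs = pinball_loss(x, y, ref.params[0], ref.params[1], 0.5)
        assert ours <= theirs + 1e-6
        assert fit.slope == pytest.approx(ref.params[1], abs=5e-3)

    def test_degenerate_x_is_rejected(self):
        with pytest.raises(DataError):
            quantile_regression(np.ones(30), np.linspace(0, 1, 30), 0.5)


class TestBinPrefire:
    def _pairs(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "pixel_id": np.arange(n),
            "a_rel2": rng.uniform(0, 1, n),
            "b2": rng.uniform(0.02, 0.12, n),
            "y_pre2": rng.uniform(-0.4, 0, n),
            "landcover": rng.choice(["NL", "Shb"], n),
            "group": rng.choice([GROUP_FASTER_E1, GROUP_FASTER_E2], n),
        })

    def test_counts_sum_to_stratum_sizes(self):
        pairs = self._pairs(200)
        out = bin_prefire(pairs, event=2, n_bins=4)
        totals = out.groupby(["landcover", "group"], observed=True)["n"].sum()
        expected = pairs.groupby(["landcover", "group"], observed=True).size()
        pd.testing.assert_series_equal(totals, expected, check_names=False)

    def test_medians_match_a_groupby_oracle(self):
        pairs = self._pairs(300, seed=1)
        out = bin_prefire(pairs, event=2, n_bins=3)
        probe = out.iloc[len(out) // 2]
        sel = pairs[(pairs.landcover == probe.landcover)
                    & (pairs.group == probe.group)]
        sel = sel[sel.a_rel2.apply(lambda v: v in probe.a_rel_bin)]
        sel = sel[sel.b2.apply(lambda v: v in probe.b_bin)]
        assert probe.median_y_pre == pytest.approx(sel.y_pre2.median())
        assert probe.n == len(sel)

    def test_single_bin_holds_everything_with_the_global_median(self):
        pairs = self._pairs(50, seed=2)
        pairs["a_rel2"] = 0.5
        pairs["b2"] = 0.06
        pairs["landcover"] = "NL"
        pairs["group"] = GROUP_FASTER_E2
        out = bin_prefire(pairs, event=2, n_bins=4)
        assert len(out) == 1
        assert out.iloc[0]["n"] == 50
        assert out.iloc[0]["median_y_pre"] == pytest.approx(
            pairs.y_pre2.median()
        )
        assert out.iloc[0]["is_mode_bin"]
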