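import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import reoscore as rs
from reoscore.core import ValidationError
from reoscore.stats import (
    ContingencyTable2x2,
    cox_multivariate,
    cox_partial_loglik,
    km_estimate,
    logrank_test,
    odds_ratio,
    platform_concordance,
    rank_sum_test,
    response_table,
    score_marker_correlation,
)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = np.array([3.0, 5, 8, 11, 3, 5, 8, 11])
        e = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_oe_sums(self):
        """Six subjects, all events: accumulate O-E and V over the risk table by hand."""
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6, dtype=int)
        g = np.array([1, 1, 1, 0, 0, 0])
        o1 = e1 = v = 0.0
        order = np.argsort(t)
        at_risk = list(order)
        for i in order:
            n = len(at_risk)
            n1 = sum(g[j] for j in at_risk)
            o1 += g[i]
            e1 += n1 / n
            v += (n1 / n) * (1 - n1 / n) * (n - 1) / (n - 1) if n > 1 else 0.0
            at_risk.remove(i)
        expected = (o1 - e1) ** 2 / v
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(expected, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 60
            t = rng.exponential(12, n)
            e = (rng.random(n) < 0.7).astype(int)
            g = rng.integers(0, 2, n)
            mine = logrank_test(t, e, g)
            ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
            assert mine.chi_square == pytest.approx(ref.test_statistic, abs=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, abs=1e-9)

    def test_invariant_to_time_transform(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 40)
        e = (rng.random(40) < 0.6).astype(int)
        g = rng.integers(0, 2, 40)
        base = logrank_test(t, e, g)
        warped = logrank_test(np.exp(t / 5.0), e, g)
        assert warped.chi_square == pytest.approx(base.chi_square, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2, 3], [1, 1, 1], [0, 0, 0])
        with pytest.raises(ValidationError):
            logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curve = km_estimate([5.0, 8.0, 9.0], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_all_events_closed_form(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve.survival.tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_all_event_data_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 30)
        curve = km_estimate(t, np.ones(30, dtype=int))
        for q in rng.uniform(0, 15, 10):
            assert curve.survival_at(q) == pytest.approx((t > q).mean())

    def test_matches_lifelines_with_censoring(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t = np.round(rng.exponential(10, 80), 1) + 0.1  # force ties
        e = (rng.random(80) < 0.6).astype(int)
        mine = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_.loc[mine.event_times, "KM_estimate"].to_numpy()
        assert np.allclose(mine.survival, ref, atol=1e-12)

    def test_survival_non_increasing_and_starts_below_one(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 50)
        e = (rng.random(50) < 0.5).astype(int)
        curve = km_estimate(t, e)
        assert (np.diff(curve.survival) <= 1e-15).all()
        assert (curve.survival <= 1.0).all()


# ---------------------------------------------------------------------------
# odds ratio
# ---------------------------------------------------------------------------

class TestOddsRatio:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((46, 24, 11, 30), 5.23),
            ((16, 8, 8, 14), 3.50),
            ((13, 6, 11, 12), 2.36),
            ((5, 5, 5, 5), 1.00),
        ],
    )
    def test_known_tables(self, table, expected):
        res = odds_ratio(ContingencyTable2x2(*table))
        assert round(res.odds_ratio, 2) == expected

    def test_woolf_interval_brackets_estimate(self):
        res = odds_ratio(ContingencyTable2x2(46, 24, 11, 30))
        assert res.ci_low < res.odds_ratio < res.ci_high

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_row_swap_reciprocity(self, cells):
        a, b, c, d = cells
        orig = odds_ratio(ContingencyTable2x2(a, b, c, d)).odds_ratio
        swapped = odds_ratio(ContingencyTable2x2(b, a, d, c)).odds_ratio
        assert orig * swapped == pytest.approx(1.0)

    def test_structural_zero_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio(ContingencyTable2x2(5, 0, 5, 5))

    def test_response_table_construction(self):
        strata = pd.Series(["high", "high", "low", "low", "high"], index=list("abcde"))
        resp = pd.Series(
            ["responder", "non_responder", "responder", None, "responder"],
            index=list("abcde"),
        )
        t = response_table(strata, resp)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 0)


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------

class TestRankSum:
    def test_identical_groups(self):
        x = list(range(10))
        u, p = rank_sum_test(x, x)
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_exact_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.integers(0, 8, size=4).astype(float)  # ties likely
            y = rng.integers(0, 8, size=5).astype(float)
            u_obs, p_obs = rank_sum_test(x, y)
            pooled = np.concatenate([x, y])
            n = len(x)
            stats = []
            for idx in itertools.combinations(range(len(pooled)), n):
                mask = np.zeros(len(pooled), dtype=bool)
                mask[list(idx)] = True
                xs, ys = pooled[mask], pooled[~mask]
                u = sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)
                stats.append(u)
            stats = np.asarray(stats)
            mu = len(x) * len(y) / 2.0
            p_exact = min(
                1.0,
                2.0 * min((stats <= u_obs).mean(), (stats >= u_obs).mean()),
            )
            # exact permutation p agrees (both count tail assignments)
            assert p_obs == pytest.approx(p_exact, abs=1e-9), (x, y, u_obs)

    def test_large_sample_null_calibration(self):
        rng = np.random.default_rng(6)
        rej = 0
        n_rep = 500
        for _ in range(n_rep):
            _, p = rank_sum_test(rng.normal(size=60), rng.normal(size=60))
            rej += p < 0.05
        assert abs(rej / n_rep - 0.05) < 0.025

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

class TestCox:
    def test_null_covariate_hazard_ratio_near_one(self):
        inside = 0
        n_rep = 100
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            n = 500
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(10, n)
            e = (rng.random(n) < 0.7).astype(int)
            fit = cox_multivariate(t, e, pd.DataFrame({"x": x}))
            hr = fit.summary.hazard_ratio.iloc[0]
            inside += 0.8 <= hr <= 1.25
        assert inside >= 90

    def test_matches_grid_search_of_partial_likelihood(self):
        """Single binary covariate: NR solution equals the 1-D maximiser of an
        independently coded Breslow partial likelihood."""
        rng = np.random.default_rng(8)
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.exp(-0.9 * x))
        e = np.ones(n, dtype=int)

        def naive_loglik(beta):  # O(n^2) risk-set sums, coded from the definition
            ll = 0.0
            for i in range(n):
                if e[i]:
                    risk = [j for j in range(n) if t[j] >= t[i]]
                    ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
            return ll

        coarse = np.arange(-3.0, 3.0, 0.01)
        best = coarse[np.argmax([naive_loglik(b) for b in coarse])]
        fine = np.arange(best - 0.02, best + 0.02, 1e-4)
        beta_star = fine[np.argmax([naive_loglik(b) for b in fine])]
        fit = cox_multivariate(t, e, pd.DataFrame({"x": x}))
        assert fit.converged
        assert fit.summary.coef.iloc[0] == pytest.approx(beta_star, abs=1e-4)
        # and the package's own loglik evaluator agrees with the naive one
        assert cox_partial_loglik(t, e, x.reshape(-1, 1), [0.5]) == pytest.approx(
            naive_loglik(0.5), abs=1e-9
        )

    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(9)
        n = 150
        df = pd.DataFrame(
            {
                "age": rng.normal(60, 8, n),
                "grp": rng.integers(0, 2, n).astype(float),
            }
        )
        t = rng.exponential(np.exp(-0.02 * df.age + 0.5 * df.grp) * 20)
        e = (rng.random(n) < 0.8).astype(int)
        fit = cox_multivariate(t, e, df)
        cph = CoxPHFitter().fit(
            pd.concat([pd.DataFrame({"t": t, "e": e}), df], axis=1), "t", "e"
        )
        assert np.allclose(fit.summary.coef.to_numpy(), cph.params_.to_numpy(), atol=1e-5)

    def test_perfect_separation_flagged(self):
        t = np.arange(1.0, 21.0)
        g = np.concatenate([np.ones(10), np.zeros(10)])  # all early events in one group
        fit = cox_multivariate(t, np.ones(20, dtype=int), pd.DataFrame({"g": g}))
        assert not fit.converged
        assert fit.flag is not None
        assert fit.summary.hazard_ratio.isna().all()

    def test_too_few_events_rejected(self):
        with pytest.raises(ValidationError):
            cox_multivariate(
                np.arange(1.0, 9.0),
                np.ones(8, dtype=int),
                pd.DataFrame({"x": np.arange(8.0)}),
            )


# ---------------------------------------------------------------------------
# concordance & marker correlation
# ---------------------------------------------------------------------------

class TestPlatformConcordance:
    def test_identity(self, small_cohort):
        expr, _, truth = small_cohort
        from reoscore.discovery import pair_score_matrix

        px = pair_score_matrix(expr, truth.planted_pairs)
        per_pair, summary = platform_concordance(px, px.copy())
        assert (per_pair == 1.0).all()
        assert summary["frac_pairs_above_threshold"] == 1.0

    def test_monotone_distortion_is_fully_concordant(self, small_cohort):
        expr, _, truth = small_cohort
        from reoscore.discovery import pair_score_matrix

        px = pair_score_matrix(expr, truth.planted_pairs)
        py = pair_score_matrix(
            rs.apply_platform_distortion(expr, "monotone", seed=1), truth.planted_pairs
        )
        per_pair, _ = platform_concordance(px, py)
        assert (per_pair == 1.0).all()

    def test_independent_platform_is_half_concordant(self):
        rng = np.random.default_rng(10)
        samples = [f"s{i}" for i in range(10)]
        pairs = [f"p{i}" for i in range(1000)]
        px = pd.DataFrame(rng.integers(0, 2, (1000, 10)), index=pairs, columns=samples)
        py = pd.DataFrame(rng.integers(0, 2, (1000, 10)), index=pairs, columns=samples)
        per_pair, _ = platform_concordance(px, py)
        assert abs(per_pair.mean() - 0.5) < 0.05

    def test_sample_mismatch_rejected(self):
        px = pd.DataFrame([[0, 1]], index=["p"], columns=["a", "b"])
        py = pd.DataFrame([[0, 1]], index=["p"], columns=["a", "c"])
        with pytest.raises(ValidationError):
            platform_concordance(px, py)


class TestMarkerCorrelation:
    def _expr(self, rows: dict, samples):
        return rs.ExpressionMatrix(pd.DataFrame(rows, index=samples).T)

    def test_marker_equal_to_score_has_rho_one(self):
        samples = [f"s{i}" for i in range(12)]
        score = pd.Series(np.arange(12.0), index=samples)
        expr = self._expr({"M1": score.to_numpy() + 1.0, "M2": np.ones(12)}, samples)
        out = score_marker_correlation(score, expr, ["M1"])
        assert out.loc["M1", "rho"] == pytest.approx(1.0)

    def test_constant_and_missing_markers_reported(self):
        samples = [f"s{i}" for i in range(12)]
        score = pd.Series(np.arange(12.0), index=samples)
        expr = self._expr({"M1": np.arange(12.0), "FLAT": np.ones(12)}, samples)
        out = score_marker_correlation(score, expr, ["FLAT", "ABSENT"])
        assert out.loc["FLAT", "note"] == "constant"
        assert out.loc["ABSENT", "note"] == "missing"
        assert out.loc[["FLAT", "ABSENT"], "rho"].isna().all()

    def test_matches_independent_rank_recomputation(self):
        rng = np.random.default_rng(11)
        samples = [f"s{i}" for i in range(40)]
        score = pd.Series(rng.integers(0, 19, 40).astype(float), index=samples)
        marker = score.to_numpy() + rng.normal(0, 3.0, 40)
        expr = self._expr({"M": marker, "Z": rng.normal(size=40)}, samples)
        out = score_marker_correlation(score, expr, ["M"])
        rx = sps.rankdata(score.to_numpy())
        ry = sps.rankdata(marker)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert out.loc["M", "rho"] == pytest.approx(rho_oracle, abs=1e-12)


class TestGroupScoreComparison:
    def test_identical_groups(self):
        s = pd.Series([3.0, 5.0, 7.0, 3.0, 5.0, 7.0])
        labels = pd.Series(["a", "a", "a", "b", "b", "b"])
        out = rs.group_score_comparison(s, labels)
        assert out["p_value"] == pytest.approx(1.0)
        assert out["means"]["a"] == out["means"]["b"]
        assert out["higher_group"] is None

    def test_responders_score_higher_with_power(self):
        wins = 0
        for seed in range(50):
            cfg = rs.SimulationConfig(n_samples=200, seed=100 + seed)
            _, clin, truth = rs.simulate_cohort(cfg)
            out = rs.group_score_comparison(truth.planted_score, clin.response)
            wins += out["higher_group"] == "responder" and out["p_value"] < 0.05
        assert wins >= 45

    def test_permuted_labels_are_calibrated(self, small_cohort):
        _, clin, truth = small_cohort
        rng = np.random.default_rng(12)
        labels = clin.response.to_numpy()
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            perm = pd.Series(rng.permutation(labels), index=truth.planted_score.index)
            out = rs.group_score_comparison(truth.planted_score, perm)
            rej += out["p_value"] < 0.05
        assert abs(rej / n_rep - 0.05) < 0.02
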