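"""Agreement statistics: moments, gates, rank correlation, bootstrap CI,
Wilcoxon signed-rank, error metrics — each checked against an independent
oracle where one exists."""

from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, strategies as st

from umni.agreement import (
    agreement_battery,
    bootstrap_rho_ci,
    criterion_moments,
    gate_check,
    mae_rmse,
    per_criterion_report,
    pooled_report,
    spearman_rho,
    wilcoxon_signed_rank,
)
from umni.exceptions import DegenerateDataError
from umni.llm import RaterConfig, mock_rate


# ---------------------------------------------------------------- oracles

def rank_then_pearson(x, y):
    """Brute-force Spearman: average ranks by hand, then Pearson by formula."""
    def avg_ranks(v):
        v = list(v)
        return [
            np.mean([i + 1 for i, u in enumerate(sorted(v)) if u == val])
            for val in v
        ]
    rx, ry = avg_ranks(x), avg_ranks(y)
    mx, my = np.mean(rx), np.mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = np.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def wilcoxon_by_enumeration(d):
    """Exact two-sided p by enumerating all sign assignments (no ties/zeros)."""
    d = np.asarray(d, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    ws = [np.dot(signs, ranks) for signs in product([0, 1], repeat=len(d))]
    ws = np.array(ws)
    lo = np.mean(ws <= w_obs)
    hi = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------- moments

class TestMoments:
    def test_constant_scores(self):
        assert criterion_moments([3, 3, 3]) == (3.0, 0.0)

    def test_two_point_spread_sample_sd(self):
        mean, sd = criterion_moments([1, 5])
        assert mean == 3.0
        assert sd == pytest.approx(2 * np.sqrt(2), abs=1e-4)

    def test_single_score_errors(self):
        with pytest.raises(DegenerateDataError):
            criterion_moments([4])


class TestGates:
    @pytest.mark.parametrize("mean_diff,sd_diff,expected", [
        (-1.40, -0.19, ("fail", "pass")),
        (0.0, 0.0, ("pass", "pass")),
        (1.0, 0.5, ("pass", "pass")),     # boundaries inclusive
        (-1.0, -0.5, ("pass", "pass")),
        (1.01, 0.51, ("fail", "fail")),
    ])
    def test_gate_decisions(self, mean_diff, sd_diff, expected):
        assert gate_check(mean_diff, sd_diff) == expected


# ----------------------------------------------------------- correlations

class TestSpearman:
    def test_perfect_agreement(self):
        assert spearman_rho([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_ranks_hand_value(self):
        # average ranks: 4.5 / sqrt(22.5)
        assert spearman_rho([1, 2, 2, 4], [1, 3, 2, 4]) == \
            pytest.approx(4.5 / np.sqrt(22.5), abs=1e-4)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_exhaustive_oracle_on_all_permutations(self, n):
        x = list(range(1, n + 1))
        for perm in permutations(x):
            assert spearman_rho(x, list(perm)) == \
                pytest.approx(rank_then_pearson(x, perm), abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.raises(DegenerateDataError, match="constant"):
            spearman_rho([2, 2, 2], [1, 2, 3])


class TestBootstrapCI:
    def test_identical_distinct_vectors_give_degenerate_interval(self):
        x = np.arange(10.0)
        assert bootstrap_rho_ci(x, x, resamples=200, seed=1) == (1.0, 1.0)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(20), rng.random(20)
        a = bootstrap_rho_ci(x, y, resamples=300, seed=9)
        assert a == bootstrap_rho_ci(x, y, resamples=300, seed=9)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        x = rng.random(30)
        y = x + rng.normal(0, 0.4, 30)
        lo, hi = bootstrap_rho_ci(x, y, resamples=500, seed=3)
        assert -1 <= lo <= spearman_rho(x, y) <= hi <= 1

    def test_small_n_refused(self):
        with pytest.raises(DegenerateDataError):
            bootstrap_rho_ci([1, 2, 3], [1, 2, 3])


# --------------------------------------------------------------- wilcoxon

class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.degenerate and res.p_value == 1.0

    def test_three_positive_differences_exact(self):
        # all 2^3 sign assignments: only the all-positive one reaches W=6
        res = wilcoxon_signed_rank([2, 3, 4], [1, 1, 1])
        assert res.p_value == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        # distinct magnitudes, random signs: no ties, exact branch applies
        d = rng.permutation(np.arange(1, n + 1)) * rng.choice([-1, 1], n)
        res = wilcoxon_signed_rank(d, np.zeros(n))
        assert res.p_value == pytest.approx(wilcoxon_by_enumeration(d), abs=1e-12)

    def test_tied_differences_use_approximation(self):
        x = np.array([5, 5, 5, 5, 1, 1, 2, 3, 4, 2], dtype=float)
        y = x - np.array([1, 1, 1, 1, -1, -1, 2, 2, 2, 2])
        res = wilcoxon_signed_rank(x, y)
        assert 0 <= res.p_value <= 1 and not res.degenerate

    @given(st.lists(st.integers(1, 5), min_size=2, max_size=15),
           st.lists(st.integers(1, 5), min_size=2, max_size=15))
    def test_p_always_in_unit_interval(self, a, b):
        n = min(len(a), len(b))
        res = wilcoxon_signed_rank(a[:n], b[:n])
        assert 0 <= res.p_value <= 1


# ---------------------------------------------------------------- errors

class TestErrorMetrics:
    def test_identical_vectors(self):
        assert mae_rmse([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)

    def test_equal_magnitude_differences(self):
        assert mae_rmse([2, 1], [1, 2]) == (1.0, 1.0)

    def test_hand_computed_rmse(self):
        mae, rmse = mae_rmse([1, 3], [1, 1])
        assert (mae, round(rmse, 4)) == (1.0, 1.4142)

    @given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 5)),
                    min_size=1, max_size=40))
    def test_rmse_dominates_mae_dominates_mean_bias(self, pairs):
        x, y = zip(*pairs)
        mae, rmse = mae_rmse(x, y)
        mean_bias = abs(np.mean(np.array(x) - np.array(y)))
        assert rmse >= mae - 1e-12
        assert mae >= mean_bias - 1e-12


# ---------------------------------------------------------------- reports

class TestReports:
    def test_self_agreement_passes_every_gate(self, rater_pair):
        expert, _ = rater_pair
        report = per_criterion_report(expert, expert)
        assert (report["gate_mean"] == "pass").all()
        assert (report["gate_sd"] == "pass").all()
        assert (report["mean_diff"] == 0).all()

    def test_zero_disagreement_mock_has_zero_error(self, rater_pair):
        expert, _ = rater_pair
        clone = mock_rate(expert, RaterConfig(seed=1), rater_id="clone")
        report = pooled_report(expert, clone, resamples=100, seed=2)
        assert (report["mae"] == 0).all()
        assert (report["rmse"] == 0).all()
        assert (report["wilcoxon_p"] == 1.0).all()

    def test_mean_diff_sign_is_expert_minus_llm(self, matrix_factory):
        expert = matrix_factory(np.full((4, 3), 2), criteria_names=list("abc"))
        llm = matrix_factory(np.full((4, 3), 3), criteria_names=list("abc"))
        report = per_criterion_report(expert, llm)
        assert (report["mean_diff"] == -1.0).all()
        assert (report["gate_mean"] == "pass").all()  # boundary inclusive

    def test_pooled_report_shape_and_invariants(self, rater_pair):
        expert, second = rater_pair
        report = pooled_report(expert, second, resamples=200, seed=11)
        assert list(report.columns) == [
            "criterion", "spearman_rho", "rho_ci_low", "rho_ci_high",
            "mae", "rmse", "wilcoxon_p"]
        ok = report.dropna(subset=["spearman_rho"])
        assert (ok["rho_ci_low"] <= ok["spearman_rho"] + 1e-12).all()
        assert (ok["spearman_rho"] <= ok["rho_ci_high"] + 1e-12).all()
        assert (report["rmse"] >= report["mae"] - 1e-12).all()

    def test_battery_on_correlated_scores(self):
        rng = np.random.default_rng(4)
        x = rng.integers(1, 6, 40).astype(float)
        y = np.clip(x + rng.choice([-1, 0, 0, 1], 40), 1, 5)
        pa = agreement_battery(x, y, resamples=300, seed=5)
        assert pa.rho_ci_low <= pa.spearman_rho <= pa.rho_ci_high
        assert pa.rmse >= pa.mae
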