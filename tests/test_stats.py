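"""Outcome statistics vs closed-form and enumeration oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

import diamotion.stats as st


def brute_force_rank_sum_p(x, y):
    """Independent oracle: enumerate every assignment of the pooled
    values to the two samples and count rank sums at least as extreme
    (mirrored about the null mean) as the observed one."""
    pooled = np.concatenate([x, y])
    n, N = len(x), len(pooled)
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n].sum()
    mean = n * (N + 1) / 2.0
    lo, hi = min(w_obs, 2 * mean - w_obs), max(w_obs, 2 * mean - w_obs)
    hits = total = 0
    for idx in combinations(range(N), n):
        w = ranks[list(idx)].sum()
        total += 1
        if w <= lo + 1e-9 or w >= hi - 1e-9:
            hits += 1
    return hits / total


class TestLinearFit:
    def test_exact_line(self):
        fit = st.linear_fit([1, 2, 3], [3, 5, 7])
        assert (fit.slope, fit.intercept, fit.r) == (2.0, 1.0, 1.0)
        assert fit.p_value == 0.0

    def test_hand_normal_equations(self):
        fit = st.linear_fit([0, 1, 2, 3], [1, 1, 3, 3])
        assert fit.slope == pytest.approx(0.8)
        assert fit.intercept == pytest.approx(0.8)
        assert fit.r == pytest.approx(0.8944, abs=5e-5)

    def test_constant_y_flagged(self):
        fit = st.linear_fit([0, 1, 2], [4, 4, 4])
        assert fit.slope == 0.0 and fit.intercept == 4.0
        assert not fit.r_defined and math.isnan(fit.r)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.linear_fit([2, 2, 2], [1, 2, 3])

    def test_matches_scipy_linregress_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            fit = st.linear_fit(x, y)
            ref = sps.linregress(x, y)
            assert fit.slope == pytest.approx(ref.slope, abs=1e-10)
            assert fit.intercept == pytest.approx(ref.intercept, abs=1e-10)
            assert fit.r == pytest.approx(ref.rvalue, abs=1e-10)
            assert fit.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_equations_residual_orthogonality(self, rng):
        for _ in range(50):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            fit = st.linear_fit(x, y)
            resid = y - fit.intercept - fit.slope * x
            assert abs(resid.sum()) < 1e-10
            assert abs((resid * x).sum()) < 1e-10


class TestLengthVsCsa:
    def test_synchronized_phantom_high_r(self, control_results):
        regs = control_results.regressions
        for m in ("ANT", "CNT", "PST", "TDM"):
            assert regs[m].r >= 0.99

    def test_tdm_slope_is_sum_of_parts(self, control_results):
        regs = control_results.regressions
        assert regs["TDM"].slope == pytest.approx(
            regs["ANT"].slope + regs["CNT"].slope + regs["PST"].slope, abs=1e-9)

    def test_phase_lag_lowers_anterior_r(self, control_results):
        import diamotion as dm
        spec = dm.preset_spec("control", phase_lag=(np.pi / 5, 0.0, 0.0))
        series, _ = dm.generate_phantom(spec)
        lagged = dm.DiaphragmMotion(series, dm.phantom_landmarks(spec)).fit()
        drop = control_results.regressions["ANT"].r - lagged.regressions["ANT"].r
        assert drop >= 0.05


class TestPercentSmaller:
    @pytest.mark.parametrize("ref, grp, expected", [
        (259.9, 143.0, 44.98),   # max CSA group means
        (685.1, 429.8, 37.26),   # max TDM group means
        (100.0, 100.0, 0.0),
    ])
    def test_worked_examples(self, ref, grp, expected):
        assert st.percent_smaller(ref, grp) == pytest.approx(expected, abs=5e-3)

    def test_antitone_in_group_mean(self):
        vals = [st.percent_smaller(200.0, g) for g in (50.0, 100.0, 150.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            st.percent_smaller(0.0, 10.0)


class TestGroupCompare:
    def test_exact_linear_recovery(self):
        height = np.array([1.4, 1.5, 1.6, 1.7, 1.45, 1.55, 1.65, 1.75])
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        y = 10 + 5 * group + 0.2 * height
        cmp_ = st.group_compare(y, group, covariate=height,
                                covariate_name="height")
        assert cmp_.effect == pytest.approx(5.0, abs=1e-10)
        assert cmp_.covariate == "height"

    def test_reduces_to_pooled_t_test(self, rng):
        for _ in range(100):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.5, 1, n2)
            labels = np.array(["a"] * n1 + ["b"] * n2)
            cmp_ = st.group_compare(np.concatenate([a, b]), labels)
            # textbook pooled-variance two-sample t as oracle
            sp2 = (((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
                   / (n1 + n2 - 2))
            t_ref = (b.mean() - a.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            p_ref = 2 * sps.t.sf(abs(t_ref), n1 + n2 - 2)
            assert cmp_.t_stat == pytest.approx(t_ref, abs=1e-10)
            assert cmp_.p_value == pytest.approx(p_ref, abs=1e-10)
            assert cmp_.effect == pytest.approx(b.mean() - a.mean(), abs=1e-10)

    def test_constant_covariate_rejected(self):
        y = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 0, 1, 1]
        with pytest.raises(ValueError, match="rank-deficient"):
            st.group_compare(y, labels, covariate=[2.0, 2.0, 2.0, 2.0])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            st.group_compare([1.0, 2.0, 3.0], [0, 0, 1])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert st.pearson(x, x)[0] == 1.0
        assert st.pearson(x, -x)[0] == -1.0

    def test_hand_example(self):
        r, p = st.pearson([0, 1, 2, 3], [1, 1, 3, 3])
        assert r == pytest.approx(0.8944, abs=5e-5)

    def test_matches_scipy_and_r_squared_identity(self, rng):
        for _ in range(50):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            r, p = st.pearson(x, y)
            ref = sps.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            fit = st.linear_fit(x, y)
            ss_res = np.sum((y - fit.intercept - fit.slope * x) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            assert r ** 2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCvPercent:
    def test_no_variation(self):
        assert st.cv_percent([100.0, 100.0, 100.0]) == 0.0

    def test_hand_arithmetic(self):
        # SD = sqrt(2), mean = 101 -> 1.400%
        assert st.cv_percent([100.0, 102.0]) == pytest.approx(1.400, abs=5e-4)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            st.cv_percent([0.0, 0.0])


class TestRankSum:
    def test_minimal_extreme_case(self):
        # x ranks {1,2}: one of the two extreme tails among C(4,2)=6
        res = st.rank_sum_exact([1.0, 2.0], [3.0, 4.0])
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_symmetric_case_p_one(self):
        res = st.rank_sum_exact([1.0, 4.0], [2.0, 3.0])
        assert res.p_value == 1.0

    def test_matches_brute_force_enumeration(self, rng):
        for n in (2, 3, 5, 7):
            for m in (2, 4, 7):
                x = rng.normal(size=n)
                y = rng.normal(0.7, 1.0, size=m)
                res = st.rank_sum_exact(x, y, mode="exact")
                assert res.p_value == pytest.approx(
                    brute_force_rank_sum_p(x, y), abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(2, 7)))
            y = rng.normal(size=int(rng.integers(2, 7)))
            res = st.rank_sum_exact(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_approx_agree_at_n10(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(0.8, 1.0, size=5)
        exact = st.rank_sum_exact(x, y, mode="exact").p_value
        approx = st.rank_sum_exact(x, y, mode="approx").p_value
        assert abs(exact - approx) < 0.05

    def test_ties_rejected_in_exact_mode(self):
        with pytest.raises(ValueError, match="approx"):
            st.rank_sum_exact([1.0, 2.0], [2.0, 3.0], mode="exact")

    def test_auto_switches_to_approx_for_large_samples(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert st.rank_sum_exact(x, y).mode == "approx"


class TestObserverVariability:
    @staticmethod
    def _table(values_by_obs):
        import pandas as pd
        rows = []
        for obs, offset in values_by_obs.items():
            for subj in ("s1", "s2"):
                for rep in range(3):
                    base = 100.0 + offset * rep
                    rows.append({"observer": obs, "subject": subj, "repeat": rep,
                                 "ANT_min": base, "CNT_min": base + 1,
                                 "PST_min": base + 2, "DIA_min": base + 3})
        return pd.DataFrame(rows)

    def test_identical_repeats_give_zero_cv_and_p_one(self):
        table = self._table({"o1": 0.0, "o2": 0.0})
        ov = st.observer_variability(table)
        assert (ov.cv_table["cv_pct"] == 0.0).all()
        assert ov.p_value == 1.0

    def test_identical_distributions_give_p_one(self):
        table = self._table({"o1": 0.5, "o2": 0.5})
        ov = st.observer_variability(table)
        assert ov.p_value == 1.0

    def test_unmatched_subjects_rejected(self):
        table = self._table({"o1": 0.1, "o2": 0.2})
        table.loc[table["observer"] == "o2", "subject"] = table.loc[
            table["observer"] == "o2", "subject"].replace("s2", "s3")
        with pytest.raises(ValueError, match="different subject sets"):
            st.observer_variability(table)

    def test_single_repeat_rejected(self):
        table = self._table({"o1": 0.1, "o2": 0.2}).groupby(
            ["observer", "subject"]).head(1)
        with pytest.raises(ValueError, match="repeats"):
            st.observer_variability(table)
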