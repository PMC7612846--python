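"""QC scoring, repeated-measures correlation, bootstrap CIs, group tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wmatlas.stats import (
    DegenerateDataError, fisher_z, mannwhitney_tracts, paired_t_peak_dice,
    qc_scores, qc_table, rm_corr, zdiff_ci_moving_block, zdiff_ci_percentile,
)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQC:
    def test_identical_subjects_all_pass(self):
        df = pd.DataFrame({"m1": [2.0] * 5, "m2": [7.0] * 5},
                          index=[f"s{i}" for i in range(5)])
        recs = qc_scores(df)
        assert all(r.score == 0.0 for r in recs)
        assert not any(r.rejected for r in recs)

    def test_five_sd_outlier_rejected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, size=(9, 3))
        out = base.mean(axis=0) + 5 * base.std(axis=0, ddof=1)
        df = pd.DataFrame(np.vstack([base, out]),
                          index=[f"s{i}" for i in range(10)])
        recs = qc_scores(df)
        assert recs[-1].rejected
        assert sum(r.rejected for r in recs) == 1

    def test_single_metric_hand_computation(self):
        # values (1,2,3,4,100): score = |z|; only the outlier exceeds mean+SD
        vals = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        df = pd.DataFrame({"m": vals}, index=list("abcde"))
        recs = qc_scores(df)
        sd = vals.std(ddof=1)
        expected = np.abs((vals - vals.mean()) / sd)
        got = np.array([r.score for r in recs])
        assert np.allclose(got, expected, atol=1e-12)
        cutoff = expected.mean() + expected.std(ddof=1)
        assert [r.rejected for r in recs] == list(expected > cutoff)
        assert [r.rejected for r in recs] == [False] * 4 + [True]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            qc_scores(pd.DataFrame({"m": [1.0, 2.0]}))  # too few subjects
        with pytest.raises(ValueError):
            qc_scores(pd.DataFrame({"m": ["a", "b", "c"]}))

    def test_table_form(self):
        df = pd.DataFrame({"subject": list("abc"), "m": [1.0, 2.0, 3.0]})
        t = qc_table(df)
        assert list(t.columns) == ["subject", "score", "rejected"]
        assert len(t) == 3


# ---------------------------------------------------------------------------
# Repeated-measures correlation
# ---------------------------------------------------------------------------

def rmcorr_lstsq_oracle(subjects, x, y):
    """Dummy-coded least squares: y ~ unit dummies + common slope.

    r from the extra-sum-of-squares of the x term, signed by the slope.
    """
    subjects = np.asarray(subjects)
    units = np.unique(subjects)
    D = np.stack([(subjects == u).astype(float) for u in units], axis=1)
    Xfull = np.column_stack([D, x])
    beta, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
    ss_full = float(((y - Xfull @ beta) ** 2).sum())
    beta0, *_ = np.linalg.lstsq(D, y, rcond=None)
    ss_red = float(((y - D @ beta0) ** 2).sum())
    ss_x = ss_red - ss_full
    r = math.copysign(math.sqrt(max(ss_x, 0.0) / (ss_x + ss_full)), beta[-1])
    return r, beta[-1]


def make_rm_data(rng, n_units=3, n_rec=5, noise=0.3, slope=1.0):
    subjects, x, y = [], [], []
    for u in range(n_units):
        xu = rng.normal(0, 1, n_rec) + rng.normal(0, 2)
        yu = slope * xu + rng.normal(0, 3) + rng.normal(0, noise, n_rec)
        subjects += [f"u{u}"] * n_rec
        x += list(xu)
        y += list(yu)
    return np.array(subjects), np.array(x), np.array(y)


class TestRmCorr:
    def test_perfect_within_unit_line(self):
        subjects = np.repeat(["a", "b", "c"], 4)
        x = np.tile(np.arange(4.0), 3)
        y = x + np.repeat([0.0, 5.0, -2.0], 4)  # y = x + unit offset
        res = rm_corr(subjects, x, y)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_negative_slope_sign(self):
        subjects = np.repeat(["a", "b"], 4)
        x = np.tile(np.arange(4.0), 2)
        y = -2 * x + np.repeat([0.0, 5.0], 4)
        assert rm_corr(subjects, x, y).r == pytest.approx(-1.0)

    def test_degenerate_y_errors(self):
        subjects = np.repeat(["a", "b"], 3)
        x = np.tile(np.arange(3.0), 2)
        y = np.repeat([1.0, 2.0], 3)  # constant within unit
        with pytest.raises(DegenerateDataError):
            rm_corr(subjects, x, y)

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            subjects, x, y = make_rm_data(rng, n_units=rng.integers(2, 6),
                                          n_rec=rng.integers(3, 9))
            res = rm_corr(subjects, x, y)
            r_oracle, slope = rmcorr_lstsq_oracle(subjects, x, y)
            assert abs(res.r - r_oracle) < 1e-10

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        subjects, x, y = make_rm_data(rng, n_units=5, n_rec=8)
        df = pd.DataFrame({"s": subjects, "x": x, "y": y})
        ref = pingouin.rm_corr(data=df, x="x", y="y", subject="s")
        res = rm_corr(subjects, x, y)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.df == int(ref["dof"].iloc[0])
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_per_unit_shift_invariance(self):
        rng = np.random.default_rng(8)
        subjects, x, y = make_rm_data(rng, n_units=4, n_rec=6)
        base = rm_corr(subjects, x, y).r
        shifts = {u: rng.normal(0, 50) for u in np.unique(subjects)}
        x2 = x + np.array([shifts[u] for u in subjects])
        y2 = y + np.array([2 * shifts[u] for u in subjects])
        assert abs(rm_corr(subjects, x2, y2).r - base) < 1e-10

    def test_pooled_line_is_plain_ols(self):
        rng = np.random.default_rng(9)
        subjects, x, y = make_rm_data(rng)
        res = rm_corr(subjects, x, y)
        m, c = np.polyfit(x, y, 1)
        assert res.m == pytest.approx(m) and res.c == pytest.approx(c)


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_is_half_log_three(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3.0), abs=1e-12)
        assert round(fisher_z(0.5), 5) == 0.54931

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-0.999, 0.999))
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


# ---------------------------------------------------------------------------
# Bootstrap CIs
# ---------------------------------------------------------------------------

def boot_data(rng, n_units=8, n_rec=11, sd1=0.02, sd2=0.02, spread=0.06):
    means = rng.normal(0.45, spread, size=n_rec)
    subjects = np.repeat([f"s{i}" for i in range(n_units)], n_rec)
    x = np.tile(means, n_units) + rng.normal(0, 0.01, n_units * n_rec)
    y1 = x + rng.normal(0, sd1, x.size)
    y2 = x + rng.normal(0, sd2, x.size)
    return subjects, x, y1, y2


class TestPercentileBootstrap:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        subjects, x, y1, y2 = boot_data(rng)
        a = zdiff_ci_percentile(subjects, x, y1, y2, n_boot=200, seed=5)
        b = zdiff_ci_percentile(subjects, x, y1, y2, n_boot=200, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = zdiff_ci_percentile(subjects, x, y1, y2, n_boot=200, seed=6)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_identical_units_zero_width(self):
        # all units identical -> every resample reproduces the sample
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y1 = np.array([0.1, 0.25, 0.28, 0.42])
        y2 = np.array([0.12, 0.18, 0.33, 0.38])
        subjects = np.repeat(["a", "b", "c"], 4)
        res = zdiff_ci_percentile(subjects, np.tile(x, 3), np.tile(y1, 3),
                                  np.tile(y2, 3), n_boot=100, seed=1)
        assert res.ci_low == pytest.approx(res.ci_high)
        assert res.ci_low == pytest.approx(res.delta_z)

    def test_ci_width_shrinks_with_more_units(self):
        rng = np.random.default_rng(2)
        widths = []
        for n_units in (6, 24):
            w = []
            for rep in range(10):
                subjects, x, y1, y2 = boot_data(rng, n_units=n_units)
                res = zdiff_ci_percentile(subjects, x, y1, y2, n_boot=300,
                                          seed=rep)
                w.append(res.ci_high - res.ci_low)
            widths.append(np.mean(w))
        assert widths[1] < widths[0]


class TestMovingBlockBootstrap:
    def test_full_length_blocks_zero_width(self):
        x = np.linspace(0.2, 0.6, 10)
        rng = np.random.default_rng(4)
        y1 = x + rng.normal(0, 0.02, 10)
        y2 = x + rng.normal(0, 0.02, 10)
        subjects = np.repeat(["a", "b"], 10)
        res = zdiff_ci_moving_block(subjects, np.tile(x, 2), np.tile(y1, 2),
                                    np.tile(y2, 2), block_len=10, n_boot=50,
                                    seed=0)
        assert res.ci_low == pytest.approx(res.ci_high)

    def test_block_len_too_large_errors(self):
        subjects = np.repeat(["a", "b"], 5)
        x = np.tile(np.arange(5.0), 2)
        with pytest.raises(ValueError):
            zdiff_ci_moving_block(subjects, x, x + 0.1, x - 0.1, block_len=6)

    def test_iid_width_agrees_with_iid_bootstrap(self):
        # on independent records the two schemes should give similar CI widths
        rng = np.random.default_rng(6)
        w_iid, w_blk = [], []
        for rep in range(20):
            subjects, x, y1, y2 = boot_data(rng, n_units=6, n_rec=30)
            a = zdiff_ci_percentile(subjects, x, y1, y2, n_boot=500, seed=rep)
            b = zdiff_ci_moving_block(subjects, x, y1, y2, block_len=1,
                                      n_boot=500, seed=rep)
            w_iid.append(a.ci_high - a.ci_low)
            w_blk.append(b.ci_high - b.ci_low)
        # block resampling with block_len=1 resamples records within units;
        # unit resampling adds between-unit variation: compare magnitudes only
        assert np.mean(w_blk) == pytest.approx(np.mean(w_iid), rel=0.6)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        subjects, x, y1, y2 = boot_data(rng, n_rec=20)
        a = zdiff_ci_moving_block(subjects, x, y1, y2, n_boot=100, seed=3)
        b = zdiff_ci_moving_block(subjects, x, y1, y2, n_boot=100, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


# ---------------------------------------------------------------------------
# Paired t and Mann-Whitney
# ---------------------------------------------------------------------------

def paired_t_oracle(a, b):
    d = a - b
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    from scipy import stats as sps
    return t, 2 * sps.t.sf(abs(t), n - 1)


class TestPairedT:
    def frame(self, col):
        return pd.DataFrame({"T": col}, index=[f"s{i}" for i in range(len(col))])

    def test_tiny_variance_large_t(self):
        a = self.frame([0.5, 0.5, 0.5, 0.5001, 0.4999])
        b = self.frame([0.4, 0.4, 0.4, 0.4, 0.4])
        res = paired_t_peak_dice(a, b)
        assert res.loc[0, "p"] < 1e-6

    def test_antisymmetric_differences(self):
        a = self.frame([0.5, 0.6, 0.4, 0.55, 0.45])
        b = self.frame([0.5, 0.4, 0.6, 0.45, 0.55])
        res = paired_t_peak_dice(a, b)
        assert res.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(12)
        av, bv = rng.random(10), rng.random(10)
        res = paired_t_peak_dice(self.frame(av), self.frame(bv))
        t, p = paired_t_oracle(av, bv)
        assert abs(res.loc[0, "t"] - t) < 1e-12
        assert abs(res.loc[0, "p"] - p) < 1e-12

    def test_zero_variance_errors(self):
        a = self.frame([0.5, 0.6, 0.7])
        b = self.frame([0.4, 0.5, 0.6])  # constant difference
        with pytest.raises(DegenerateDataError):
            paired_t_peak_dice(a, b)


def mw_enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = sum(x > y for x in a for y in b)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        ga = pooled[list(comb)]
        gb = np.delete(pooled, list(comb))
        us.append(sum(x > y for x in ga for y in gb))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestMannWhitney:
    def wrap(self, a, b, m=1):
        ca = pd.DataFrame({"T": a})
        cb = pd.DataFrame({"T": b})
        return mannwhitney_tracts(ca, cb, m_tests=m)[0]

    def test_separated_groups(self):
        res = self.wrap([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.U == 0.0
        assert res.p_raw == pytest.approx(0.1)

    def test_interleaved_groups(self):
        res = self.wrap([1.0, 4.0], [2.0, 3.0])
        assert res.p_raw == pytest.approx(1.0)

    def test_bonferroni(self):
        # raw p 0.1 with m=3 -> 0.3; significance threshold respected
        res = self.wrap([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], m=3)
        assert res.p_corrected == pytest.approx(0.3)
        assert not res.significant

    def test_corrected_capped_at_one(self):
        res = self.wrap([1.0, 4.0], [2.0, 3.0], m=12)
        assert res.p_corrected == 1.0

    def test_all_identical_p_one(self):
        res = self.wrap([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.p_raw == 1.0 and not res.significant

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for n1, n2 in [(2, 3), (3, 3), (4, 2), (4, 4), (5, 3)]:
            a = rng.random(n1)
            b = rng.random(n2)
            res = self.wrap(list(a), list(b))
            assert res.p_raw == pytest.approx(mw_enumeration_p(a, b), abs=1e-12)
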