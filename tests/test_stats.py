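"""Statistical layer, each operation validated against an independent oracle."""

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from alphasep import (
    bh_fdr,
    holm_adjust,
    one_sample_t,
    partial_spearman,
    rm_anova_oneway,
)


# ---------------------------------------------------------------- oracles
def _bh_oracle(p, q):
    """Literal step-up scan."""
    p = np.asarray(p)
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    k = 0
    for i in range(1, m + 1):
        if ranked[i - 1] <= i * q / m:
            k = i
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    adj = np.empty(m)
    for pos, i in enumerate(order):
        adj[i] = min(1.0, min(m * ranked[j] / (j + 1) for j in range(pos, m)))
    return reject, adj


def _holm_oracle(p):
    p = np.asarray(p)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for pos, i in enumerate(order):
        running = max(running, (m - pos) * p[i])
        adj[i] = min(1.0, running)
    return adj


def _rm_anova_oracle(x):
    """Brute-force sums-of-squares decomposition, cell by cell."""
    n, k = x.shape
    grand = x.mean()
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return f


def _partial_spearman_oracle(x, y, cov):
    """Explicit rank residual regression then Pearson correlation."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rc = sps.rankdata(cov)
    design = np.column_stack([np.ones(len(x)), rc])
    ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    return np.corrcoef(ex, ey)[0, 1]


# ------------------------------------------------------------------ tests
class TestOneSampleT:
    def test_symmetric_sample_gives_t_zero_p_one(self):
        res = one_sample_t([-1.0, 1.0], 0.0, "two")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        res = one_sample_t([1.0, 2.0, 3.0], 0.0, "two")
        assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.df == 2

    def test_p_matches_quadrature_of_t_density(self):
        res = one_sample_t([0.3, 1.1, -0.4, 0.9, 0.2], 0.0, "two")
        df = res.df
        dens = lambda u: sps.t.pdf(u, df)  # noqa: E731
        tail, _ = integrate.quad(dens, abs(res.statistic), np.inf)
        assert res.p_value == pytest.approx(2 * tail, abs=1e-8)

    def test_one_tailed_is_half_two_tailed_in_hypothesised_direction(self):
        x = [0.5, 1.2, 0.8, 1.5]
        assert one_sample_t(x, 0, "one").p_value == pytest.approx(
            one_sample_t(x, 0, "two").p_value / 2
        )

    def test_matches_scipy(self, rng):
        x = rng.standard_normal(15) + 0.4
        res = one_sample_t(x, 0.1, "two")
        ref = sps.ttest_1samp(x, 0.1)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_type_one_error_calibration(self):
        """At mu0 = true mean, the 0.05-level test rejects at rate 0.05 +/- 0.01."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal((10_000, 20))
        rate = np.mean(
            [one_sample_t(row, 0.0, "two").p_value < 0.05 for row in x]
        )
        assert abs(rate - 0.05) < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0], 0.0)


class TestBhFdr:
    def test_all_rejected_when_under_stepup_thresholds(self):
        reject, _ = bh_fdr([0.01, 0.02, 0.03, 0.04], 0.05)
        assert reject.all()

    def test_single_p_reduces_to_plain_threshold(self):
        reject, adj = bh_fdr([0.04], 0.05)
        assert reject[0] and adj[0] == pytest.approx(0.04)

    def test_largest_i_scan_can_fail_everywhere(self):
        reject, _ = bh_fdr([0.04, 0.9], 0.05)
        assert not reject.any()

    def test_matches_statsmodels_and_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 12))
            reject, adj = bh_fdr(p, 0.05)
            o_rej, o_adj = _bh_oracle(p, 0.05)
            np.testing.assert_array_equal(reject, o_rej)
            np.testing.assert_allclose(adj, o_adj, atol=1e-10)
            sm_rej, sm_adj, *_ = multipletests(p, 0.05, method="fdr_bh")
            np.testing.assert_array_equal(reject, sm_rej)
            np.testing.assert_allclose(adj, sm_adj, atol=1e-10)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], 0.05)


class TestHolm:
    def test_two_p_hand_values(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.3]), [0.3])

    def test_matches_statsmodels_and_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 12))
            adj = holm_adjust(p)
            np.testing.assert_allclose(adj, _holm_oracle(p), atol=1e-10)
            _, sm_adj, *_ = multipletests(p, 0.05, method="holm")
            np.testing.assert_allclose(adj, sm_adj, atol=1e-10)

    def test_adjusted_at_least_raw_and_dominates_bh(self, rng):
        for _ in range(50):
            p = rng.uniform(size=8)
            holm = holm_adjust(p)
            _, bh = bh_fdr(p, 0.05)
            assert np.all(holm >= p - 1e-15)
            assert np.all(holm >= bh - 1e-12)


class TestRmAnova:
    def test_identical_columns_give_f_zero_p_one(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova_oneway(x)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_two_conditions_equal_squared_paired_t(self, rng):
        x = rng.standard_normal((12, 2))
        res = rm_anova_oneway(x)
        t = sps.ttest_rel(x[:, 0], x[:, 1])
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_brute_force_and_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        for _ in range(100):
            x = rng.standard_normal((rng.integers(3, 9), rng.integers(2, 5)))
            res = rm_anova_oneway(x)
            assert res.statistic == pytest.approx(_rm_anova_oracle(x), rel=1e-10)
        x = rng.standard_normal((8, 3)) + [0.0, 0.3, 0.6]
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "cond": np.tile(np.arange(3), 8),
                "y": x.ravel(),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        res = rm_anova_oneway(x)
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-8)

    def test_missing_cells_rejected(self):
        x = np.ones((3, 3))
        x[1, 1] = np.nan
        with pytest.raises(ValueError):
            rm_anova_oneway(x)


class TestPartialSpearman:
    def test_monotone_identity_gives_one(self, rng):
        x = np.sort(rng.standard_normal(30))
        cov = rng.standard_normal(30)
        res = partial_spearman(x, np.exp(x), cov)
        assert res.statistic == pytest.approx(1.0, abs=1e-10)

    def test_antimonotone_gives_minus_one(self, rng):
        x = np.sort(rng.standard_normal(30))
        cov = rng.standard_normal(30)
        res = partial_spearman(x, -(x**3), cov)
        assert res.statistic == pytest.approx(-1.0, abs=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            cov = rng.standard_normal(n)
            res = partial_spearman(x, y, cov)
            assert res.statistic == pytest.approx(
                _partial_spearman_oracle(x, y, cov), abs=1e-12
            )

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        n = 50
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(n),
                "y": rng.standard_normal(n),
                "c": rng.standard_normal(n),
            }
        )
        res = partial_spearman(df["x"], df["y"], df["c"])
        ref = pg.partial_corr(df, x="x", y="y", covar="c", method="spearman")
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_categorical_covariate_uses_indicator_encoding(self, rng):
        n = 60
        dataset = np.repeat(["a", "b", "c"], n // 3)
        shift = {"a": 0.0, "b": 2.0, "c": -1.0}
        x = rng.standard_normal(n) + [shift[d] for d in dataset]
        y = 0.5 * x + rng.standard_normal(n)
        res = partial_spearman(x, y, dataset)
        assert res.df == n - 2 - 2  # two indicator columns
        assert 0 < res.statistic <= 1

    def test_constant_covariate_contribution_equals_plain_spearman(self, rng):
        n = 40
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        cov = np.full(n, 3.14)
        # A constant covariate adds nothing beyond the intercept: the partial
        # correlation equals the plain Spearman rho.
        res = partial_spearman(x, y, np.column_stack([cov]))
        rho = sps.spearmanr(x, y).statistic
        assert res.statistic == pytest.approx(rho, abs=1e-10)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            partial_spearman([1, 2, 3], [1, 2, 3], [1, 2, 3])
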