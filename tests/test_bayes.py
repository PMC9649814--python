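"""Bayes factors against independent oracles; power; descriptives; gates."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from numsense import bayes as b
from numsense.exceptions import CollinearityError, InsufficientDataError

LOG10 = math.log(10)


# ---------------------------------------------------------------------------
# independent quadrature oracles (trapezoid on fine fixed grids)


def oracle_jzs_ttest(t, n1, n2, r=0.707, npts=100_000):
    neff = n1 * n2 / (n1 + n2)
    df = n1 + n2 - 2
    u = np.linspace(1e-9, 1 - 1e-9, npts)
    g = u / (1 - u)
    jac = 1.0 / (1 - u) ** 2
    lik = (1 + neff * g) ** -0.5 * (1 + t * t / ((1 + neff * g) * df)) ** (-(df + 1) / 2)
    prior = (
        (r * r / 2) ** 0.5 / special.gamma(0.5) * g ** -1.5 * np.exp(-r * r / (2 * g))
    )
    num = np.trapezoid(lik * prior * jac, u)
    den = (1 + t * t / df) ** (-(df + 1) / 2)
    return math.log10(num / den)


def oracle_pearson(r_obs, n, width=1.0, npts=100_000):
    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, npts)
    a = 1.0 / width
    prior = stats.beta.pdf((rho + 1) / 2, a, a) / 2
    lik = (
        (1 - rho**2) ** ((n - 1) / 2)
        * (1 - rho * r_obs) ** (1.5 - n)
        * special.hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r_obs) / 2)
    )
    lik0 = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    return math.log10(np.trapezoid(lik / lik0 * prior, rho))


def oracle_kendall(tau, n, width=1.0, npts=100_000):
    se0 = math.sqrt(2 * (2 * n + 5) / (9 * n * (n - 1)))
    t_star = tau / se0
    tgrid = np.linspace(-1 + 1e-9, 1 - 1e-9, npts)
    a = 1.0 / width
    prior = stats.beta.pdf((tgrid + 1) / 2, a, a) / 2
    lik = stats.norm.pdf(t_star, loc=1.5 * tgrid * math.sqrt(n))
    return math.log10(np.trapezoid(lik * prior, tgrid) / stats.norm.pdf(t_star))


def oracle_contingency_indep(tab, a=1.0, npts=200_000):
    """2x2 rows-fixed Bayes factor by direct numerical integration of the
    binomial likelihoods over Beta(a, a) priors."""
    tab = np.asarray(tab, float)
    th = np.linspace(1e-12, 1 - 1e-12, npts)
    w = stats.beta.pdf(th, a, a)
    m1 = 1.0
    for y1, y2 in tab:
        m1 *= np.trapezoid(th**y1 * (1 - th) ** y2 * w, th)
    c1, c2 = tab.sum(axis=0)
    m0 = np.trapezoid(th**c1 * (1 - th) ** c2 * w, th)
    return math.log10(m1 / m0)


def oracle_two_model_ancova(y, group01, r_fixed=0.5, npts=100_000):
    """Direct BF of {group} vs intercept-only under the JZS one-g prior."""
    y = np.asarray(y, float)
    yc = y - y.mean()
    x = np.where(group01, 0.5, -0.5)
    x = r_fixed * (x - x.mean())
    n = len(y)
    xtx = float(x @ x)
    xty = float(x @ yc)
    yy = float(yc @ yc)
    u = np.linspace(1e-9, 1 - 1e-9, npts)
    g = u / (1 - u)
    jac = 1.0 / (1 - u) ** 2
    q = (1 + g * xtx) ** -0.5 * (1 - g * xty**2 / ((1 + g * xtx) * yy)) ** (-(n - 1) / 2)
    prior = (0.5) ** 0.5 / special.gamma(0.5) * g**-1.5 * np.exp(-0.5 / g)
    return math.log10(np.trapezoid(q * prior * jac, u))


def exact_rank_bf(x, y, r=0.707):
    """Exact rank-likelihood Bayes factor at small n: ordering probabilities
    by sequential integration, then quadrature over the Cauchy prior."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    signs = np.where(order < n1, 0.5, -0.5)
    grid = np.linspace(-12, 12, 4001)
    dg = grid[1] - grid[0]

    def ordering_prob(mus):
        F = np.ones_like(grid)
        for mu in mus:
            integrand = stats.norm.pdf(grid - mu) * F
            F = np.concatenate([[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2 * dg)])
        return F[-1]

    deltas = np.linspace(-12, 12, 121)
    probs = np.array([ordering_prob(signs * d) for d in deltas])
    prior = stats.cauchy.pdf(deltas, 0, r)
    tail = probs[0] * stats.cauchy.cdf(-12, 0, r) + probs[-1] * stats.cauchy.sf(12, 0, r)
    return math.log10((np.trapezoid(probs * prior, deltas) + tail) / probs[len(deltas) // 2])


# ---------------------------------------------------------------------------


class TestJZSTTest:
    def test_null_effect_favors_null(self):
        x = np.arange(20.0)
        assert b.lbf_ttest_two_sample(x, x[::-1]).lbf < 0

    def test_oracle_equivalence(self):
        for i in range(20):
            rng = np.random.default_rng(i)
            d = rng.uniform(0, 1.5)
            n1, n2 = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            x, y = rng.normal(0, 1, n1), rng.normal(d, 1, n2)
            res = b.lbf_ttest_two_sample(x, y)
            assert abs(res.lbf - oracle_jzs_ttest(res.statistic, n1, n2)) < 1e-3

    def test_monotone_in_t(self):
        lbfs = [b._jzs_log_bf10(t, 20, 20, 0.707) for t in np.linspace(0, 6, 13)]
        assert np.all(np.diff(lbfs) > 0)

    def test_null_consistency_in_n(self):
        lbfs = [b._jzs_log_bf10(0.0, n, n, 0.707) for n in (10, 40, 160, 640)]
        assert np.all(np.diff(lbfs) < 0)

    def test_degenerate_variance(self):
        with pytest.raises(ValueError):
            b.lbf_ttest_two_sample([1.0, 1.0, 1.0], [2.0, 2.0])

    def test_h0_false_positive_rate_bounded(self):
        """Under d=0 (n=20/20), few datasets reach substantial evidence."""
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2000, 2, 20))
        m = data.mean(axis=2)
        v = data.var(axis=2, ddof=1)
        sp = np.sqrt(v.mean(axis=1))
        t = (m[:, 0] - m[:, 1]) / (sp * math.sqrt(2 / 20))
        hits = sum(b._jzs_log_bf10(tt, 20, 20, 0.707) / LOG10 > 0.5 for tt in t)
        assert hits / 2000 < 0.10


class TestMannWhitney:
    def test_identical_samples(self):
        x = np.arange(10.0)
        assert b.lbf_mannwhitney(x, x + 0.01, seed=1, draws=1500).lbf < 0

    def test_large_separation(self):
        x = np.arange(20.0)
        assert b.lbf_mannwhitney(x, x + 100.0, seed=1, draws=1500).lbf > 1

    def test_exact_small_n_oracle(self):
        """Gibbs Savage-Dickey matches the exact rank-likelihood BF."""
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 4), rng.normal(0.8, 1, 4)
        res = b.lbf_mannwhitney(x, y, seed=7, draws=20_000, burn=2000)
        assert abs(res.lbf - exact_rank_bf(x, y)) < max(3 * res.mc_se, 0.02)

    def test_tracks_parametric_on_normal_data(self):
        """On normal data the rank BF tracks the JZS t-test BF closely."""
        tts, mws = [], []
        for i in range(10):
            rng = np.random.default_rng(100 + i)
            d = rng.uniform(0, 0.8)
            x, y = rng.normal(0, 1, 20), rng.normal(d, 1, 20)
            tts.append(b.lbf_ttest_two_sample(x, y).lbf)
            mws.append(b.lbf_mannwhitney(x, y, seed=200 + i, draws=3000).lbf)
        assert stats.kendalltau(tts, mws).statistic >= 0.8
        assert np.max(np.abs(np.array(tts) - np.array(mws))) < 0.4

    def test_reports_mc_se(self):
        res = b.lbf_mannwhitney(np.arange(8.0), np.arange(8.0) + 1, seed=2, draws=1500)
        assert res.mc_se is not None and res.mc_se > 0


class TestPearson:
    def test_zero_correlation_favors_null(self):
        x = np.arange(20.0)
        y = (x - x.mean()) ** 2  # exactly uncorrelated with x
        assert abs(np.corrcoef(x, y)[0, 1]) < 1e-12
        assert b.lbf_pearson(x, y).lbf < 0

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert b.lbf_pearson(x, x).lbf > 1

    def test_oracle_equivalence(self):
        for i in range(20):
            rng = np.random.default_rng(50 + i)
            rho = rng.uniform(-0.8, 0.8)
            n = int(rng.integers(10, 60))
            cov = [[1, rho], [rho, 1]]
            x, y = rng.multivariate_normal([0, 0], cov, n).T
            res = b.lbf_pearson(x, y)
            assert abs(res.lbf - oracle_pearson(res.statistic, n)) < 1e-3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            b.lbf_pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKendall:
    def test_brute_force_tau_example(self):
        assert b.kendall_tau_exact([1, 2, 3], [2, 1, 3]) == pytest.approx(1 / 3)

    def test_brute_force_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            x = rng.integers(0, 5, n).astype(float)  # ties included
            y = rng.integers(0, 5, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert b.kendall_tau_exact(x, y) == pytest.approx(
                stats.kendalltau(x, y).statistic
            )

    def test_perfect_concordance(self):
        res = b.lbf_kendall(np.arange(10.0), np.arange(10.0))
        assert res.statistic == pytest.approx(1.0)
        assert res.lbf > 0

    def test_oracle_equivalence(self):
        for i in range(20):
            rng = np.random.default_rng(80 + i)
            rho = rng.uniform(-0.8, 0.8)
            n = int(rng.integers(10, 60))
            x, y = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], n).T
            res = b.lbf_kendall(x, y)
            assert abs(res.lbf - oracle_kendall(res.statistic, n)) < 1e-3

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            b.lbf_kendall([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestContingency:
    def test_exact_independence_favors_null(self):
        assert b.lbf_contingency_2x2([[10, 10], [10, 10]]).lbf < 0

    def test_perfect_association(self):
        assert b.lbf_contingency_2x2([[20, 0], [0, 20]]).lbf > 1

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tab = rng.integers(1, 30, (2, 2))
            res = b.lbf_contingency_2x2(tab)
            assert abs(res.lbf - oracle_contingency_indep(tab)) < 1e-3

    def test_transpose_and_swap_invariance(self):
        tab = np.array([[14, 6], [9, 11]])
        base = b.lbf_contingency_2x2(tab).lbf
        assert b.lbf_contingency_2x2(tab.T).lbf == pytest.approx(
            b.lbf_contingency_2x2(tab.T).lbf
        )
        assert b.lbf_contingency_2x2(tab[::-1]).lbf == pytest.approx(base)
        assert b.lbf_contingency_2x2(tab[:, ::-1]).lbf == pytest.approx(base)

    def test_study_sex_table_is_weak_evidence(self):
        """The study's sex split (14M/6F vs 9M/11F) is weak evidence either
        way under the default contingency model."""
        res = b.lbf_contingency_2x2([[14, 6], [9, 11]])
        assert res.label.category == "inconclusive"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            b.lbf_contingency_2x2([[1, 2], [3, 4]], a=0)
        with pytest.raises(ValueError):
            b.lbf_contingency_2x2([[0, 0], [1, 2]])

    def test_multinomial_onesample(self):
        res = b.lbf_multinomial([30, 10], [0.5, 0.5])
        assert res.lbf > 0  # clearly unequal counts
        assert b.lbf_multinomial([20, 20], [0.5, 0.5]).lbf < 0


class TestAncova:
    def make_data(self, seed=0, n=40, beta_g=1.0):
        rng = np.random.default_rng(seed)
        group = np.repeat([1, 0], n // 2)
        cov = rng.normal(0, 1, n)
        y = beta_g * group + rng.normal(0, 1, n)
        return pd.DataFrame(
            {"dv": y, "group": np.where(group == 1, "ADHD", "control"), "cov": cov}
        )

    def test_two_model_reduction_oracle(self):
        """With no covariates the inclusion BF equals the direct two-model
        BF computed by independent quadrature."""
        for i in range(20):
            df = self.make_data(seed=i, beta_g=float(i % 4) / 3)
            inc = b.lbf_ancova_inclusion(df, "dv")["group"]
            direct = oracle_two_model_ancova(
                df["dv"].to_numpy(), (df["group"] == "ADHD").to_numpy()
            )
            assert abs(inc.lbf - direct) < 1e-3

    def test_sign_behavior(self):
        """Strong group effect, pure-noise covariate: group in, noise out."""
        df = self.make_data(seed=1, beta_g=1.5)
        inc = b.lbf_ancova_inclusion(df, "dv", covariates=["cov"])
        assert inc["group"].lbf > 0
        assert inc["cov"].lbf < 0

    def test_true_covariate_included(self):
        rng = np.random.default_rng(4)
        n = 40
        cov = rng.normal(0, 1, n)
        df = pd.DataFrame(
            {
                "dv": 1.2 * cov + rng.normal(0, 0.5, n),
                "group": np.repeat(["ADHD", "control"], n // 2),
                "cov": cov,
            }
        )
        inc = b.lbf_ancova_inclusion(df, "dv", covariates=["cov"])
        assert inc["cov"].lbf > 1

    def test_listwise_deletion(self):
        df = self.make_data(seed=2)
        df.loc[0, "cov"] = np.nan
        inc = b.lbf_ancova_inclusion(df, "dv", covariates=["cov"])
        assert inc["group"].n == (len(df) - 1,)

    def test_collinear_covariates_named(self):
        df = self.make_data(seed=3)
        df["cov2"] = 2 * df["cov"]
        with pytest.raises(CollinearityError) as exc:
            b.lbf_ancova_inclusion(df, "dv", covariates=["cov", "cov2"])
        assert "cov" in str(exc.value)


class TestConservationEverywhere:
    """BF10 * BF01 = 1 for every method (label-swap / negation identity)."""

    def test_ttest_group_swap(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.7, 1, 18)
        assert b.lbf_ttest_two_sample(x, y).lbf == pytest.approx(
            -b.lbf_ttest_two_sample(y, x).swapped().lbf
        )

    def test_swapped_negates(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.7, 1, 18)
        for res in (
            b.lbf_ttest_two_sample(x, y),
            b.lbf_pearson(x[:15], y[:15]),
            b.lbf_kendall(x[:15], y[:15]),
            b.lbf_contingency_2x2([[8, 7], [9, 9]]),
            b.lbf_mannwhitney(x, y, seed=0, draws=1000),
        ):
            assert res.swapped().lbf == -res.lbf
            assert res.bf10 * res.swapped().bf10 == pytest.approx(1.0)


class TestPowerAnalysis:
    def test_required_n_is_20(self):
        assert b.required_n_per_group(b.PowerQuery(d=1.2, alpha=0.05, power=0.95)) == 20

    def test_huge_effect_floor(self):
        assert b.required_n_per_group(b.PowerQuery(d=10.0)) == 2

    def test_monte_carlo_power_agreement(self):
        """Noncentral-t power matches simulation within 3 binomial SEs."""
        n, d, alpha, reps = 20, 1.2, 0.05, 20_000
        rng = np.random.default_rng(1)
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n)) + d
        t = (y.mean(1) - x.mean(1)) / np.sqrt(
            (x.var(1, ddof=1) + y.var(1, ddof=1)) / 2 * (2 / n)
        )
        crit = stats.t.ppf(1 - alpha / 2, 2 * n - 2)
        phat = np.mean(np.abs(t) > crit)
        pth = b.power_two_sample_t(n, d, alpha)
        assert abs(phat - pth) <= 3 * math.sqrt(pth * (1 - pth) / reps)

    def test_invalid_queries(self):
        with pytest.raises(ValueError):
            b.PowerQuery(d=-1)
        with pytest.raises(ValueError):
            b.PowerQuery(d=1, alpha=1.5)


class TestEvidenceLabels:
    @pytest.mark.parametrize(
        "lbf,cat",
        [
            (2.3, "definitive_H1"),
            (1.5, "strong_H1"),
            (0.7, "substantial_H1"),
            (0.5, "inconclusive"),
            (-0.24, "inconclusive"),
            (-0.5, "inconclusive"),
            (-0.7, "substantial_H0"),
            (-1.5, "strong_H0"),
            (-2.5, "definitive_H0"),
        ],
    )
    def test_categories(self, lbf, cat):
        assert b.classify_evidence(lbf).category == cat

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            b.classify_evidence(float("nan"))


class TestDescriptives:
    def test_symmetric_sample(self):
        d = b.describe([1.0, 2.0, 3.0])
        assert (d.mean, d.sd, d.skewness) == (2.0, 1.0, pytest.approx(0.0))

    def test_constant_sample(self):
        d = b.describe([5.0, 5.0, 5.0, 5.0])
        assert d.sd == 0 and d.skewness is None and d.kurtosis is None

    def test_formula_oracle(self):
        """Bias-corrected skewness / excess kurtosis match direct formulas."""
        x = np.random.default_rng(8).normal(2, 3, 20)
        n = len(x)
        m = x.mean()
        m2, m3, m4 = ((x - m) ** 2).mean(), ((x - m) ** 3).mean(), ((x - m) ** 4).mean()
        g1 = m3 / m2**1.5
        G1 = g1 * math.sqrt(n * (n - 1)) / (n - 2)
        g2 = m4 / m2**2 - 3
        G2 = ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
        d = b.describe(x)
        assert d.skewness == pytest.approx(G1, abs=1e-10)
        assert d.kurtosis == pytest.approx(G2, abs=1e-10)

    def test_min_le_mean_le_max(self, rng):
        d = b.describe(rng.normal(0, 1, 50))
        assert d.min <= d.mean <= d.max

    def test_too_small(self):
        with pytest.raises(InsufficientDataError):
            b.describe([1.0])


class TestNormalityGate:
    def test_normal_selects_parametric(self):
        rng = np.random.default_rng(2)
        out = b.check_normality_and_select(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        assert out["selected"] == "parametric"

    def test_skewed_selects_nonparametric(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(1, 20)
        assert stats.shapiro(x).pvalue < 0.05  # verify rejection at this seed
        out = b.check_normality_and_select(x, rng.normal(0, 1, 20))
        assert out["selected"] == "nonparametric"

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        x, y = rng.exponential(1, 20), rng.normal(0, 1, 20)
        a = b.check_normality_and_select(x, y)
        bb = b.check_normality_and_select(y, x)
        assert a["selected"] == bb["selected"]
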