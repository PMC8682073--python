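"""Bayes-factor kernels: Monte-Carlo oracle agreement, limiting behaviour,
symmetries, consistency, and the model-search enumeration."""

import math

import numpy as np
import pytest
from scipy import special, stats

from vascbayes import (
    CorrSummary,
    PriorScale,
    RegressionSummary,
    TTestSummary,
    gprior_regression_bf,
    interpret_bf,
    jzs_ttest_bf,
    model_search,
    nested_model_bf,
    stretched_beta_corr_bf,
)
from vascbayes.bayesfactor import corr_log_density

SQRT2_2 = math.sqrt(2) / 2


# ---------------------------------------------------------------- oracles

def mc_jzs_bf01(t, n1, n2, rscale, n_draws=1_000_000, seed=11):
    """Cauchy-as-inverse-gamma-mixture oracle for the JZS t-test BF."""
    nu = n1 + n2 - 2
    neff = n1 * n2 / (n1 + n2)
    g = stats.invgamma.rvs(0.5, scale=rscale ** 2 / 2, size=n_draws,
                           random_state=np.random.default_rng(seed))
    alt = np.mean((1 + neff * g) ** -0.5
                  * (1 + t ** 2 / ((1 + neff * g) * nu)) ** (-(nu + 1) / 2))
    return (1 + t ** 2 / nu) ** (-(nu + 1) / 2) / alt


def mc_corr_bf01(n, r, kappa, n_draws=1_000_000, seed=12):
    """Prior-draw oracle: average the sampling-density ratio over antithetic
    draws of rho from the stretched-beta prior."""
    rng = np.random.default_rng(seed)
    a = 1 / kappa
    rho = 2 * rng.beta(a, a, size=n_draws) - 1
    rho = np.concatenate([rho, -rho])
    log0 = corr_log_density(r, 0.0, n)
    lg = (math.log(n - 2) + special.gammaln(n - 1)
          + (n - 1) / 2 * np.log1p(-rho ** 2)
          + (n - 4) / 2 * math.log1p(-r * r)
          - 0.5 * math.log(2 * math.pi) - special.gammaln(n - 0.5)
          - (n - 1.5) * np.log1p(-rho * r)
          + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)))
    return 1.0 / np.exp(lg - log0).mean()


def mc_gprior_bf10(n, k, r2, rscale, n_draws=1_000_000, seed=13):
    """Inverse-gamma draws of g, integrand averaged in log space."""
    g = stats.invgamma.rvs(0.5, scale=n * rscale ** 2 / 2, size=n_draws,
                           random_state=np.random.default_rng(seed))
    lv = (n - 1 - k) / 2 * np.log1p(g) - (n - 1) / 2 * np.log1p(g * (1 - r2))
    return math.exp(special.logsumexp(lv) - math.log(n_draws))


@pytest.mark.parametrize("t,n1,n2,scale", [
    (2.0, 15, 15, SQRT2_2),
    (0.8, 66, 21, SQRT2_2),
    (3.1, 40, 40, 1.0),
    (-1.7, 20, 35, 0.4),
])
def test_jzs_matches_mixture_oracle(t, n1, n2, scale):
    bf = jzs_ttest_bf(TTestSummary(n1, n2, t), PriorScale("cauchy_effect", scale))
    oracle = mc_jzs_bf01(t, n1, n2, scale)
    assert bf.bf01 == pytest.approx(oracle, rel=5e-3)


@pytest.mark.parametrize("n,r,kappa", [
    (87, -0.11, 1 / 3),
    (87, 0.3, 1.0),
    (30, 0.55, 0.5),
    (200, -0.05, 1 / 3),
])
def test_corr_matches_prior_draw_oracle(n, r, kappa):
    bf = stretched_beta_corr_bf(CorrSummary(n, r), PriorScale("stretched_beta", kappa))
    oracle = mc_corr_bf01(n, r, kappa)
    assert bf.bf01 == pytest.approx(oracle, rel=5e-3)


@pytest.mark.parametrize("n,k,r2,scale", [
    (50, 2, 0.2, SQRT2_2),
    (87, 3, 0.1, SQRT2_2),
    (87, 1, 0.05, 0.5),
    (30, 4, 0.4, SQRT2_2),
])
def test_gprior_matches_mc_oracle(n, k, r2, scale):
    bf = gprior_regression_bf(RegressionSummary(n, k, r2),
                              PriorScale("g_invgamma", scale))
    oracle = mc_gprior_bf10(n, k, r2, scale)
    assert bf.bf10 == pytest.approx(oracle, rel=5e-3)


# ---------------------------------------------------- limits and symmetries

@pytest.mark.parametrize("make", [
    lambda s: jzs_ttest_bf(TTestSummary(20, 20, 2.5),
                           PriorScale("cauchy_effect", s)),
    lambda s: stretched_beta_corr_bf(CorrSummary(87, 0.3),
                                     PriorScale("stretched_beta", s)),
    lambda s: gprior_regression_bf(RegressionSummary(50, 2, 0.3),
                                   PriorScale("g_invgamma", s)),
])
def test_scale_collapse_toward_unity(make):
    """As the prior scale shrinks the alternative collapses onto the null."""
    assert abs(make(1e-8).log_bf01) < 1e-3


def test_corr_prior_concentration_limit():
    """Shrinking kappa concentrates the prior at rho = 0 and drives the
    Bayes factor to 1; the approach is monotone in |log bf01|."""
    logs = [abs(stretched_beta_corr_bf(CorrSummary(87, 0.3),
                                       PriorScale("stretched_beta", k)).log_bf01)
            for k in (1e-2, 1e-4, 1e-6, 1e-8)]
    assert all(x > y for x, y in zip(logs, logs[1:]))
    assert logs[-1] < 1e-3


def test_null_best_supported_at_t_zero():
    assert jzs_ttest_bf(TTestSummary(10, 10, 0.0)).bf01 > 1


def test_sign_and_label_symmetry():
    a = jzs_ttest_bf(TTestSummary(15, 25, 1.8))
    b = jzs_ttest_bf(TTestSummary(15, 25, -1.8))
    c = jzs_ttest_bf(TTestSummary(25, 15, 1.8))
    assert a.bf01 == pytest.approx(b.bf01, rel=1e-9)
    assert a.bf01 == pytest.approx(c.bf01, rel=1e-9)
    ra = stretched_beta_corr_bf(CorrSummary(40, 0.5))
    rb = stretched_beta_corr_bf(CorrSummary(40, -0.5))
    assert ra.bf01 == pytest.approx(rb.bf01, rel=1e-9)


def test_monotone_in_t_magnitude():
    bfs = [jzs_ttest_bf(TTestSummary(20, 20, t)).bf01
           for t in (0.0, 0.5, 1.0, 2.0, 3.0)]
    assert all(x > y for x, y in zip(bfs, bfs[1:]))


@pytest.mark.parametrize("family", ["ttest", "corr"])
def test_evidence_accumulates_with_n(family):
    """A fixed nonzero effect drives bf01 to 0 as n grows."""
    vals = []
    for n in (20, 50, 100, 500):
        if family == "ttest":
            t = 0.5 * math.sqrt(n * n / (2 * n))  # d=0.5 at balanced n
            vals.append(jzs_ttest_bf(TTestSummary(n, n, t)).bf01)
        else:
            vals.append(stretched_beta_corr_bf(CorrSummary(n, 0.3)).bf01)
    assert all(x > y for x, y in zip(vals, vals[1:]))


def test_corr_sampling_density_matches_simulation(rng):
    """The implemented p(r | rho, n) against 1e5 simulated r values."""
    n, rho, reps = 30, 0.5, 100_000
    z = rng.normal(size=(reps, n, 2))
    x = z[:, :, 0]
    y = rho * x + math.sqrt(1 - rho ** 2) * z[:, :, 1]
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = np.sum(xc * yc, 1) / np.sqrt(np.sum(xc ** 2, 1) * np.sum(yc ** 2, 1))
    grid = np.linspace(-0.999, 0.999, 4001)
    pdf = np.exp([corr_log_density(g, rho, n) for g in grid])
    cdf = np.concatenate([[0], np.cumsum((pdf[1:] + pdf[:-1]) / 2
                                         * np.diff(grid))])
    cdf /= cdf[-1]
    stat, p = stats.ks_1samp(r, lambda v: np.interp(v, grid, cdf))
    assert p > 0.01


# ------------------------------------------------------------- regression

def test_intercept_only_is_its_own_null():
    assert gprior_regression_bf(RegressionSummary(50, 0, 0.0)).bf01 == 1.0


def test_zero_r2_penalised_by_occam():
    assert gprior_regression_bf(RegressionSummary(50, 3, 0.0)).bf01 > 1


def test_nested_identity_and_reciprocal():
    full = RegressionSummary(87, 3, 0.25)
    null = RegressionSummary(87, 2, 0.20)
    same = nested_model_bf(full, full)
    assert same.bf01 == pytest.approx(1.0, abs=1e-10)
    vs_intercept = nested_model_bf(full, RegressionSummary(87, 0, 0.0))
    assert vs_intercept.bf01 == pytest.approx(
        1 / gprior_regression_bf(full).bf10, rel=1e-9)
    res = nested_model_bf(full, null)
    assert res.bf01 == pytest.approx(
        gprior_regression_bf(full).bf10 ** -1 * gprior_regression_bf(null).bf10,
        rel=1e-9)


def test_nested_rejects_non_nested():
    with pytest.raises(ValueError):
        nested_model_bf(RegressionSummary(87, 3, 0.1),
                        RegressionSummary(87, 2, 0.2))
    with pytest.raises(ValueError):
        nested_model_bf(RegressionSummary(87, 3, 0.3),
                        RegressionSummary(50, 2, 0.2))


def test_pure_noise_covariate_favours_null(rng):
    """Adding a noise covariate to a true model: the simpler model wins on
    median over seeded replicates."""
    n = 87
    vals = []
    for _ in range(100):
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        noise = rng.normal(size=n)
        null = RegressionSummary.from_fit(y, x)
        full = RegressionSummary.from_fit(y, np.column_stack([x, noise]))
        vals.append(nested_model_bf(full, null).bf01)
    assert np.median(vals) > 1


# ------------------------------------------------------------ model search

def test_model_search_enumerates_all_subsets(rng):
    import pandas as pd
    y = rng.normal(size=40)
    cands = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
    table = model_search(y, cands)
    assert len(table) == 4
    assert ((), 0) in zip(table["covariates"], table["k"])
    inter = table[table["k"] == 0].iloc[0]
    assert inter["bf10"] == pytest.approx(1.0)
    assert (table["bf10"].to_numpy()[:-1] >= table["bf10"].to_numpy()[1:] - 1e-12).all()


def test_model_search_null_and_recovery(rng):
    import pandas as pd
    n = 87
    top_is_intercept = 0
    hits = 0
    for _ in range(100):
        cands = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y_null = rng.normal(size=n)
        if model_search(y_null, cands).iloc[0]["covariates"] == ():
            top_is_intercept += 1
        y_sig = 1.0 * cands["b"].to_numpy() + rng.normal(size=n)
        if "b" in model_search(y_sig, cands).iloc[0]["covariates"]:
            hits += 1
    assert top_is_intercept > 50
    assert hits >= 95


def test_model_search_flags_rank_deficiency(rng):
    import pandas as pd
    x = rng.normal(size=30)
    cands = pd.DataFrame({"a": x, "b": 2 * x})
    table = model_search(rng.normal(size=30), cands)
    flagged = table[table["rank_deficient"]]
    assert list(flagged["covariates"]) == [("a", "b")]


# ------------------------------------------------------------- guards, misc

def test_summary_validation():
    with pytest.raises(ValueError):
        TTestSummary(1, 10, 2.0)
    with pytest.raises(ValueError):
        TTestSummary(10, 10, float("nan"))
    with pytest.raises(ValueError):
        CorrSummary(3, 0.5)
    with pytest.raises(ValueError):
        CorrSummary(50, 1.0)
    with pytest.raises(ValueError):
        RegressionSummary(10, 9, 0.5)
    with pytest.raises(ValueError):
        PriorScale("stretched_beta", 1.5)
    with pytest.raises(ValueError):
        PriorScale("cauchy_effect", -1.0)


def test_interpret_bf_bands():
    assert interpret_bf(3.4) == "moderate evidence for null"
    assert interpret_bf(1.0) == "equivocal"
    assert interpret_bf(0.2) == "moderate evidence for alternative"
    assert interpret_bf(2.0) == "weak evidence for null"
    assert interpret_bf(50.0) == "strong evidence for null"
    with pytest.raises(ValueError):
        interpret_bf(0.0)
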