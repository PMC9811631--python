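"""The REML/ML engine against independent oracles.

Oracles: the closed-form ANOVA estimators on balanced one-way layouts; the
brute-force multivariate-normal density of orthonormal error contrasts for
the restricted likelihood; and statsmodels MixedLM for the ML path.
"""

import numpy as np
import pytest
from scipy.linalg import null_space
from scipy.stats import multivariate_normal

from rhizosge.reml import (
    LRTResult,
    MixedModel,
    RandomTerm,
    VarianceComponentFit,
    likelihood_ratio_test,
)


def _balanced_oneway(rng, g, m, sd_b, sd_e):
    groups = np.repeat(np.arange(g), m)
    y = 3.0 + rng.normal(0, sd_b, g)[groups] + rng.normal(0, sd_e, g * m)
    return y, groups


def _anova_estimates(y, groups, g, m):
    means = np.array([y[groups == i].mean() for i in range(g)])
    msb = m * np.sum((means - y.mean()) ** 2) / (g - 1)
    msw = sum(((y[groups == i] - means[i]) ** 2).sum() for i in range(g)) / (g * (m - 1))
    return (msb - msw) / m, msw


@pytest.mark.parametrize("trial", range(5))
def test_balanced_oneway_matches_anova(trial, rng):
    """REML equals the closed-form ANOVA estimators on balanced one-way data."""
    g, m = 10, 10
    y, groups = _balanced_oneway(rng, g, m, sd_b=1.5, sd_e=1.0)
    fit = MixedModel(y, np.ones((g * m, 1)),
                     [RandomTerm.from_codes("grp", groups)]).fit()
    s2b, s2e = _anova_estimates(y, groups, g, m)
    assert fit.components["grp"] == pytest.approx(s2b, rel=1e-6)
    assert fit.resid == pytest.approx(s2e, rel=1e-6)


def _brute_force_restricted_loglik(y, X, V):
    """Density of orthonormal error contrasts K'y, K spanning null(X')."""
    K = null_space(X.T)
    return multivariate_normal(
        mean=np.zeros(K.shape[1]), cov=K.T @ V @ K).logpdf(K.T @ y)


@pytest.mark.parametrize("signed", [False, True])
def test_restricted_loglik_matches_brute_force(signed, rng):
    """Woodbury-based restricted likelihood equals the dense MVN contrast density,
    including for signed (+1/-1) incidence as used by the constrained models."""
    n, levels = 24, 5
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    codes = rng.integers(0, levels, n)
    if signed:
        signs = rng.choice([-1.0, 1.0], n)
        Z = RandomTerm.from_codes("t", codes, signs=signs).Z
    else:
        Z = RandomTerm.from_codes("t", codes).Z
    y = rng.normal(size=n) + Z @ rng.normal(0, 1.0, levels)
    model = MixedModel(y, X, [RandomTerm("t", Z)])
    for gamma, s2 in [(0.3, 0.8), (1.7, 2.5), (1e-6, 1.0)]:
        V = s2 * (np.eye(n) + gamma * Z @ Z.T)
        brute = _brute_force_restricted_loglik(y, X, V)
        assert -0.5 * model.neg2_reml([gamma], resid=s2) == pytest.approx(brute, abs=1e-8)


def test_ml_loglik_matches_brute_force(rng):
    """ML mode equals the plain MVN density at the GLS fixed-effect estimate."""
    n, levels = 20, 4
    X = np.ones((n, 1))
    codes = rng.integers(0, levels, n)
    Z = RandomTerm.from_codes("t", codes).Z
    y = 2.0 + rng.normal(size=n) + Z @ rng.normal(0, 1.2, levels)
    model = MixedModel(y, X, [RandomTerm("t", Z)])
    gamma, s2 = 0.9, 1.1
    V = s2 * (np.eye(n) + gamma * Z @ Z.T)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    brute = multivariate_normal(mean=(X @ beta).ravel(), cov=V).logpdf(y)
    assert -0.5 * model.neg2_ml([gamma], resid=s2) == pytest.approx(brute, abs=1e-8)


def test_ml_fit_matches_statsmodels(rng):
    """Full ML fit agrees with statsmodels MixedLM on a one-term model."""
    import statsmodels.api as sm

    g, m = 8, 12
    y, groups = _balanced_oneway(rng, g, m, sd_b=1.2, sd_e=0.9)
    fit = MixedModel(y, np.ones(y.size)[:, None],
                     [RandomTerm.from_codes("grp", groups)]).fit(method="ml")
    sm_fit = sm.MixedLM(y, np.ones(y.size)[:, None], groups=groups).fit(reml=False)
    assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
    assert fit.components["grp"] == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-3)
    assert fit.resid == pytest.approx(sm_fit.scale, rel=1e-3)


def test_null_structure_hits_boundary(rng):
    """With no true group variance, the group estimate sits at zero and the
    residual near the sample variance."""
    n = 200
    y = rng.normal(0, 2.0, n)
    codes = rng.integers(0, 10, n)
    fit = MixedModel(y, np.ones((n, 1)),
                     [RandomTerm.from_codes("grp", codes)]).fit()
    assert fit.components["grp"] <= 0.05 * y.var()
    assert fit.resid == pytest.approx(y.var(ddof=1), rel=0.1)


def test_loglik_monotone_under_nesting(rng):
    """Adding a random term can only increase the restricted likelihood."""
    n = 60
    X = np.ones((n, 1))
    t1 = RandomTerm.from_codes("a", rng.integers(0, 6, n))
    t2 = RandomTerm.from_codes("b", rng.integers(0, 5, n))
    y = (rng.normal(size=n) + t1.Z @ rng.normal(0, 1, 6) + t2.Z @ rng.normal(0, 0.5, 5))
    full = MixedModel(y, X, [t1, t2]).fit()
    reduced = MixedModel(y, X, [t1]).fit()
    lrt = likelihood_ratio_test(full, reduced)
    assert lrt.chi2 >= 0.0
    assert 0.0 <= lrt.p_value <= 1.0


def test_lrt_definition_and_identity():
    def fake(ll):
        return VarianceComponentFit(components={}, resid=1.0, loglik=ll, method="reml",
                                    converged=True, n_iter=1, n_obs=10)

    res = likelihood_ratio_test(fake(-10.0), fake(-15.0))
    assert res.chi2 == pytest.approx(10.0)
    same = likelihood_ratio_test(fake(-10.0), fake(-10.0))
    assert same.chi2 == 0.0 and same.p_value == pytest.approx(1.0)
    assert isinstance(res, LRTResult)


def test_model_validation_errors(rng):
    y = rng.normal(size=10)
    term = RandomTerm.from_codes("g", rng.integers(0, 3, 10))
    with pytest.raises(ValueError, match="rank deficient"):
        MixedModel(y, np.ones((10, 2)), [term])
    model = MixedModel(y, np.ones((10, 1)), [term])
    with pytest.raises(ValueError, match="residual"):
        model.drop_term("residual")
    with pytest.raises(KeyError):
        model.drop_term("nope")
    with pytest.raises(ValueError, match="only random term"):
        model.drop_term("g")
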