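"""Penalized weight estimation against closed-form and external oracles."""

import shutil
import subprocess

import numpy as np
import pytest

from grsxe.core import GenotypeMatrix
from grsxe.simulation import ScenarioConfig, simulate_study
from grsxe.weighting import (
    FitError,
    fit_penalized_interaction,
    fit_penalized_marginal,
    make_split,
    weights_interaction_training,
    weights_marginal_internal,
)

from .conftest import make_genotypes


def _toy(n=100, k=3, seed=0, beta=(1.0, -0.5, 0.0), sd=1.0):
    rng = np.random.default_rng(seed)
    G = make_genotypes(rng.binomial(2, 0.3, size=(n, k)))
    y = 0.5 + G.dosages @ np.asarray(beta[:k]) + sd * rng.standard_normal(n)
    return G, y


# ---------------------------------------------------------------------------
# closed-form oracles


def test_lambda_zero_equals_ols():
    """At zero penalty the fit is ordinary least squares (normal equations)."""
    G, y = _toy(n=100, k=3, seed=1)
    fit = fit_penalized_marginal(G, y, alpha=0.5, lambda_=0.0)
    Z = np.column_stack([np.ones(G.n), G.dosages])
    beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
    assert fit.intercept == pytest.approx(beta[0], rel=1e-8)
    np.testing.assert_allclose(fit.snp_main, beta[1:], rtol=1e-8)


def test_small_lambda_converges_to_ols():
    G, y = _toy(n=120, k=4, seed=2, beta=(1.0, -0.5, 0.3, 0.0))
    fit = fit_penalized_marginal(G, y, alpha=0.5, lambda_=1e-8)
    Z = np.column_stack([np.ones(G.n), G.dosages])
    beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
    np.testing.assert_allclose(fit.snp_main, beta[1:], rtol=1e-4)


def test_scalar_ridge_closed_form():
    """alpha=0, one predictor: beta = beta_OLS / (1 + lambda) on the
    standardized scale, i.e. beta_OLS * n / (n + lambda * c) with c = n
    under the 1/(2n) loss convention."""
    rng = np.random.default_rng(3)
    n = 200
    x = rng.binomial(2, 0.4, size=n).astype(float)
    y = 1.0 + 0.8 * x + rng.standard_normal(n)
    G = make_genotypes(x[:, None].astype(np.int8))
    xs = (x - x.mean()) / x.std()
    beta_ols_std = xs @ (y - y.mean()) / n
    for lam in (0.1, 0.5, 2.0):
        fit = fit_penalized_marginal(G, y, alpha=0.0, lambda_=lam)
        expected = (beta_ols_std / (1.0 + lam)) / x.std()
        assert fit.snp_main[0] == pytest.approx(expected, rel=1e-10)


def test_lasso_stationarity_at_fixed_lambda():
    """KKT conditions of the lasso hold at the returned coefficients."""
    G, y = _toy(n=150, k=5, seed=4, beta=(1.0, -0.8, 0.4, 0.0, 0.0))
    lam = 0.1
    fit = fit_penalized_marginal(G, y, alpha=1.0, lambda_=lam)
    X = G.dosages.astype(float)
    Xs = (X - X.mean(0)) / X.std(0)
    beta_std = fit.snp_main * X.std(0)
    r = (y - y.mean()) - Xs @ beta_std
    grad = Xs.T @ r / G.n
    for j in range(G.k):
        if beta_std[j] == 0.0:
            assert abs(grad[j]) <= lam + 1e-6
        else:
            assert grad[j] == pytest.approx(lam * np.sign(beta_std[j]), abs=1e-6)


def test_null_signal_shrinks_to_zero():
    rng = np.random.default_rng(5)
    G = make_genotypes(rng.binomial(2, 0.3, size=(500, 12)))
    y = rng.standard_normal(500)
    fit = fit_penalized_marginal(G, y, alpha=0.5, cv_folds=10, seed=5)
    assert np.count_nonzero(fit.snp_main) <= 1


def test_objective_no_worse_than_zero_vector():
    G, y = _toy(n=200, k=6, seed=6, beta=(1.0, -0.5, 0.3, 0.0, 0.0, 0.0))
    fit = fit_penalized_marginal(G, y, alpha=0.5, cv_folds=5, seed=6)
    X = G.dosages.astype(float)

    def objective(b0, b):
        rss = np.mean((y - b0 - X @ b) ** 2) / 2.0
        sd = X.std(0)
        bs = b * sd  # penalty applies on the standardized scale
        pen = fit.lambda_chosen * np.sum(0.25 * bs**2 + 0.5 * np.abs(bs))
        return rss + pen

    at_fit = objective(fit.intercept, fit.snp_main)
    at_zero = objective(y.mean(), np.zeros(G.k))
    assert at_fit <= at_zero + 1e-12


# ---------------------------------------------------------------------------
# external oracle: R glmnet on a tiny fixture


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_fixed_lambda_matches_glmnet(tmp_path):
    """Lasso coefficients at fixed lambda agree with glmnet exactly; the
    mixed penalty agrees closely (glmnet standardizes the response
    internally, slightly perturbing its ridge component)."""
    rng = np.random.default_rng(42)
    n, k = 80, 5
    X = rng.binomial(2, 0.3, (n, k)).astype(float)
    y = 1.0 + X @ np.array([0.8, -0.5, 0.3, 0.0, 0.0]) + rng.standard_normal(n)
    np.savetxt(tmp_path / "X.csv", X, delimiter=",")
    np.savetxt(tmp_path / "y.csv", y)
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(glmnet))\n'
        f'X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))\n'
        f'y <- scan("{tmp_path}/y.csv", quiet=TRUE)\n'
        'f1 <- glmnet(X, y, alpha=1, lambda=0.2, standardize=TRUE, thresh=1e-14)\n'
        'f2 <- glmnet(X, y, alpha=0.5, lambda=0.2, standardize=TRUE, thresh=1e-14)\n'
        'cat(as.numeric(coef(f1)), "\\n"); cat(as.numeric(coef(f2)), "\\n")\n'
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    ).stdout.strip().splitlines()
    glmnet_lasso = np.array([float(v) for v in out[0].split()])
    glmnet_enet = np.array([float(v) for v in out[1].split()])
    G = make_genotypes(X.astype(np.int8))
    ours_lasso = fit_penalized_marginal(G, y, alpha=1.0, lambda_=0.2)
    np.testing.assert_allclose(
        np.r_[ours_lasso.intercept, ours_lasso.snp_main], glmnet_lasso, atol=1e-5
    )
    ours_enet = fit_penalized_marginal(G, y, alpha=0.5, lambda_=0.2)
    np.testing.assert_allclose(
        np.r_[ours_enet.intercept, ours_enet.snp_main], glmnet_enet, atol=0.02
    )


# ---------------------------------------------------------------------------
# interaction fit


def test_interaction_null_shrinks_deltas_to_zero():
    rng = np.random.default_rng(7)
    G = make_genotypes(rng.binomial(2, 0.3, size=(400, 8)))
    E = rng.binomial(1, 0.5, size=400).astype(float)
    y = rng.standard_normal(400)
    fit = fit_penalized_interaction(G, E, y, alpha=0.5, cv_folds=10, seed=7)
    assert np.all(fit.snp_env_interaction == 0.0)


def test_interaction_recovers_risk_snps():
    """Predominant-interaction data: the six risk-SNP interaction terms
    are selected with positive sign and most noise terms stay at zero."""
    study = simulate_study(
        ScenarioConfig(n=5000, k_risk=6, k_noise=6, scenario="a", seed=11)
    )
    from grsxe.core import recode_genotypes

    G = recode_genotypes(study.genotypes, "dominant")
    fit = fit_penalized_interaction(
        G, study.exposure, study.phenotype, alpha=0.5, cv_folds=10, seed=11
    )
    assert np.all(fit.snp_env_interaction[:6] > 0)
    assert np.count_nonzero(fit.snp_env_interaction[6:]) <= 2


def test_interaction_recovers_env_main_effect():
    """y = 2E + noise at large n: the exposure coefficient is recovered.

    Because the product columns G*E correlate with E through E[G] > 0,
    any shrinkage of the penalized gamma leaks into small positive
    deltas; under the CV-minimum rule gamma comes back within 0.1 of
    truth with only small leakage, and with gamma unpenalized the
    recovery is clean (deltas identically zero)."""
    rng = np.random.default_rng(8)
    G = make_genotypes(rng.binomial(2, 0.3, size=(5000, 4)))
    E = rng.standard_normal(5000)
    y = 2.0 * E + rng.standard_normal(5000)
    fit = fit_penalized_interaction(G, E, y, alpha=0.5, cv_folds=10, seed=8,
                                    lambda_rule="min")
    assert abs(fit.env_main - 2.0) < 0.1
    assert np.max(np.abs(fit.snp_env_interaction)) < 0.1
    unpen = fit_penalized_interaction(G, E, y, alpha=0.5, cv_folds=10, seed=8,
                                      penalize_env_main=False)
    assert abs(unpen.env_main - 2.0) < 0.1
    assert np.all(unpen.snp_env_interaction == 0.0)


def test_interaction_constant_exposure_rejected():
    G, y = _toy(n=50, k=2, seed=9)
    with pytest.raises(FitError, match="constant"):
        fit_penalized_interaction(G, np.ones(50), y)


def test_nesting_zero_exposure_matches_marginal_path():
    """With E identically zero the gamma/delta columns are identically
    zero predictors and the SNP coefficients match the marginal fit."""
    G, y = _toy(n=150, k=4, seed=10, beta=(1.0, -0.5, 0.3, 0.0))
    for lam in (0.05, 0.3):
        marg = fit_penalized_marginal(G, y, alpha=0.5, lambda_=lam)
        joint = fit_penalized_interaction(G, np.zeros(150), y, alpha=0.5, lambda_=lam)
        np.testing.assert_allclose(joint.snp_main, marg.snp_main, atol=1e-8)
        assert joint.env_main == 0.0
        assert np.all(joint.snp_env_interaction == 0.0)


def test_unpenalized_env_main_option():
    """penalize_env_main=False leaves gamma at its least-squares value
    given the penalized SNP terms (here: no shrinkage of a strong E)."""
    rng = np.random.default_rng(12)
    G = make_genotypes(rng.binomial(2, 0.3, size=(800, 3)))
    E = rng.standard_normal(800)
    y = 1.5 * E + rng.standard_normal(800)
    pen = fit_penalized_interaction(G, E, y, lambda_=5.0, penalize_env_main=True)
    unpen = fit_penalized_interaction(G, E, y, lambda_=5.0, penalize_env_main=False)
    assert pen.env_main == 0.0  # heavy penalty kills gamma
    assert unpen.env_main == pytest.approx(1.5, abs=0.1)


# ---------------------------------------------------------------------------
# splitting and weight wrappers


@pytest.mark.parametrize(
    "n,ratio,expected",
    [(3000, (1, 1), (1500, 1500)), (400, (1, 3), (100, 300)), (100, (19, 1), (95, 5))],
)
def test_split_sizes(n, ratio, expected):
    plan = make_split(n, ratio, seed=0)
    assert (plan.train_indices.size, plan.test_indices.size) == expected


def test_split_is_a_partition():
    plan = make_split(57, (2, 1), seed=3)
    union = np.union1d(plan.train_indices, plan.test_indices)
    np.testing.assert_array_equal(union, np.arange(57))
    assert np.intersect1d(plan.train_indices, plan.test_indices).size == 0


def test_split_determinism_and_errors():
    a = make_split(100, (1, 1), seed=9)
    b = make_split(100, (1, 1), seed=9)
    np.testing.assert_array_equal(a.train_indices, b.train_indices)
    with pytest.raises(FitError, match="ratio"):
        make_split(100, (1, 0), seed=0)
    with pytest.raises(FitError, match="too small"):
        make_split(2, (2, 1), seed=0)


def test_weight_wrappers_and_determinism():
    study = simulate_study(ScenarioConfig(n=400, k_risk=3, k_noise=3, scenario="a", seed=13))
    G, E, y = study.genotypes, study.exposure, study.phenotype
    wm = weights_marginal_internal(G, y, seed=13)
    assert wm.provenance == "marginal-internal" and wm.weights.size == G.k
    w1, s1 = weights_interaction_training(G, E, y, (1, 1), seed=13)
    w2, s2 = weights_interaction_training(G, E, y, (1, 1), seed=13)
    np.testing.assert_array_equal(w1.weights, w2.weights)
    np.testing.assert_array_equal(s1.train_indices, s2.train_indices)
    assert w1.provenance == "interaction-training"


def test_over_shrunk_weights_flagged_degenerate():
    rng = np.random.default_rng(21)
    G = make_genotypes(rng.binomial(2, 0.3, size=(300, 6)))
    E = rng.binomial(1, 0.5, size=300).astype(float)
    y = rng.standard_normal(300)  # no signal at all
    with pytest.warns(UserWarning, match="degenerate"):
        w, _ = weights_interaction_training(G, E, y, (1, 1), seed=21)
    assert w.degenerate and np.all(w.weights == 0.0)


def test_validation_errors():
    G, y = _toy(n=30, k=2, seed=14)
    with pytest.raises(FitError, match="alpha"):
        fit_penalized_marginal(G, y, alpha=1.5)
    with pytest.raises(FitError, match="constant"):
        fit_penalized_marginal(G, np.ones(30))
    with pytest.raises(FitError, match="cv_folds"):
        fit_penalized_marginal(G, y, cv_folds=2)


def test_binomial_lambda_zero_matches_logistic_ml():
    import statsmodels.api as sm

    rng = np.random.default_rng(15)
    G = make_genotypes(rng.binomial(2, 0.4, size=(300, 2)))
    eta = -0.5 + 0.9 * G.dosages[:, 0]
    y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_penalized_marginal(G, y, family="binomial", lambda_=0.0)
    ref = sm.GLM(y, sm.add_constant(G.dosages.astype(float)),
                 family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.snp_main, ref.params[1:], rtol=1e-5)


def test_binomial_penalized_path_runs():
    rng = np.random.default_rng(16)
    G = make_genotypes(rng.binomial(2, 0.4, size=(200, 4)))
    eta = -0.2 + 1.2 * np.minimum(G.dosages[:, 0], 1)
    y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_penalized_marginal(
        G, y, family="binomial", cv_folds=5, seed=16, n_lambdas=25
    )
    assert fit.family == "binomial"
    assert fit.lambda_chosen in fit.lambda_path
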