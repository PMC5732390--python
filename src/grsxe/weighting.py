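"""GRS weight estimation: external, marginal-internal, interaction-training.

Three weighting regimes feed :func:`grsxe.core.compute_grs`:

* **external** — weights supplied from an independent study (read with
  :func:`grsxe.io.read_weights` or simulated with
  :func:`grsxe.simulation.simulate_external_study`); nothing is fitted
  here.
* **marginal-internal** — weights are the SNP coefficients of a single
  multivariable elastic-net regression of the outcome on the whole SNP
  panel, fitted on the full sample.
* **interaction-training** — the sample is split at random into a
  training and a test part; an elastic net with SNP main effects, an
  exposure main effect and all SNP-by-exposure product terms is fitted
  on the training part only, and the estimated interaction coefficients
  become the weights.  All downstream scoring and testing must then use
  the disjoint test part (the returned :class:`SplitPlan` records it).

Objective convention
--------------------
The penalized least-squares objective is

    (1 / 2n) * RSS + lambda * P(beta),
    P(beta) = sum_j [ (1 - alpha)/2 * beta_j^2 + alpha * |beta_j| ],

i.e. the loss is divided by the sample size, the convention of the
standard coordinate-descent software this mirrors, so lambda values are
comparable across sample sizes and the 1-SE cross-validation rule has
its usual meaning.  Predictors (including product terms, which are
formed first) are standardized internally to unit variance for the
penalty; coefficients are reported on the original scale.  In the joint
interaction fit the exposure main effect is penalized like every other
coefficient by default (``penalize_env_main=False`` profiles it out as
an unpenalized coefficient via blockwise descent).

lambda is chosen by K-fold cross-validation (default K=10, fold
assignment seeded) with the "within 1 SE of the minimum" rule: the
*largest* lambda on the fitted grid whose mean CV error is within one
standard error of the minimum.  ``lambda_rule="min"`` selects the
minimizer instead, and ``lambda_=c`` skips CV and fits at a fixed
penalty (``lambda_=0`` is the ordinary unpenalized fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from .core import GenotypeMatrix, WeightVector

LAMBDA_RULES = ("within-1SE-of-min", "min")


class FitError(ValueError):
    """Raised for unfittable inputs (constant outcome/exposure, bad alpha)."""


@dataclass
class PenalizedFit:
    """A fitted penalized regression on the original dosage scale."""

    intercept: float
    snp_main: np.ndarray
    env_main: float | None
    snp_env_interaction: np.ndarray | None
    alpha: float
    lambda_chosen: float
    lambda_rule: str
    cv_folds: int
    family: str
    snp_ids: list[str]
    lambda_path: np.ndarray | None = None
    cv_mean: np.ndarray | None = None
    cv_se: np.ndarray | None = None

    def coefficients(self) -> np.ndarray:
        parts = [self.snp_main]
        if self.env_main is not None:
            parts.append([self.env_main])
        if self.snp_env_interaction is not None:
            parts.append(self.snp_env_interaction)
        return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "snp_main": np.asarray(self.snp_main).tolist(),
            "env_main": None if self.env_main is None else float(self.env_main),
            "snp_env_interaction": None
            if self.snp_env_interaction is None
            else np.asarray(self.snp_env_interaction).tolist(),
            "alpha": self.alpha,
            "lambda_chosen": float(self.lambda_chosen),
            "lambda_rule": self.lambda_rule,
            "cv_folds": self.cv_folds,
            "family": self.family,
            "snp_ids": list(self.snp_ids),
            "lambda_path": None
            if self.lambda_path is None
            else np.asarray(self.lambda_path).tolist(),
        }


@dataclass
class SplitPlan:
    """A random disjoint train/test partition of the sample."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices)
        self.test_indices = np.asarray(self.test_indices)


# ---------------------------------------------------------------------------
# path fitting internals (gaussian)


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _lambda_grid(Xs, r, alpha, n_lambdas, *, min_ratio=None):
    """Descending log-spaced grid from the smallest all-zero lambda."""
    n, k = Xs.shape
    denom = n * max(alpha, 1e-3)
    lmax = np.abs(Xs.T @ r).max() / denom
    if lmax <= 0:
        lmax = 1e-3
    if min_ratio is None:
        min_ratio = 1e-4 if n > k else 1e-2
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def _path_coefs_gaussian(Xs, yc, lambdas, alpha, tol=1e-4):
    """Standardized-scale coefficients for each lambda (k x L).

    ``tol`` is the coordinate-descent duality-gap tolerance; path/CV
    fits use the customary 1e-4, single fixed-lambda fits tighten it
    for oracle-grade accuracy.
    """
    if alpha == 0.0:
        # closed-form ridge per lambda via eigendecomposition of X'X/n
        n = Xs.shape[0]
        gram = Xs.T @ Xs / n
        xy = Xs.T @ yc / n
        evals, evecs = np.linalg.eigh(gram)
        proj = evecs.T @ xy
        coefs = np.column_stack(
            [evecs @ (proj / (evals + lam)) for lam in lambdas]
        )
        return coefs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            Xs, yc, l1_ratio=alpha, alphas=lambdas, max_iter=2000, tol=tol
        )
    return coefs


def _enet_chunk(Xs, yc, lam_chunk, alpha, coef_init, tol=1e-4):
    """Warm-started descending-path fit of one lambda chunk."""
    if alpha == 0.0:
        return _path_coefs_gaussian(Xs, yc, lam_chunk, alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(
            Xs, yc, l1_ratio=alpha, alphas=lam_chunk, max_iter=2000, tol=tol,
            coef_init=None if coef_init is None else coef_init.copy(),
        )
    return coefs


def _cv_path_gaussian(X, y, lambdas, alpha, cv_folds, seed, chunk=10):
    """K-fold CV error curve plus the full-data coefficient path.

    The descending lambda path is evaluated in warm-started chunks and
    truncated once the mean CV error has risen clearly (beyond the 1-SE
    band) past its running minimum: both the CV-minimum and the 1-SE
    lambda lie in the computed prefix, and the deep (expensive, never
    selected) end of the path is skipped.  Returns
    (mean_mse, se_mse, full_coefs, n_computed).
    """
    L = lambdas.size
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=int(seed) % (2**31))
    folds = []
    for tr, te in kf.split(X):
        Xs_t, m_t, s_t = _standardize(X[tr])
        ybar_t = y[tr].mean()
        folds.append((Xs_t, y[tr] - ybar_t, (X[te] - m_t) / s_t, y[te], ybar_t))
    Xs, _, _ = _standardize(X)
    ybar = y.mean()
    yc = y - ybar
    fold_mse = np.empty((cv_folds, L))
    full_coefs = np.empty((X.shape[1], L))
    fold_init = [None] * cv_folds
    full_init = None
    end = 0
    for start in range(0, L, chunk):
        stop = min(start + chunk, L)
        lam_chunk = lambdas[start:stop]
        cf = _enet_chunk(Xs, yc, lam_chunk, alpha, full_init)
        full_coefs[:, start:stop] = cf
        full_init = cf[:, -1]
        for f, (Xs_t, yc_t, Xte_s, yte, ybar_t) in enumerate(folds):
            cff = _enet_chunk(Xs_t, yc_t, lam_chunk, alpha, fold_init[f])
            fold_init[f] = cff[:, -1]
            pred = Xte_s @ cff + ybar_t
            fold_mse[f, start:stop] = ((yte[:, None] - pred) ** 2).mean(axis=0)
        end = stop
        mean_c = fold_mse[:, :end].mean(axis=0)
        se_c = fold_mse[:, :end].std(axis=0, ddof=1) / np.sqrt(cv_folds)
        i_min = int(np.argmin(mean_c))
        threshold = mean_c[i_min] + 2.0 * se_c[i_min]
        if i_min < start and np.all(mean_c[start:end] > threshold):
            break
    mean_mse = fold_mse[:, :end].mean(axis=0)
    se_mse = fold_mse[:, :end].std(axis=0, ddof=1) / np.sqrt(cv_folds)
    return mean_mse, se_mse, full_coefs[:, :end], end


def _choose_lambda(lambdas, mean_err, se_err, rule):
    i_min = int(np.argmin(mean_err))
    if rule == "min":
        return i_min
    threshold = mean_err[i_min] + se_err[i_min]
    # grid is descending: the first index satisfying the criterion is the
    # largest lambda within one SE of the minimum
    return int(np.argmax(mean_err <= threshold))


def _fit_gaussian(
    X, y, alpha, cv_folds, seed, lambda_, lambda_rule, n_lambdas,
    unpenalized_col=None,
):
    """Penalized gaussian fit; returns (intercept, coefs, lam, path, cvm, cvs).

    ``unpenalized_col``: index of one column left unpenalized (profiled
    out by blockwise descent, used for the exposure main effect).
    """
    n, k = X.shape
    y = np.asarray(y, dtype=float)
    if lambda_ is not None and lambda_ == 0.0:
        Z = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        return beta[0], beta[1:], 0.0, None, None, None

    if unpenalized_col is not None:
        return _fit_gaussian_unpenalized_col(
            X, y, alpha, cv_folds, seed, lambda_, lambda_rule, n_lambdas,
            unpenalized_col,
        )

    Xs, mean, sd = _standardize(X)
    ybar = y.mean()
    yc = y - ybar
    if lambda_ is not None:
        lambdas = np.array([float(lambda_)])
        coefs = _path_coefs_gaussian(Xs, yc, lambdas, alpha, tol=1e-9)
        idx, cvm, cvs = 0, None, None
    else:
        lambdas = _lambda_grid(Xs, yc, alpha, n_lambdas)
        cvm, cvs, coefs, end = _cv_path_gaussian(
            X, y, lambdas, alpha, cv_folds, seed
        )
        lambdas = lambdas[:end]
        idx = _choose_lambda(lambdas, cvm, cvs, lambda_rule)
    beta_orig = coefs[:, idx] / sd
    intercept = ybar - float(mean @ beta_orig)
    return intercept, beta_orig, float(lambdas[idx]), lambdas, cvm, cvs


def _fit_gaussian_unpenalized_col(
    X, y, alpha, cv_folds, seed, lambda_, lambda_rule, n_lambdas, col
):
    """Blockwise descent: the ``col`` coefficient is updated by least
    squares, the rest by the elastic net on the partial residual."""
    keep = [j for j in range(X.shape[1]) if j != col]

    def solve(lam, Xsub, ysub):
        Xp, xu = Xsub[:, keep], Xsub[:, col]
        gamma, beta = 0.0, np.zeros(len(keep))
        intercept = float(np.mean(ysub))
        Xs, mean, sd = _standardize(Xp)
        z = np.column_stack([np.ones_like(xu), xu])
        for _ in range(50):
            resid = ysub - Xp @ beta
            sol, *_ = np.linalg.lstsq(z, resid, rcond=None)
            new_intercept, new_gamma = sol
            partial = ysub - new_intercept - new_gamma * xu
            pc = partial - partial.mean()
            coef_s = _path_coefs_gaussian(Xs, pc, np.array([lam]), alpha)[:, 0]
            new_beta = coef_s / sd
            shift = partial.mean() - float(mean @ new_beta)
            converged = (
                abs(new_gamma - gamma) < 1e-8
                and np.max(np.abs(new_beta - beta)) < 1e-8
            )
            gamma, beta, intercept = new_gamma, new_beta, new_intercept + shift
            if converged:
                break
        return intercept, beta, gamma

    y = np.asarray(y, dtype=float)
    Xs0, _, _ = _standardize(X[:, keep])
    if lambda_ is not None:
        lambdas = np.array([float(lambda_)])
        cvm = cvs = None
        idx = 0
    else:
        lambdas = _lambda_grid(Xs0, y - y.mean(), alpha, n_lambdas)
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=int(seed) % (2**31))
        fold_mse = np.empty((cv_folds, lambdas.size))
        for f, (tr, te) in enumerate(kf.split(X)):
            for i, lam in enumerate(lambdas):
                b0, b, g = solve(lam, X[tr], y[tr])
                pred = b0 + X[te][:, keep] @ b + g * X[te][:, col]
                fold_mse[f, i] = np.mean((y[te] - pred) ** 2)
        cvm = fold_mse.mean(axis=0)
        cvs = fold_mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
        idx = _choose_lambda(lambdas, cvm, cvs, lambda_rule)
    b0, b, g = solve(float(lambdas[idx]), X, y)
    coefs = np.empty(X.shape[1])
    coefs[keep] = b
    coefs[col] = g
    return b0, coefs, float(lambdas[idx]), lambdas, cvm, cvs


# ---------------------------------------------------------------------------
# binomial (penalized logistic) internals


def _path_coefs_binomial(Xs, y, lambdas, alpha):
    from sklearn.linear_model import LogisticRegression

    n = Xs.shape[0]
    coefs = np.empty((Xs.shape[1], lambdas.size))
    intercepts = np.empty(lambdas.size)
    clf = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            C = 1.0 / (n * lam)
            if clf is None:
                clf = LogisticRegression(
                    solver="saga", l1_ratio=alpha,
                    C=C, max_iter=2000, tol=1e-6, warm_start=True,
                )
            else:
                clf.C = C
            clf.fit(Xs, y)
            coefs[:, i] = clf.coef_[0]
            intercepts[i] = clf.intercept_[0]
    return coefs, intercepts


def _fit_binomial(X, y, alpha, cv_folds, seed, lambda_, lambda_rule, n_lambdas):
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise FitError("binomial family requires a 0/1 outcome")
    if lambda_ is not None and lambda_ == 0.0:
        Z = sm.add_constant(X)
        res = sm.GLM(y, Z, family=sm.families.Binomial()).fit()
        return res.params[0], res.params[1:], 0.0, None, None, None
    Xs, mean, sd = _standardize(X)
    pbar = y.mean()
    if lambda_ is not None:
        lambdas = np.array([float(lambda_)])
        coefs, icepts = _path_coefs_binomial(Xs, y, lambdas, alpha)
        idx, cvm, cvs = 0, None, None
    else:
        lambdas = _lambda_grid(Xs, y - pbar, alpha, n_lambdas)
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=int(seed) % (2**31))
        fold_dev = np.empty((cv_folds, lambdas.size))
        for f, (tr, te) in enumerate(kf.split(Xs)):
            Xst, m_t, s_t = _standardize(X[tr])
            cf, ic = _path_coefs_binomial(Xst, y[tr], lambdas, alpha)
            eta = ((X[te] - m_t) / s_t) @ cf + ic
            p = 1.0 / (1.0 + np.exp(-eta))
            p = np.clip(p, 1e-10, 1 - 1e-10)
            fold_dev[f] = -2.0 * (
                y[te, None] * np.log(p) + (1 - y[te, None]) * np.log(1 - p)
            ).mean(axis=0)
        cvm = fold_dev.mean(axis=0)
        cvs = fold_dev.std(axis=0, ddof=1) / np.sqrt(cv_folds)
        idx = _choose_lambda(lambdas, cvm, cvs, lambda_rule)
        coefs, icepts = _path_coefs_binomial(Xs, y, lambdas[idx : idx + 1], alpha)
        idx = 0
        lambdas_chosen = lambdas[_choose_lambda(lambdas, cvm, cvs, lambda_rule)]
        beta_orig = coefs[:, 0] / sd
        intercept = icepts[0] - float(mean @ beta_orig)
        return intercept, beta_orig, float(lambdas_chosen), lambdas, cvm, cvs
    beta_orig = coefs[:, idx] / sd
    intercept = icepts[idx] - float(mean @ beta_orig)
    return intercept, beta_orig, float(lambdas[idx]), lambdas, cvm, cvs


# ---------------------------------------------------------------------------
# public fitting operations


def _validate_common(n, y, alpha, cv_folds, lambda_, lambda_rule):
    if not 0.0 <= alpha <= 1.0:
        raise FitError(f"alpha must be in [0, 1], got {alpha}")
    if lambda_rule not in LAMBDA_RULES:
        raise FitError(f"unknown lambda_rule {lambda_rule!r}")
    if np.all(np.asarray(y) == np.asarray(y)[0]):
        raise FitError("outcome y is constant")
    if lambda_ is None:
        if cv_folds < 3:
            raise FitError("cv_folds must be >= 3")
        if n <= cv_folds:
            raise FitError(f"need n > cv_folds ({n} <= {cv_folds})")


def fit_penalized_marginal(
    G: GenotypeMatrix,
    y,
    alpha: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    *,
    family: str = "gaussian",
    lambda_=None,
    lambda_rule: str = "within-1SE-of-min",
    n_lambdas: int = 100,
) -> PenalizedFit:
    """Elastic-net fit of the outcome on all SNP main effects jointly.

    The fitted SNP coefficients estimate the *marginal genetic effects*
    of the panel and serve as marginal-internal GRS weights.  With
    ``lambda_=0`` this is the ordinary unpenalized fit (least squares or
    logistic ML); with ``lambda_`` unset, lambda is chosen by seeded
    K-fold CV under ``lambda_rule``.
    """
    X = G.dosages.astype(float)
    _validate_common(X.shape[0], y, alpha, cv_folds, lambda_, lambda_rule)
    fitter = _fit_gaussian if family == "gaussian" else _fit_binomial
    if family not in ("gaussian", "binomial"):
        raise FitError(f"unknown family {family!r}")
    icept, coefs, lam, path, cvm, cvs = fitter(
        X, np.asarray(y, float), alpha, cv_folds, seed, lambda_, lambda_rule, n_lambdas
    )
    return PenalizedFit(
        intercept=float(icept), snp_main=np.asarray(coefs), env_main=None,
        snp_env_interaction=None, alpha=alpha, lambda_chosen=lam,
        lambda_rule=lambda_rule if lambda_ is None else "fixed",
        cv_folds=cv_folds, family=family, snp_ids=list(G.snp_ids),
        lambda_path=path, cv_mean=cvm, cv_se=cvs,
    )


def fit_penalized_interaction(
    G: GenotypeMatrix,
    E,
    y,
    alpha: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    *,
    family: str = "gaussian",
    lambda_=None,
    lambda_rule: str = "within-1SE-of-min",
    n_lambdas: int = 100,
    penalize_env_main: bool = True,
) -> PenalizedFit:
    """Joint elastic-net fit with SNP, exposure and SNP-x-exposure terms.

    The design holds the k SNP columns, the exposure E and the k product
    columns G_ij * E_i (formed on the dosage scale, then standardized
    like any other predictor).  All coefficients are penalized,
    including the exposure main effect, unless
    ``penalize_env_main=False`` (gaussian family only), in which case the
    exposure coefficient is profiled out unpenalized.  The fitted
    interaction coefficients are the interaction-training weight
    candidates.
    """
    E = np.asarray(E, dtype=float)
    # an identically-zero E contributes identically-zero predictor columns
    # (nesting the marginal fit); any other constant E is unidentifiable
    if np.all(E == E[0]) and E[0] != 0.0:
        raise FitError("exposure E is constant; interaction unidentifiable")
    k = G.k
    X = np.column_stack([G.dosages.astype(float), E, G.dosages * E[:, None]])
    _validate_common(X.shape[0], y, alpha, cv_folds, lambda_, lambda_rule)
    if family == "gaussian":
        icept, coefs, lam, path, cvm, cvs = _fit_gaussian(
            X, np.asarray(y, float), alpha, cv_folds, seed, lambda_, lambda_rule,
            n_lambdas, unpenalized_col=None if penalize_env_main else k,
        )
    elif family == "binomial":
        if not penalize_env_main:
            raise FitError("penalize_env_main=False supports the gaussian family only")
        icept, coefs, lam, path, cvm, cvs = _fit_binomial(
            X, np.asarray(y, float), alpha, cv_folds, seed, lambda_, lambda_rule,
            n_lambdas,
        )
    else:
        raise FitError(f"unknown family {family!r}")
    return PenalizedFit(
        intercept=float(icept), snp_main=np.asarray(coefs[:k]),
        env_main=float(coefs[k]), snp_env_interaction=np.asarray(coefs[k + 1 :]),
        alpha=alpha, lambda_chosen=lam,
        lambda_rule=lambda_rule if lambda_ is None else "fixed",
        cv_folds=cv_folds, family=family, snp_ids=list(G.snp_ids),
        lambda_path=path, cv_mean=cvm, cv_se=cvs,
    )


def make_split(n: int, ratio: tuple[int, int] = (1, 1), seed: int = 0) -> SplitPlan:
    """Uniformly random disjoint train/test partition at a given balance.

    ``|train| = round(n * r_train / (r_train + r_test))``; e.g. n=3000 at
    1:1 gives 1500/1500 and n=400 at 1:3 gives 100/300.
    """
    r_train, r_test = int(ratio[0]), int(ratio[1])
    if r_train < 1 or r_test < 1:
        raise FitError(f"degenerate ratio {ratio}: both parts must be >= 1")
    if n < r_train + r_test:
        raise FitError(f"n={n} too small for ratio {r_train}:{r_test}")
    n_train = int(round(n * r_train / (r_train + r_test)))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitPlan(
        train_indices=np.sort(perm[:n_train]),
        test_indices=np.sort(perm[n_train:]),
        ratio=(r_train, r_test),
        seed=int(seed),
    )


def weights_marginal_internal(
    G: GenotypeMatrix, y, alpha: float = 0.5, cv_folds: int = 10, seed: int = 0, **kw
) -> WeightVector:
    """Marginal-internal weights: elastic-net SNP coefficients on the full sample."""
    fit = fit_penalized_marginal(G, y, alpha, cv_folds, seed, **kw)
    w = np.asarray(fit.snp_main, dtype=float)
    degenerate = bool(np.all(w == 0.0))
    if degenerate:
        warnings.warn("all marginal-internal weights are zero (over-shrunk fit)",
                      stacklevel=2)
    return WeightVector(
        weights=w, snp_ids=list(G.snp_ids), provenance="marginal-internal",
        scale_note=f"{fit.family} elastic-net coefficient", degenerate=degenerate,
    )


def weights_interaction_training(
    G: GenotypeMatrix,
    E,
    y,
    ratio: tuple[int, int] = (1, 1),
    alpha: float = 0.5,
    cv_folds: int = 10,
    seed: int = 0,
    **kw,
) -> tuple[WeightVector, SplitPlan]:
    """Interaction-training weights plus the split that produced them.

    The penalized interaction model is fitted on the training subset
    only; the interaction coefficients become the weights.  Downstream
    GRS scoring and interaction testing must use
    ``split.test_indices`` exclusively — reusing the training samples
    would re-introduce the bias the split exists to remove.
    """
    n = G.n
    split = make_split(n, ratio, seed)
    if split.train_indices.size <= cv_folds and kw.get("lambda_") is None:
        raise FitError(
            f"training subset of size {split.train_indices.size} too small "
            f"for {cv_folds}-fold CV"
        )
    E = np.asarray(E, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = fit_penalized_interaction(
        G.subset_samples(split.train_indices),
        E[split.train_indices],
        y[split.train_indices],
        alpha, cv_folds, seed, **kw,
    )
    w = np.asarray(fit.snp_env_interaction, dtype=float)
    degenerate = bool(np.all(w == 0.0))
    if degenerate:
        warnings.warn(
            "all interaction-training weights are zero (over-shrunk fit); "
            "downstream GRS is degenerate", stacklevel=2,
        )
    return (
        WeightVector(
            weights=w, snp_ids=list(G.snp_ids), provenance="interaction-training",
            scale_note=f"{fit.family} elastic-net interaction coefficient",
            degenerate=degenerate,
        ),
        split,
    )
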