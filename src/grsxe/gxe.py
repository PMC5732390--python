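"""The GRS-by-exposure interaction test.

Given per-sample scores, an exposure and an outcome, fit the generalized
linear model

    g(E[y]) = tau_0 + tau_1 * GRS + tau_2 * E + tau_3 * GRS*E  (+ covariates)

by maximum likelihood (identity link for a gaussian outcome, logit link
for a binary one) and report the Wald test of the interaction
coefficient tau_3: estimate, standard error, two-sided p-value and sign.
Gaussian inference uses the t reference with residual degrees of
freedom; binomial inference uses the asymptotic normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .core import GRSVector


class DegenerateGRSError(ValueError):
    """Raised when the GRS is constant, so no interaction is estimable."""


class RankDeficientError(ValueError):
    """Raised when the design matrix is rank deficient."""


@dataclass
class InteractionTestResult:
    """Wald test of the GRS-by-exposure interaction coefficient."""

    estimate: float
    std_error: float
    p_value: float
    sign: str  # '+', '-' or '0'
    family: str
    n_used: int
    covariate_names: list[str]
    converged: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate, "std_error": self.std_error,
            "p_value": self.p_value, "sign": self.sign, "family": self.family,
            "n_used": self.n_used, "covariates": list(self.covariate_names),
            "converged": self.converged, "note": self.note,
        }


def _sign(x: float) -> str:
    if x > 0:
        return "+"
    if x < 0:
        return "-"
    return "0"


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    from scipy.linalg import qr

    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(names)) if diag[i] <= tol]
    raise RankDeficientError(f"design matrix rank deficient; collinear columns: {bad}")


def test_grs_by_e(
    grs,
    E,
    y,
    family: str = "gaussian",
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> InteractionTestResult:
    """Fit intercept + GRS + E + GRS*E (+ covariates) and Wald-test GRS*E.

    A constant GRS (e.g. one scored with all-zero weights) raises
    :class:`DegenerateGRSError` rather than producing a meaningless
    p-value.  Perfect separation in the binomial family returns a result
    flagged ``converged=False`` with NaN estimate.
    """
    g = grs.values if isinstance(grs, GRSVector) else np.asarray(grs, dtype=float)
    E = np.asarray(E, dtype=float)
    y = np.asarray(y, dtype=float)
    if not g.shape == E.shape == y.shape:
        raise ValueError(f"length mismatch: grs {g.shape}, E {E.shape}, y {y.shape}")
    if np.all(g == g[0]):
        raise DegenerateGRSError("degenerate GRS: scores are constant")
    names = ["const", "grs", "E", "grs:E"]
    X = np.column_stack([np.ones_like(g), g, E, g * E])
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != g.size:
            cov = cov.T
        cnames = covariate_names or [f"cov{i}" for i in range(cov.shape[1])]
        X = np.column_stack([X, cov])
        names = names + list(cnames)
    else:
        cnames = []
    _check_rank(X, names)
    idx = 3  # grs:E column
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        est, se, p = res.params[idx], res.bse[idx], res.pvalues[idx]
    elif family == "binomial":
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception as exc:  # perfect separation and friends
            return InteractionTestResult(
                estimate=float("nan"), std_error=float("nan"), p_value=1.0,
                sign="0", family=family, n_used=int(g.size),
                covariate_names=cnames, converged=False,
                note=f"non-convergence: {exc}",
            )
        if not res.converged or np.any(~np.isfinite(res.bse)):
            return InteractionTestResult(
                estimate=float(res.params[idx]), std_error=float("nan"),
                p_value=1.0, sign="0", family=family, n_used=int(g.size),
                covariate_names=cnames, converged=False,
                note="non-convergence (possible perfect separation)",
            )
        est, se, p = res.params[idx], res.bse[idx], res.pvalues[idx]
    else:
        raise ValueError(f"unknown family {family!r}")
    return InteractionTestResult(
        estimate=float(est), std_error=float(se), p_value=float(p),
        sign=_sign(float(est)), family=family, n_used=int(g.size),
        covariate_names=cnames,
    )


def bonferroni(p_values, m: int | None = None):
    """Bonferroni correction used for per-SNP reporting: raw p times the
    number of tested SNPs, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else int(m)
    return np.minimum(p * m, 1.0)
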