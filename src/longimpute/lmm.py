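"""Random-intercept linear mixed model via profiled likelihood.

The model is y_it = x_it' beta + b_i + e_it with b_i ~ N(0, s2_b) and
e_it ~ N(0, s2_e).  With lambda = s2_b / s2_e, the marginal covariance of
group i is s2_e (I + lambda J), whose inverse is (1/s2_e)(I - theta_i J)
with theta_i = lambda / (1 + n_i lambda).  Both beta and s2_e have closed
forms given lambda, so fitting reduces to a one-dimensional optimization of
the profiled (restricted) log-likelihood over log lambda — a few
milliseconds per fit at the panel sizes used here, which is what makes the
Monte-Carlo replication harness and the EM tree's inner loop affordable.

Log-likelihood conventions match statsmodels MixedLM (the REML criterion
uses the scale-free weighted cross-product in its determinant term), so the
two agree to numerical precision on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["LMMFit", "LMMError", "fit_lmm", "fit_random_intercept",
           "conditional_residuals"]


class LMMError(RuntimeError):
    """Mixed-model estimation failure (rank deficiency, non-convergence)."""


@dataclass
class RandomInterceptFit:
    """Low-level fit result on a design matrix."""
    beta: np.ndarray
    se: np.ndarray
    resid_var: float          # s2_e
    re_var: float             # s2_b
    loglik: float             # per the requested criterion
    reml: bool
    groups: np.ndarray        # unique group labels
    ranef: np.ndarray         # BLUP b_i per unique group
    converged: bool


def fit_random_intercept(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                         reml: bool = True) -> RandomInterceptFit:
    """Fit the random-intercept model on a prebuilt design matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N, p = X.shape
    if N == 0:
        raise LMMError("empty design")
    if np.linalg.matrix_rank(X) < p:
        raise LMMError("rank-deficient design matrix")

    ulab, gidx = np.unique(groups, return_inverse=True)
    ni = np.bincount(gidx).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Sx = np.zeros((len(ulab), p))
    for j in range(p):
        Sx[:, j] = np.bincount(gidx, weights=X[:, j])
    Sy = np.bincount(gidx, weights=y)

    def _solve(lam: float):
        th = lam / (1.0 + ni * lam)
        A = XtX - (Sx * th[:, None]).T @ Sx
        b = Xty - (Sx * th[:, None]).T @ Sy
        beta = np.linalg.solve(A, b)
        rss = yty - float((Sy ** 2 * th).sum()) - 2 * beta @ b + beta @ A @ beta
        # floor guards the perfect-fit limit (exactly linear response)
        rss = max(float(rss), 1e-12 * max(yty, 1.0))
        return th, A, b, beta, rss

    logdet_cache = {}

    def neg_profile(loglam: float) -> float:
        lam = np.exp(loglam)
        th, A, b, beta, rss = _solve(lam)
        logdet = float(np.log1p(ni * lam).sum())
        if reml:
            sig2 = rss / (N - p)
            sign, ldA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            ll = -0.5 * ((N - p) * np.log(2 * np.pi * sig2) + logdet
                         + ldA + rss / sig2)
        else:
            sig2 = rss / N
            ll = -0.5 * (N * np.log(2 * np.pi * sig2) + logdet + rss / sig2)
        if not np.isfinite(ll):
            return np.inf
        return -ll

    res = minimize_scalar(neg_profile, bounds=(-14.0, 14.0),
                          method="bounded", options={"xatol": 1e-10})
    if not np.isfinite(res.fun):
        raise LMMError("non-finite profiled likelihood")
    lam = float(np.exp(res.x))
    th, A, b, beta, rss = _solve(lam)
    sig2 = rss / (N - p) if reml else rss / N
    se = np.sqrt(np.diag(np.linalg.inv(A)) * sig2)
    resid_sum = Sy - Sx @ beta
    ranef = lam * resid_sum / (1.0 + ni * lam)
    return RandomInterceptFit(beta=beta, se=se, resid_var=float(sig2),
                              re_var=float(lam * sig2), loglik=-float(res.fun),
                              reml=reml, groups=ulab, ranef=ranef,
                              converged=bool(res.success))


@dataclass
class LMMFit:
    """Fitted random-intercept LMM on a long panel.

    Coefficients/SEs come from the requested criterion (REML by default);
    deviance and AIC always use the ML log-likelihood, with the parameter
    count equal to the number of fixed effects plus the two variance
    components.
    """
    response: str
    predictors: list[str]
    params: "pd.Series"
    bse: "pd.Series"
    re_var: float
    resid_var: float
    loglik: float
    loglik_ml: float
    deviance: float
    aic: float
    method: str
    ranef: "pd.Series"
    n_obs: int
    n_params: int

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": self.predictors,
            "method": self.method,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "re_var": self.re_var,
            "resid_var": self.resid_var,
            "loglik": self.loglik,
            "loglik_ml": self.loglik_ml,
            "deviance": self.deviance,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
        }


def _design(panel: pd.DataFrame, response: str,
            predictors: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    cols = [response] + list(predictors)
    for c in cols:
        if c not in panel.columns:
            raise LMMError(f"column {c!r} absent from panel")
        if panel[c].isna().any():
            raise LMMError(f"column {c!r} contains missing values; impute first")
    X = np.column_stack([np.ones(len(panel))]
                        + [panel[c].to_numpy(dtype=float) for c in predictors])
    names = ["intercept"] + list(predictors)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise LMMError(f"rank-deficient design among columns {names}")
    return X, panel[response].to_numpy(dtype=float), panel["subject_id"].to_numpy(), names


def fit_lmm(panel: pd.DataFrame, response: str = "dbp",
            predictors: list[str] | None = None,
            method: str = "REML") -> LMMFit:
    """Fit ``response ~ 1 + predictors + (1 | subject)``.

    Default predictors are age, sex, bmi and time (the numeric wave index).
    """
    if predictors is None:
        predictors = ["age", "sex", "bmi", "time"]
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    if panel["subject_id"].nunique() < 2:
        raise LMMError("need at least 2 subjects")
    X, y, groups, names = _design(panel, response, predictors)
    fit = fit_random_intercept(X, y, groups, reml=(method == "REML"))
    if method == "ML":
        loglik_ml = fit.loglik
    else:
        loglik_ml = fit_random_intercept(X, y, groups, reml=False).loglik
    n_params = X.shape[1] + 2
    deviance = -2.0 * loglik_ml
    return LMMFit(
        response=response, predictors=list(predictors),
        params=pd.Series(fit.beta, index=names),
        bse=pd.Series(fit.se, index=names),
        re_var=fit.re_var, resid_var=fit.resid_var,
        loglik=fit.loglik, loglik_ml=loglik_ml,
        deviance=deviance, aic=deviance + 2 * n_params,
        method=method,
        ranef=pd.Series(fit.ranef, index=fit.groups),
        n_obs=len(y), n_params=n_params,
    )


def conditional_residuals(fit: LMMFit, panel: pd.DataFrame) -> np.ndarray:
    """r_it = y_it - x_it' beta_hat - b_hat_i for every panel row.

    In-sample only: a subject absent from the training panel raises.
    """
    X, y, groups, _ = _design(panel, fit.response, fit.predictors)
    unseen = set(np.unique(groups)) - set(fit.ranef.index)
    if unseen:
        raise LMMError(f"subjects not in fitted model: {sorted(unseen)[:5]}")
    b = fit.ranef.reindex(groups).to_numpy()
    return y - X @ fit.params.to_numpy() - b
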