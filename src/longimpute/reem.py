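"""Random-effects EM (REEM) longitudinal regression tree.

Alternates two stages until the (restricted) log-likelihood stabilizes:

1. fit a regression tree to the random-effect-adjusted response
   y_it - b_i_hat against the covariates x_it;
2. fit a random-intercept mixed model with one fixed effect per terminal
   node, y_it = b_i + sum_p I(x_it in g_p) mu_p + e_it, updating b_i_hat,
   the node means mu_p and the variance components.

After convergence the tree's terminal predictions are replaced by the
mixed-model estimates mu_p_hat.  The random-effect design is a subject
intercept (Z_it = 1); random slopes are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import LMMError, fit_random_intercept
from .tree import RegressionTree, TreeControls, fit_regression_tree

__all__ = ["REEMModel", "fit_reem", "predict_reem"]


@dataclass
class REEMModel:
    tree: RegressionTree
    mu: pd.Series                # terminal-node fixed effects, index = leaf id
    ranef: pd.Series             # subject random intercepts
    re_var: float
    resid_var: float
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    response: str
    predictors: list[str]
    loglik: float                # final REML log-likelihood
    loglik_ml: float
    deviance: float              # -2 * ML log-likelihood
    n_params: int                # terminal nodes + 2 variance components

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": self.predictors,
            "tree": self.tree.to_dict(),
            "mu": {int(k): v for k, v in self.mu.items()},
            "ranef": {str(k): float(v) for k, v in self.ranef.items()},
            "re_var": self.re_var,
            "resid_var": self.resid_var,
            "loglik": self.loglik,
            "loglik_ml": self.loglik_ml,
            "deviance": self.deviance,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik_trace": self.loglik_trace,
        }


def _indicator(leaf_ids: np.ndarray, n_leaves: int) -> np.ndarray:
    Z = np.zeros((leaf_ids.size, n_leaves))
    Z[np.arange(leaf_ids.size), leaf_ids] = 1.0
    return Z


def fit_reem(panel: pd.DataFrame, response: str = "dbp",
             predictors: list[str] | None = None,
             controls: TreeControls | None = None,
             reml: bool = True) -> REEMModel:
    """Fit the REEM tree on a complete panel.

    Convergence: absolute change in the (restricted) log-likelihood below
    ``controls.tol`` (default 1e-3), capped at ``controls.max_iter``
    iterations with a warning rather than an error on non-convergence.
    """
    if predictors is None:
        predictors = ["age", "sex", "bmi", "time"]
    if controls is None:
        controls = TreeControls()
    for c in [response] + list(predictors):
        if c not in panel.columns:
            raise LMMError(f"column {c!r} absent from panel")
        if panel[c].isna().any():
            raise LMMError(f"column {c!r} contains missing values; impute first")
    groups = panel["subject_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise LMMError("need at least 2 subjects")
    X = panel[list(predictors)].to_numpy(dtype=float)
    y = panel[response].to_numpy(dtype=float)

    subjects = np.unique(groups)
    b_hat = pd.Series(0.0, index=subjects)
    trace: list[float] = []
    converged = False
    tree = mm = None
    for it in range(controls.max_iter):
        adj = y - b_hat.reindex(groups).to_numpy()
        tree = fit_regression_tree(X, adj, controls, list(predictors))
        leaf_ids = tree.apply(X)
        design = _indicator(leaf_ids, tree.n_leaves)
        try:
            mm = fit_random_intercept(design, y, groups, reml=reml)
        except LMMError as exc:
            raise LMMError(f"mixed-model stage failed at EM iteration "
                           f"{it + 1}: {exc}") from exc
        if not np.isfinite(mm.loglik):
            raise LMMError(f"non-finite likelihood at EM iteration {it + 1}")
        b_hat = pd.Series(mm.ranef, index=mm.groups).reindex(subjects).fillna(0.0)
        trace.append(mm.loglik)
        if len(trace) >= 2:
            delta = trace[-1] - trace[-2]
            if delta < -10 * controls.tol:
                warnings.warn(
                    f"REEM log-likelihood decreased by {-delta:.4g} at "
                    f"iteration {it + 1}", RuntimeWarning)
            if abs(delta) < controls.tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"REEM did not converge in {controls.max_iter} iterations",
            RuntimeWarning)

    tree.set_leaf_values(mm.beta)
    leaf_ids = tree.apply(X)
    ml = fit_random_intercept(_indicator(leaf_ids, tree.n_leaves), y,
                              groups, reml=False)
    n_params = tree.n_leaves + 2
    return REEMModel(
        tree=tree,
        mu=pd.Series(mm.beta, index=range(tree.n_leaves)),
        ranef=b_hat,
        re_var=mm.re_var, resid_var=mm.resid_var,
        loglik_trace=trace, converged=converged, n_iter=len(trace),
        response=response, predictors=list(predictors),
        loglik=mm.loglik, loglik_ml=ml.loglik,
        deviance=-2.0 * ml.loglik, n_params=n_params,
    )


def predict_reem(model: REEMModel, newdata: pd.DataFrame) -> np.ndarray:
    """Predict: routed leaf mu_p_hat plus the subject's random intercept
    when the subject was in training, else the population-level value."""
    for c in model.predictors:
        if c not in newdata.columns:
            raise ValueError(f"missing predictor column {c!r}")
    X = newdata[model.predictors].to_numpy(dtype=float)
    pred = model.mu.to_numpy()[model.tree.apply(X)]
    if "subject_id" in newdata.columns:
        b = model.ranef.reindex(newdata["subject_id"]).fillna(0.0).to_numpy()
        pred = pred + b
    return pred
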