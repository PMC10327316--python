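"""Comparison metrics, Rubin's-rules pooling, and the Monte-Carlo
replication harness.

The harness repeats, per replicate: generate a complete cohort, inject MAR
missingness, complete the data with each requested single-imputation
method, fit each requested analysis model (random-intercept LMM and/or
REEM tree), and record coefficients, standard errors and fit metrics.  It
then reports per-(method, model) means with Monte-Carlo standard errors.

Metrics are computed on conditional residuals standardized by the fitted
residual SD; MSE = mean(s^2), RMSE = sqrt(MSE), MAD = median(|s|),
deviance = -2 log-likelihood (ML), AIC = deviance + 2 k.  AIC is reported
for the LMM only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .impute import METHODS, impute
from .lmm import LMMFit, conditional_residuals, fit_lmm
from .reem import fit_reem, predict_reem
from .simulate import ampute_mar, generate_complete
from .tree import TreeControls

__all__ = ["FitMetrics", "PooledEstimate", "ReplicationReport",
           "compute_metrics", "pool_rubin", "run_replication",
           "lmm_metrics", "reem_metrics"]

logger = logging.getLogger(__name__)

COEF_NAMES = ["intercept", "age", "sex", "bmi", "time"]


@dataclass(frozen=True)
class FitMetrics:
    mse: float
    rmse: float
    mad: float
    deviance: float
    aic: float | None = None

    def to_dict(self) -> dict:
        return {"mse": self.mse, "rmse": self.rmse, "mad": self.mad,
                "deviance": self.deviance, "aic": self.aic}


def compute_metrics(residuals, residual_sd: float, loglik: float,
                    n_params: int, include_aic: bool = True) -> FitMetrics:
    """Standardize residuals by ``residual_sd`` and compute the metric set."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("residuals must be non-empty")
    if not residual_sd > 0:
        raise ValueError("residual_sd must be positive")
    s = r / residual_sd
    mse = float(np.mean(s ** 2))
    deviance = -2.0 * loglik
    return FitMetrics(
        mse=mse, rmse=float(np.sqrt(mse)), mad=float(np.median(np.abs(s))),
        deviance=deviance,
        aic=deviance + 2 * n_params if include_aic else None)


def lmm_metrics(fit: LMMFit, panel: pd.DataFrame) -> FitMetrics:
    r = conditional_residuals(fit, panel)
    return compute_metrics(r, np.sqrt(fit.resid_var), fit.loglik_ml,
                           fit.n_params, include_aic=True)


def reem_metrics(model, panel: pd.DataFrame) -> FitMetrics:
    r = panel[model.response].to_numpy(dtype=float) - predict_reem(model, panel)
    return compute_metrics(r, np.sqrt(model.resid_var), model.loglik_ml,
                           model.n_params, include_aic=False)


# ---------------------------------------------------------------------------
# Rubin's rules


@dataclass
class PooledEstimate:
    """Rubin's-rules pooling of m per-imputation fits.

    ``table`` has one row per coefficient with columns estimate (mean of
    the m estimates), W (within-imputation variance = mean squared SE),
    B (between-imputation sample variance), T = W + (1 + 1/m) B, and
    se = sqrt(T).
    """
    table: pd.DataFrame
    m: int


def pool_rubin(per_dataset_fits) -> PooledEstimate:
    """Pool a list of (estimates, SEs) pairs (Series or dicts)."""
    fits = [(pd.Series(e), pd.Series(s)) for e, s in per_dataset_fits]
    m = len(fits)
    if m < 2:
        raise ValueError("Rubin pooling requires m >= 2 datasets")
    schema = list(fits[0][0].index)
    for e, s in fits:
        if list(e.index) != schema or list(s.index) != schema:
            raise ValueError("coefficient schema mismatch across fits")
    Q = pd.DataFrame([e for e, _ in fits])
    U = pd.DataFrame([s for _, s in fits]) ** 2
    qbar = Q.mean(axis=0)
    W = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    table = pd.DataFrame({"estimate": qbar, "W": W, "B": B, "T": T,
                          "se": np.sqrt(T)})
    return PooledEstimate(table=table, m=m)


# ---------------------------------------------------------------------------
# Replication harness


@dataclass
class ReplicationReport:
    """Per-(method, model) summary of a Monte-Carlo run.

    ``table`` holds the across-replicate mean of every recorded quantity
    plus its Monte-Carlo SE (columns suffixed ``_mcse`` = sd / sqrt(reps));
    ``per_replicate`` holds the raw rows.  Metrics are computed per
    replicate and averaged (not pooled across residuals).
    """
    table: pd.DataFrame
    per_replicate: pd.DataFrame
    config: SimulationConfig
    base_seed: int
    reps: int
    methods: list[str]
    models: list[str]
    failed: list[tuple[int, str]] = field(default_factory=list)


def _impute_both(amputed: pd.DataFrame, method: str, seed: int) -> pd.DataFrame:
    out = impute(amputed, "bmi", method, seed=seed,
                 on_degenerate="skip").panel
    out = impute(out, "dbp", method, seed=seed + 1000003,
                 on_degenerate="skip").panel
    return out


def _one_replicate(config: SimulationConfig, methods, models, seed: int,
                   controls: TreeControls) -> list[dict]:
    complete = generate_complete(config, seed)
    amputed = ampute_mar(complete, config, seed)
    rows = []
    for mi, method in enumerate(methods):
        if method == "complete":
            data = complete
        else:
            data = _impute_both(amputed, method, seed + 2000003 * (mi + 1))
            keep = data["bmi"].notna() & data["dbp"].notna()
            data = data[keep].reset_index(drop=True)
        for model in models:
            row = {"method": method, "model": model, "seed": seed}
            if model == "lmm":
                fit = fit_lmm(data, "dbp", ["age", "sex", "bmi", "time"],
                              method="REML")
                met = lmm_metrics(fit, data)
                for name in COEF_NAMES:
                    row[f"coef_{name}"] = fit.params[name]
                    row[f"se_{name}"] = fit.bse[name]
            elif model == "reem":
                reem = fit_reem(data, "dbp", ["age", "sex", "bmi", "time"],
                                controls)
                met = reem_metrics(reem, data)
            else:
                raise ValueError(f"unknown model {model!r}")
            row.update(met.to_dict())
            rows.append(row)
    return rows


def run_replication(config: SimulationConfig, methods, models,
                    reps: int, base_seed: int,
                    controls: TreeControls | None = None) -> ReplicationReport:
    """Run the Monte-Carlo comparison harness.

    ``methods`` may include any of the sixteen single-imputation names plus
    ``"complete"`` for the pre-amputation benchmark; ``models`` is a subset
    of {"lmm", "reem"}.  Replicate r uses seed base_seed + r for both
    generation and amputation (independent substreams), so every method
    sees identical data within a replicate.  A failed stage aborts its
    replicate; more than 5% failed replicates fails the run.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    methods = list(methods)
    models = list(models)
    for m in methods:
        if m != "complete" and m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    for m in models:
        if m not in ("lmm", "reem"):
            raise ValueError(f"unknown model {m!r}")
    if controls is None:
        controls = TreeControls()

    all_rows: list[dict] = []
    failed: list[tuple[int, str]] = []
    for r in range(reps):
        seed = base_seed + r
        try:
            all_rows.extend(
                _one_replicate(config, methods, models, seed, controls))
        except Exception as exc:  # noqa: BLE001 - logged and counted
            logger.warning("replicate %d (seed %d) failed: %s", r, seed, exc)
            failed.append((r, str(exc)))
    if len(failed) > 0.05 * reps:
        raise RuntimeError(
            f"{len(failed)}/{reps} replicates failed; first cause: "
            f"{failed[0][1]}")

    per_rep = pd.DataFrame(all_rows)
    num_cols = [c for c in per_rep.columns
                if c not in ("method", "model", "seed")]
    grouped = per_rep.groupby(["method", "model"], sort=False)[num_cols]
    means = grouped.mean()
    n_ok = grouped.count()
    mcse = grouped.std(ddof=1) / np.sqrt(n_ok)
    mcse.columns = [f"{c}_mcse" for c in mcse.columns]
    table = means.join(mcse)
    table["reps"] = grouped.size()
    table = table.reset_index()
    return ReplicationReport(table=table, per_replicate=per_rep,
                             config=config, base_seed=base_seed, reps=reps,
                             methods=methods, models=models, failed=failed)
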