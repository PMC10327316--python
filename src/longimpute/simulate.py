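"""Synthetic cohort generation and MAR amputation.

``generate_complete`` draws a fully observed six-wave panel; ``ampute_mar``
deletes BMI/DBP cells through wave-specific logistic models evaluated on the
complete (pre-deletion) data, so BMI missingness may depend on a DBP value
that is itself subsequently deleted — the two missingness indicators are
drawn independently cell by cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimulationConfig
from .panel import N_WAVES, PANEL_COLUMNS, PanelError, validate_panel

__all__ = ["generate_complete", "ampute_mar"]


def _rng(seed: int, stream: int) -> np.random.Generator:
    # Independent substreams: generation (0), amputation (1), hot-deck (2).
    return np.random.default_rng([int(seed), stream])


def _truncated_normal(rng: np.random.Generator, n: int,
                      mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    """Rejection sampling from N(mean, sd^2) restricted to [lo, hi]."""
    out = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        draw = rng.normal(mean, sd, int(todo.sum()))
        out[todo] = draw
        todo = (out < lo) | (out > hi)
    return out


def generate_complete(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a complete (no missing cells) long panel.

    Sex is Bernoulli(p_sex), constant within subject; baseline age is
    truncated normal and advances by ``wave_spacing_years`` per wave; BMI
    and DBP follow the configured linear models with one random-intercept
    draw per subject per outcome and independent per-wave residuals.
    Deterministic given (config, seed).
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, 0)
    n, w = config.n_subjects, config.n_waves

    sex = (rng.random(n) < config.p_sex).astype(float)
    age1 = _truncated_normal(rng, n, config.age_mean, config.age_sd,
                             config.age_min, config.age_max)
    age = age1[:, None] + config.wave_spacing_years * np.arange(w)

    b0, b_age, b_sex = config.bmi_coef
    re_bmi = rng.normal(0.0, config.sd(config.bmi_re_scale), n)
    eps_bmi = rng.normal(0.0, config.sd(config.bmi_resid_scale), (n, w))
    bmi = b0 + b_age * age + b_sex * sex[:, None] + re_bmi[:, None] + eps_bmi

    d0, d_age, d_sex, d_bmi = config.dbp_coef
    re_dbp = rng.normal(0.0, config.sd(config.dbp_re_scale), n)
    eps_dbp = rng.normal(0.0, config.sd(config.dbp_resid_scale), (n, w))
    dbp = (d0 + d_age * age + d_sex * sex[:, None] + d_bmi * bmi
           + re_dbp[:, None] + eps_dbp)

    waves = np.tile(np.arange(1, w + 1), n)
    panel = pd.DataFrame({
        "subject_id": np.repeat(np.arange(1, n + 1), w),
        "wave": waves,
        "time": waves.astype(float),
        "age": age.ravel(),
        "sex": np.repeat(sex, w),
        "bmi": bmi.ravel(),
        "dbp": dbp.ravel(),
    }, columns=PANEL_COLUMNS)
    return panel


def ampute_mar(panel: pd.DataFrame, config: SimulationConfig,
               seed: int | None = None) -> pd.DataFrame:
    """Inject MAR missingness into a complete panel.

    Each BMI cell is deleted with probability
    ``expit(beta0[j] + beta1*Age_ij + beta2*DBP_ij)`` and each DBP cell with
    ``expit(phi0[j] + phi1*Age_ij + phi2*BMI_ij)``, both evaluated on the
    complete data.  Retained values are unchanged bit-for-bit.
    """
    panel = validate_panel(panel)
    if panel["bmi"].isna().any() or panel["dbp"].isna().any():
        raise PanelError("ampute_mar requires a complete panel")
    if seed is None:
        seed = config.seed
    rng = _rng(seed, 1)

    wave_ix = panel["wave"].to_numpy() - 1
    beta0 = np.asarray(config.beta0)[wave_ix]
    phi0 = np.asarray(config.phi0)[wave_ix]
    age = panel["age"].to_numpy()
    bmi = panel["bmi"].to_numpy()
    dbp = panel["dbp"].to_numpy()

    p_bmi = expit(beta0 + config.beta1 * age + config.beta2 * dbp)
    p_dbp = expit(phi0 + config.phi1 * age + config.phi2 * bmi)
    drop_bmi = rng.random(len(panel)) < p_bmi
    drop_dbp = rng.random(len(panel)) < p_dbp

    out = panel.copy()
    out.loc[drop_bmi, "bmi"] = np.nan
    out.loc[drop_dbp, "dbp"] = np.nan
    return out
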