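"""The sixteen single-imputation methods for longitudinal panels.

Three families:

* cross-sectional — ``crossMean``, ``crossMedian``, ``crossHotDeck``: replace
  a missing cell with the mean / median / a uniform random draw of the
  values observed at the same wave across subjects;
* longitudinal — ``trajMean``, ``trajMedian``, ``trajHotDeck``, ``locf``,
  ``nocb`` and the four ``interpolation.*`` variants: use only the subject's
  own trajectory;
* cross-sectional-longitudinal — the four ``copyMean.*`` variants: an
  initial within-trajectory completion refined by the wave-level average
  variation AV_k between the population's observed mean trajectory and its
  initially-imputed mean trajectory.

All interpolation is linear in the wave index; waves are equally spaced, so
any affine time scale gives identical imputations.  Internal (intermittent)
gaps are filled by the line through the nearest observed neighbours; the
variants differ only in how they extend into leading/trailing (monotone)
gaps: ``locf`` carries the boundary value flat, ``global`` extends the line
through the first and last observed values, ``local`` uses the line through
the two boundary observed values, and ``bisector`` follows the angle
bisector of the global and local lines anchored at the boundary point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import matrix_to_panel, panel_to_matrix, validate_panel

__all__ = [
    "METHODS",
    "DegenerateTrajectoryError",
    "DegenerateWaveError",
    "ImputedPanel",
    "impute",
    "impute_cross",
    "impute_traj",
    "impute_locf_nocb",
    "interpolate_internal",
    "impute_interpolation",
    "impute_copy_mean",
]

METHODS = (
    "crossMean", "crossMedian", "crossHotDeck",
    "trajMean", "trajMedian", "trajHotDeck",
    "locf", "nocb",
    "interpolation.locf", "interpolation.global",
    "interpolation.local", "interpolation.bisector",
    "copyMean.locf", "copyMean.global",
    "copyMean.local", "copyMean.bisector",
)

_HOTDECK = {"crossHotDeck", "trajHotDeck"}


class DegenerateTrajectoryError(ValueError):
    """A trajectory has too few observed values for the chosen method."""


class DegenerateWaveError(ValueError):
    """A wave has zero observed values across subjects."""


@dataclass
class ImputedPanel:
    """A completed panel plus per-cell provenance.

    ``mask`` is a boolean matrix aligned with ``subjects`` x waves, True
    where the cell was imputed (originally missing).
    """
    panel: pd.DataFrame
    variable: str
    method: str
    subjects: np.ndarray
    mask: np.ndarray
    seed: int | None = None


# ---------------------------------------------------------------------------
# Trajectory-level kernels (1-D arrays, NaN = missing)


def _require_observed(y: np.ndarray, k: int, label: str) -> np.ndarray:
    obs = np.flatnonzero(~np.isnan(y))
    if obs.size < k:
        raise DegenerateTrajectoryError(
            f"trajectory {label}: needs >= {k} observed values, has {obs.size}")
    return obs


def impute_traj(y, stat: str, rng: np.random.Generator | None = None,
                label: str = "?") -> np.ndarray:
    """Replace missing cells with the trajectory's observed mean / median /
    a uniform draw from its observed values (``stat='hotdeck'``)."""
    y = np.asarray(y, dtype=float).copy()
    obs = _require_observed(y, 1, label)
    miss = np.isnan(y)
    vals = y[obs]
    if stat == "mean":
        y[miss] = vals.mean()
    elif stat == "median":
        y[miss] = np.median(vals)
    elif stat == "hotdeck":
        if rng is None:
            raise ValueError("hot-deck imputation requires a seeded rng")
        y[miss] = rng.choice(vals, size=int(miss.sum()), replace=True)
    else:
        raise ValueError(f"unknown stat {stat!r}")
    return y


def impute_cross(column, stat: str, rng: np.random.Generator | None = None,
                 wave: int | str = "?") -> np.ndarray:
    """Replace missing entries of one cross-section (values of all subjects
    at a single wave) with the observed mean / median / hot-deck draw."""
    col = np.asarray(column, dtype=float).copy()
    miss = np.isnan(col)
    vals = col[~miss]
    if vals.size == 0:
        raise DegenerateWaveError(f"wave {wave}: no observed values")
    if stat == "mean":
        col[miss] = vals.mean()
    elif stat == "median":
        col[miss] = np.median(vals)
    elif stat == "hotdeck":
        if rng is None:
            raise ValueError("hot-deck imputation requires a seeded rng")
        col[miss] = rng.choice(vals, size=int(miss.sum()), replace=True)
    else:
        raise ValueError(f"unknown stat {stat!r}")
    return col


def impute_locf_nocb(y, direction: str, label: str = "?") -> np.ndarray:
    """LOCF / NOCB with mutual fallback.

    ``locf``: each missing cell takes the nearest earlier observed value;
    leading cells (no earlier observation) fall back to the next observed
    value.  ``nocb`` is the mirror image with an LOCF fallback at the tail.
    """
    y = np.asarray(y, dtype=float)
    _require_observed(y, 1, label)
    s = pd.Series(y)
    if direction == "locf":
        return s.ffill().bfill().to_numpy()
    if direction == "nocb":
        return s.bfill().ffill().to_numpy()
    raise ValueError(f"unknown direction {direction!r}")


def interpolate_internal(y) -> np.ndarray:
    """Fill internal gaps by the line through the nearest observed
    neighbours: y_a + (k-a)*(y_b - y_a)/(b-a).  Leading/trailing gaps are
    left untouched; a trajectory with no internal gap passes through."""
    y = np.asarray(y, dtype=float)
    obs = np.flatnonzero(~np.isnan(y))
    if obs.size == 0:
        return y.copy()
    out = y.copy()
    idx = np.arange(y.size)
    inner = (idx > obs[0]) & (idx < obs[-1]) & np.isnan(y)
    if inner.any():
        out[inner] = np.interp(idx[inner], obs, y[obs])
    return out


def _bisector_slope(s1: float, s2: float) -> float:
    """Slope of the angle bisector of two lines with slopes s1, s2 (both
    taken in the forward direction), via unit direction vectors."""
    a1 = math.atan2(s1, 1.0)
    a2 = math.atan2(s2, 1.0)
    mid = (a1 + a2) / 2.0
    return math.tan(mid)


def impute_interpolation(y, variant: str, label: str = "?") -> np.ndarray:
    """Linear interpolation for internal gaps plus a tail strategy.

    ``locf`` needs >= 1 observed value; the line-based variants
    (``global``, ``local``, ``bisector``) need >= 2.
    """
    if variant == "locf":
        y = np.asarray(y, dtype=float)
        _require_observed(y, 1, label)
        out = interpolate_internal(y)
        return impute_locf_nocb(out, "locf", label)
    if variant not in ("global", "local", "bisector"):
        raise ValueError(f"unknown interpolation variant {variant!r}")
    y = np.asarray(y, dtype=float)
    obs = _require_observed(y, 2, label)
    out = interpolate_internal(y)
    f, l = obs[0], obs[-1]
    s_global = (y[l] - y[f]) / (l - f)
    s_head_local = (y[obs[1]] - y[f]) / (obs[1] - f)
    s_tail_local = (y[l] - y[obs[-2]]) / (l - obs[-2])
    if variant == "global":
        s_head = s_tail = s_global
    elif variant == "local":
        s_head, s_tail = s_head_local, s_tail_local
    else:
        s_head = _bisector_slope(s_global, s_head_local)
        s_tail = _bisector_slope(s_global, s_tail_local)
    idx = np.arange(y.size)
    head = idx < f
    tail = idx > l
    out[head] = y[f] + (idx[head] - f) * s_head
    out[tail] = y[l] + (idx[tail] - l) * s_tail
    return out


# ---------------------------------------------------------------------------
# Panel-level driver


def _traj_kernel(mat: np.ndarray, subjects: np.ndarray, method: str,
                 rng: np.random.Generator | None,
                 on_degenerate: str) -> np.ndarray:
    """Apply a within-trajectory method row-wise to an n x t matrix."""
    out = mat.copy()
    for i in np.flatnonzero(np.isnan(mat).any(axis=1)):
        row = mat[i]
        label = str(subjects[i])
        n_obs = int((~np.isnan(row)).sum())
        try:
            if method == "trajMean":
                out[i] = impute_traj(row, "mean", label=label)
            elif method == "trajMedian":
                out[i] = impute_traj(row, "median", label=label)
            elif method == "trajHotDeck":
                out[i] = impute_traj(row, "hotdeck", rng, label=label)
            elif method == "locf":
                out[i] = impute_locf_nocb(row, "locf", label)
            elif method == "nocb":
                out[i] = impute_locf_nocb(row, "nocb", label)
            elif method.startswith("interpolation."):
                variant = method.split(".", 1)[1]
                if (on_degenerate == "skip" and variant != "locf"
                        and n_obs == 1):
                    # no line is defined; constant extension
                    out[i] = impute_locf_nocb(row, "locf", label)
                else:
                    out[i] = impute_interpolation(row, variant, label)
            else:  # pragma: no cover
                raise ValueError(method)
        except DegenerateTrajectoryError:
            if on_degenerate == "raise":
                raise
            # skip: leave the row's missing cells missing
    return out


def _cross_kernel(mat: np.ndarray, method: str,
                  rng: np.random.Generator | None) -> np.ndarray:
    stat = {"crossMean": "mean", "crossMedian": "median",
            "crossHotDeck": "hotdeck"}[method]
    out = mat.copy()
    for k in range(mat.shape[1]):
        out[:, k] = impute_cross(mat[:, k], stat, rng, wave=k + 1)
    return out


def impute_copy_mean(panel: pd.DataFrame, variable: str, variant: str,
                     on_degenerate: str = "raise") -> ImputedPanel:
    """Copy-mean imputation: an initial LOCF/interpolation completion
    refined by the wave-level average variation.

    Step 1 completes every trajectory with the matching variant (``locf`` ->
    plain LOCF, otherwise the interpolation variant).  Step 2 computes, per
    wave k, the mean of the originally observed values, the mean of the
    step-1 completed values, their difference AV_k, and adds AV_k to every
    imputed cell.  Observed cells are untouched.
    """
    if variant not in ("locf", "global", "local", "bisector"):
        raise ValueError(f"unknown copy-mean variant {variant!r}")
    panel = validate_panel(panel)
    subjects, mat = panel_to_matrix(panel, variable)
    mask = np.isnan(mat)
    n_obs = (~mask).sum(axis=0)
    if (n_obs == 0).any():
        wave = int(np.flatnonzero(n_obs == 0)[0]) + 1
        raise DegenerateWaveError(f"wave {wave}: no observed values")
    obs_mean = np.where(mask, 0.0, mat).sum(axis=0) / n_obs
    step1_method = "locf" if variant == "locf" else f"interpolation.{variant}"
    step1 = _traj_kernel(mat, subjects, step1_method, None, on_degenerate)
    init_mean = np.nanmean(step1, axis=0)
    av = obs_mean - init_mean
    filled = np.isnan(mat) & ~np.isnan(step1)
    out = step1.copy()
    out[filled] = step1[filled] + np.broadcast_to(av, mat.shape)[filled]
    out[~mask] = mat[~mask]
    return ImputedPanel(matrix_to_panel(panel, variable, subjects, out),
                        variable, f"copyMean.{variant}", subjects, mask)


def impute(panel: pd.DataFrame, variable: str, method: str,
           seed: int | None = None,
           on_degenerate: str = "raise") -> ImputedPanel:
    """Dispatch one of the sixteen single-imputation methods.

    ``seed`` is required for the hot-deck methods and ignored otherwise.
    ``on_degenerate='skip'`` leaves cells that a method cannot impute
    (e.g. an all-missing trajectory) missing instead of raising; the
    provenance mask still marks exactly the originally missing cells.
    """
    if method not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid methods: {', '.join(METHODS)}")
    if on_degenerate not in ("raise", "skip"):
        raise ValueError("on_degenerate must be 'raise' or 'skip'")
    panel = validate_panel(panel)
    if variable not in ("bmi", "dbp"):
        raise ValueError(f"variable {variable!r} not in panel value columns")

    rng = None
    if method in _HOTDECK:
        if seed is None:
            raise ValueError(f"{method} requires a seed")
        rng = np.random.default_rng([int(seed), 2])

    if method.startswith("copyMean."):
        result = impute_copy_mean(panel, variable, method.split(".", 1)[1],
                                  on_degenerate)
        result.seed = seed
        return result

    subjects, mat = panel_to_matrix(panel, variable)
    mask = np.isnan(mat)
    if method.startswith("cross"):
        out = _cross_kernel(mat, method, rng)
    else:
        out = _traj_kernel(mat, subjects, method, rng, on_degenerate)
    out[~mask] = mat[~mask]
    return ImputedPanel(matrix_to_panel(panel, variable, subjects, out),
                        variable, method, subjects, mask, seed)
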