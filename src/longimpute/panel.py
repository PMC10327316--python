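"""Long-format panel container, missingness classification, and CSV/wide IO.

A panel is a tidy :class:`pandas.DataFrame` with one row per (subject, wave)
and columns ``subject_id, wave, time, age, sex, bmi, dbp``.  Missingness
lives in the *values* (NaN cells of ``bmi``/``dbp``), never in absent rows:
every subject carries all six wave rows.  ``sex`` and ``age`` are never
missing.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PANEL_COLUMNS",
    "N_WAVES",
    "PanelError",
    "validate_panel",
    "classify_missing",
    "missing_proportions",
    "to_wide",
    "from_wide",
    "read_long_csv",
    "write_long_csv",
    "panel_to_matrix",
    "matrix_to_panel",
]

PANEL_COLUMNS = ["subject_id", "wave", "time", "age", "sex", "bmi", "dbp"]
N_WAVES = 6
VALUE_COLUMNS = ["bmi", "dbp"]

OBSERVED = "observed"
LEADING = "leading"
INTERNAL = "internal"
TRAILING = "trailing"


class PanelError(ValueError):
    """Raised when a table violates the long-panel schema."""


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check the long-panel invariants and return the panel sorted by
    (subject_id, wave).

    Raises :class:`PanelError` on missing columns, duplicated
    (subject, wave) pairs, incomplete wave grids, out-of-range waves, or
    missing sex/age values.
    """
    missing_cols = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing_cols:
        raise PanelError(f"panel lacks required columns: {missing_cols}")
    if len(panel) == 0:
        raise PanelError("panel is empty")
    if panel.duplicated(["subject_id", "wave"]).any():
        dup = panel[panel.duplicated(["subject_id", "wave"])].iloc[0]
        raise PanelError(
            f"duplicate (subject_id, wave) pair: "
            f"({dup['subject_id']}, {dup['wave']})")
    waves = set(panel["wave"].unique())
    if not waves <= set(range(1, N_WAVES + 1)):
        raise PanelError(f"waves outside 1..{N_WAVES}: {sorted(waves)}")
    counts = panel.groupby("subject_id")["wave"].count()
    if (counts != N_WAVES).any():
        bad = counts.index[counts != N_WAVES][0]
        raise PanelError(f"subject {bad} does not have all {N_WAVES} waves")
    if panel["age"].isna().any() or panel["sex"].isna().any():
        raise PanelError("sex and age must never be missing")
    if not panel["sex"].isin([0, 1]).all():
        raise PanelError("sex must be coded 0/1")
    return panel.sort_values(["subject_id", "wave"], kind="mergesort").reset_index(drop=True)


def classify_missing(values: Sequence[float]) -> list[str]:
    """Classify each cell of one trajectory.

    ``observed`` for non-missing cells; ``internal`` for missing cells with
    observed values both before and after; ``trailing`` for missing cells
    after the last observation; ``leading`` for missing cells before the
    first observation.  An all-missing trajectory is classed all-trailing
    (treated as a dropout from the start).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("trajectory must have at least one cell")
    obs = ~np.isnan(arr)
    if not obs.any():
        return [TRAILING] * arr.size
    first, last = np.flatnonzero(obs)[[0, -1]]
    out = []
    for k in range(arr.size):
        if obs[k]:
            out.append(OBSERVED)
        elif k < first:
            out.append(LEADING)
        elif k > last:
            out.append(TRAILING)
        else:
            out.append(INTERNAL)
    return out


def missing_proportions(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-wave, per-variable missing proportions.

    Returns a DataFrame indexed by wave 1..6 with columns ``bmi`` and
    ``dbp``; each entry is (#missing at that wave) / n_subjects.
    """
    panel = validate_panel(panel)
    out = panel.groupby("wave")[VALUE_COLUMNS].apply(
        lambda g: g.isna().mean())
    out.index.name = "wave"
    return out


# ---------------------------------------------------------------------------
# Wide <-> long reshaping


def to_wide(panel: pd.DataFrame) -> pd.DataFrame:
    """One row per subject with ``bmi_w1..bmi_w6`` / ``dbp_w1..dbp_w6``."""
    panel = validate_panel(panel)
    base = panel[panel["wave"] == 1][["subject_id", "age", "sex"]]
    base = base.rename(columns={"age": "age_w1"}).set_index("subject_id")
    wide = base
    for var in VALUE_COLUMNS:
        piv = panel.pivot(index="subject_id", columns="wave", values=var)
        piv.columns = [f"{var}_w{w}" for w in piv.columns]
        wide = wide.join(piv)
    return wide.reset_index()


def from_wide(wide: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_wide` (age re-expanded on the 3-year grid)."""
    needed = (["subject_id", "age_w1", "sex"]
              + [f"{v}_w{w}" for v in VALUE_COLUMNS
                 for w in range(1, N_WAVES + 1)])
    lacking = [c for c in needed if c not in wide.columns]
    if lacking:
        raise PanelError(f"wide table lacks columns: {lacking}")
    rows = []
    for _, r in wide.iterrows():
        for w in range(1, N_WAVES + 1):
            rows.append({
                "subject_id": r["subject_id"],
                "wave": w,
                "time": w,
                "age": r["age_w1"] + (w - 1) * 3.0,
                "sex": r["sex"],
                "bmi": r[f"bmi_w{w}"],
                "dbp": r[f"dbp_w{w}"],
            })
    return validate_panel(pd.DataFrame(rows, columns=PANEL_COLUMNS))


# ---------------------------------------------------------------------------
# CSV round trip (missing cells: empty field on write; empty or "NA" on read)


def write_long_csv(panel: pd.DataFrame, path: str) -> None:
    panel = validate_panel(panel)
    panel.to_csv(path, index=False, na_rep="", float_format="%.17g")


def read_long_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=False,
                     float_precision="round_trip")
    header = list(df.columns)
    if header != PANEL_COLUMNS:
        raise PanelError(
            f"unexpected header {header}; expected {PANEL_COLUMNS}")
    for col in ("time", "age", "sex", "bmi", "dbp"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["wave"] = df["wave"].astype(int)
    return validate_panel(df)


# ---------------------------------------------------------------------------
# Dense matrix view used by the imputation kernels


def panel_to_matrix(panel: pd.DataFrame, variable: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (subjects, n_subjects x n_waves matrix) for ``variable``.

    The panel must already be validated/sorted; missing cells are NaN.
    """
    piv = panel.pivot(index="subject_id", columns="wave", values=variable)
    piv = piv.reindex(columns=range(1, N_WAVES + 1))
    return piv.index.to_numpy(), piv.to_numpy(dtype=float)


def matrix_to_panel(panel: pd.DataFrame, variable: str,
                    subjects: np.ndarray, mat: np.ndarray) -> pd.DataFrame:
    """Write a dense matrix of ``variable`` back into a copy of ``panel``."""
    out = panel.copy()
    long_vals = pd.DataFrame(mat, index=subjects,
                             columns=range(1, N_WAVES + 1)).stack(future_stack=True)
    key = pd.MultiIndex.from_frame(out[["subject_id", "wave"]])
    out[variable] = long_vals.reindex(key).to_numpy()
    return out
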