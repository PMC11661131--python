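"""Behavioral endpoint normalization and time-course testing.

Daily endpoints (infusions, active/inactive lever presses, percent active
presses) are normalized within each testing day by rank-based inverse normal
transformation (Blom scores), with tied values sharing their mean rank.
The time-course test fits the same random-intercept/random-slope model used
for mapping, without the kinship terms, and tests the fixed day effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, t as t_dist

from .lmm import fit_longitudinal_lmm

ENDPOINTS = ("infusions", "active_presses", "inactive_presses", "percent_active")


def percent_active(active, inactive):
    """100 * active / (active + inactive); undefined (NaN) when both are zero."""
    active = np.asarray(active, dtype=float)
    inactive = np.asarray(inactive, dtype=float)
    if np.any(active < 0) or np.any(inactive < 0):
        raise ValueError("press counts must be non-negative")
    total = active + inactive
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, 100.0 * active / total, np.nan)
    return out if out.ndim else float(out) if total > 0 else np.nan


def blom_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform (Blom's offsets).

    A value with (mean, for ties) rank r among n non-missing values maps to
    Phi^-1((r - 3/8) / (n + 1/4)). Missing values stay missing.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all values missing")
    if n < 2:
        raise ValueError("need at least two non-missing values")
    r = rankdata(values[ok], method="average")
    out[ok] = norm.ppf((r - 3.0 / 8.0) / (n + 0.25))
    return out


def normalize_endpoint(
    table: pd.DataFrame, endpoint: str, out_col: str | None = None, scope: str = "day"
) -> pd.DataFrame:
    """Blom-normalize an endpoint, by default within each testing day.

    For percent_active the ratio is computed first and cells where it is
    undefined (no presses at all) are excluded from the transform. The
    per-day scope is what association mapping uses (the SNP effect is a
    within-day contrast); it necessarily centers every day at zero, so
    analyses of the day trend itself must use ``scope='pooled'``, which
    ranks all mouse-day values together and preserves between-day structure.
    Returns a copy of the table with the normalized column added.
    """
    table = table.copy()
    if endpoint == "percent_active":
        raw = percent_active(table["active_presses"], table["inactive_presses"])
    else:
        raw = table[endpoint].to_numpy(dtype=float)
    col = out_col or f"{endpoint}_norm"
    if scope == "pooled":
        table[col] = blom_transform(raw)
    elif scope == "day":
        out = np.full(len(table), np.nan)
        for _, idx in table.groupby("day").groups.items():
            pos = table.index.get_indexer(idx)
            out[pos] = blom_transform(raw[pos])
        table[col] = out
    else:
        raise ValueError("scope must be 'day' or 'pooled'")
    return table


def _design_matrix(table: pd.DataFrame, include_day: bool = True):
    """Fixed-effect design: intercept, age, sex, lever, chamber + cohort dummies, day."""
    parts = [np.ones(len(table))]
    names = ["intercept"]
    for c in ("age_weeks", "sex", "lever"):
        parts.append(table[c].to_numpy(dtype=float))
        names.append(c)
    for c in ("chamber", "cohort"):
        dummies = pd.get_dummies(table[c].astype("category"), prefix=c, drop_first=True)
        for col in dummies.columns:
            parts.append(dummies[col].to_numpy(dtype=float))
            names.append(str(col))
    if include_day:
        parts.append(table["day"].to_numpy(dtype=float))
        names.append("day")
    return np.column_stack(parts), names


def time_course_test(table: pd.DataFrame, endpoint: str) -> dict:
    """Test the fixed day effect of a Blom-normalized endpoint time course.

    Fits the mixed model with fixed effects of day (continuous), sex, lever
    side, chamber, cohort and age plus a per-mouse random intercept and day
    slope (no kinship terms), and returns the day slope estimate with a
    Satterthwaite-type t test.
    """
    if table["mouse_id"].nunique() < 2:
        raise ValueError("time-course test needs at least two mice")
    norm_tab = normalize_endpoint(table, endpoint, out_col="_y", scope="pooled")
    norm_tab = norm_tab.dropna(subset=["_y"])
    X, names = _design_matrix(norm_tab)
    fit = fit_longitudinal_lmm(
        y=norm_tab["_y"].to_numpy(),
        X=X,
        day=norm_tab["day"].to_numpy(dtype=float),
        mouse=norm_tab["mouse_id"].to_numpy(),
        K=None,
        include_genetic=False,
        fixef_names=names,
    )
    j = names.index("day")
    slope = float(fit.fixef[j])
    se = float(np.sqrt(fit.fixef_cov[j, j]))
    df = fit.satterthwaite_df(j)
    tval = slope / se
    p = 2.0 * t_dist.sf(abs(tval), df)
    return {
        "endpoint": endpoint,
        "slope": slope,
        "se": se,
        "t": tval,
        "df": df,
        "p": float(p),
        "df_method": fit.df_method,
        "converged": fit.converged,
    }
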