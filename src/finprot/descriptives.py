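"""Expenditure quintiles and descriptive utilization / OOP summaries.

Households are ranked into quintiles of a living-standard variable
(per-capita expenditure by default).  On top of the assignment the module
tabulates health-service utilization proportions per group with a Pearson
chi-square test of independence, and mean OOP payments per quintile with
the richest-to-poorest ratio — the classic descriptive openers of a
financial-protection analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .survey import SurveyDataset, per_capita_expenditure

__all__ = [
    "QuintileAssignment",
    "assign_quintiles",
    "utilization_by_group",
    "oop_by_quintile",
]


@dataclass
class QuintileAssignment:
    """Quintile (1 = poorest .. 5 = richest) per household, plus cutoffs."""

    quintile: np.ndarray
    cutoffs: np.ndarray  # rank-variable value at the Q1..Q4 upper edges
    rank_variable: str


def assign_quintiles(
    dataset: SurveyDataset,
    rank_variable: Literal["per_capita_expenditure", "total_expenditure"] = "per_capita_expenditure",
    weights=None,
) -> QuintileAssignment:
    """Partition households into weighted quintiles of a living standard.

    Households are stably sorted by the rank variable (ties keep input
    order) and the cumulative weight is split at 20/40/60/80 %.  A household
    straddling a cut belongs to the quintile containing the midpoint of its
    own weight span, so each quintile holds 20 % of the weight up to one
    household's worth.
    """
    n = dataset.n_households
    if n < 5:
        raise InputError(f"quintile assignment needs at least 5 households, got {n}")
    if rank_variable == "per_capita_expenditure":
        v = per_capita_expenditure(dataset)
    elif rank_variable == "total_expenditure":
        v = dataset.total_expenditure
    else:
        raise InputError(f"unknown rank variable: {rank_variable!r}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    order = np.argsort(v, kind="stable")
    w_sorted = w[order]
    total = w_sorted.sum()
    mid = (np.cumsum(w_sorted) - w_sorted / 2.0) / total
    q_sorted = np.minimum((mid * 5).astype(int), 4) + 1
    quintile = np.empty(n, dtype=int)
    quintile[order] = q_sorted

    v_sorted = v[order]
    cutoffs = np.array(
        [v_sorted[q_sorted <= q].max() if np.any(q_sorted <= q) else v_sorted[0] for q in (1, 2, 3, 4)]
    )
    return QuintileAssignment(quintile=quintile, cutoffs=cutoffs, rank_variable=rank_variable)


def utilization_by_group(
    dataset: SurveyDataset,
    assignment: QuintileAssignment,
    indicator: Literal["outpatient", "inpatient"],
    strata: Literal["urban"] | None = None,
) -> pd.DataFrame:
    """Utilization proportion per quintile (or stratum) with a chi-square test.

    Returns one row per group plus an ``All`` row, with columns ``n``,
    ``n_used``, ``proportion``, and the Pearson chi-square p-value of the
    group-by-indicator independence test attached to every group row
    (``NaN`` on the ``All`` row, or everywhere when the table is degenerate,
    e.g. nobody used the service).
    """
    col = f"used_{indicator}"
    flags = dataset.optional_column(col)
    if flags is None:
        raise ConfigurationError(f"indicator column {col!r} absent from dataset")
    flags = np.asarray(flags, dtype=float)
    valid = ~np.isnan(flags)

    if strata == "urban":
        urban = dataset.optional_column("urban")
        if urban is None:
            raise ConfigurationError("stratum column 'urban' absent from dataset")
        groups = np.where(np.asarray(urban, dtype=float) == 1, "Urban", "Rural")
        group_order = ["Urban", "Rural"]
    elif strata is None:
        groups = np.array([f"Q{q}" for q in assignment.quintile])
        group_order = [f"Q{q}" for q in (1, 2, 3, 4, 5)]
    else:
        raise ConfigurationError(f"unknown stratum: {strata!r}")

    rows = []
    for g in group_order:
        m = (groups == g) & valid
        n = int(m.sum())
        used = int(np.nansum(flags[m]))
        rows.append({"group": g, "n": n, "n_used": used,
                     "proportion": used / n if n else np.nan})
    n_all = int(valid.sum())
    used_all = int(np.nansum(flags[valid]))
    rows.append({"group": "All", "n": n_all, "n_used": used_all,
                 "proportion": used_all / n_all if n_all else np.nan})
    table = pd.DataFrame(rows).set_index("group")

    counts = table.loc[group_order]
    contingency = np.c_[counts["n_used"], counts["n"] - counts["n_used"]]
    contingency = contingency[contingency.sum(axis=1) > 0]
    degenerate = (
        contingency.shape[0] < 2
        or contingency[:, 0].sum() == 0
        or contingency[:, 1].sum() == 0
    )
    if degenerate:
        table["p_value"] = np.nan
        table.attrs["test"] = "skipped (degenerate table)"
    else:
        res = stats.chi2_contingency(contingency, correction=False)
        table["p_value"] = np.where(table.index == "All", np.nan, res.pvalue)
        table.attrs["test"] = "pearson-chi2"
        table.attrs["chi2"] = float(res.statistic)
        table.attrs["dof"] = int(res.dof)
    return table


def oop_by_quintile(
    dataset: SurveyDataset,
    assignment: QuintileAssignment,
    weights=None,
) -> pd.DataFrame:
    """(Weighted) mean OOP per quintile and overall, with the Q5/Q1 ratio.

    The ratio is stored in ``table.attrs["q5_q1_ratio"]`` (NaN when the
    poorest quintile's mean is zero).
    """
    oop = dataset.oop_health
    w = np.ones(dataset.n_households) if weights is None else np.asarray(weights, dtype=float)
    rows = []
    for q in (1, 2, 3, 4, 5):
        m = assignment.quintile == q
        rows.append({"group": f"Q{q}",
                     "mean_oop": float(np.sum(w[m] * oop[m]) / np.sum(w[m]))})
    rows.append({"group": "All", "mean_oop": float(np.sum(w * oop) / np.sum(w))})
    table = pd.DataFrame(rows).set_index("group")
    q1, q5 = table.loc["Q1", "mean_oop"], table.loc["Q5", "mean_oop"]
    table.attrs["q5_q1_ratio"] = q5 / q1 if q1 > 0 else float("nan")
    return table
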