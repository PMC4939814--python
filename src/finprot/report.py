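"""Table rendering for catastrophic-payment and impoverishment results.

Layouts mirror the standard presentation of a financial-protection study:
measures as rows, thresholds (or poverty lines x gross/net/absolute/relative)
as columns.  All computation upstream is full precision; rounding to
percentage points happens only here, in the ``text`` format — ``csv`` and
``json`` carry raw floats so derived identities survive serialization.
"""

from __future__ import annotations

import json
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .catastrophic import CatastrophicResult
from .errors import InputError
from .impoverishment import ImpoverishmentComparison

__all__ = ["catastrophic_frame", "impoverishment_frame", "render_table"]

Format = Literal["csv", "json", "text"]

_CAT_ROWS = [
    ("head_count", "Head count"),
    ("ci_incidence", "Concentration index C_E"),
    ("weighted_head_count", "Rank-weighted head count"),
    ("mean_overshoot", "Mean overshoot"),
    ("ci_overshoot", "Concentration index C_O"),
    ("weighted_overshoot", "Rank-weighted overshoot"),
    ("mpo", "Mean positive overshoot"),
]
# measures expressed as budget-share fractions, shown as % in text output
_CAT_PERCENT = {"head_count", "weighted_head_count", "mean_overshoot",
                "weighted_overshoot", "mpo"}

_POV_ROWS = [
    ("head_count", "Poverty head count"),
    ("gap", "Poverty gap"),
    ("normalized_gap", "Normalized poverty gap"),
    ("normalized_mean_positive_gap", "Normalized mean positive gap"),
]
_POV_PERCENT = {"head_count", "normalized_gap", "normalized_mean_positive_gap"}


def catastrophic_frame(results: Sequence[CatastrophicResult]) -> pd.DataFrame:
    """Measure-by-threshold DataFrame (raw fractions, NaN where undefined)."""
    if not results:
        raise InputError("no results to render")
    data = {}
    for res in results:
        col = res.threshold.label
        data[col] = {
            label: (np.nan if getattr(res, attr) is None else getattr(res, attr))
            for attr, label in _CAT_ROWS
        }
    frame = pd.DataFrame(data)
    frame.index.name = "measure"
    return frame


def impoverishment_frame(
    comparisons: Sequence[ImpoverishmentComparison],
) -> pd.DataFrame:
    """Gross/net/absolute/relative columns per poverty line (raw values)."""
    comparisons = list(comparisons)
    if not comparisons:
        raise InputError("no results to render")
    data = {}
    for cmp_ in comparisons:
        line = cmp_.gross.line
        label = line.label or f"PL={line.value:g}"
        for col, values in (
            ("gross", {a: getattr(cmp_.gross, a) for a, _ in _POV_ROWS}),
            ("net", {a: getattr(cmp_.net, a) for a, _ in _POV_ROWS}),
            ("absolute", cmp_.absolute_change),
            ("relative", cmp_.relative_change),
        ):
            data[(label, col)] = {
                lbl: (np.nan if values[a] is None else values[a]) for a, lbl in _POV_ROWS
            }
    frame = pd.DataFrame(data)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=["line", "basis"])
    frame.index.name = "measure"
    return frame


def _cat_text(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy().astype(object)
    for attr, label in _CAT_ROWS:
        for col in frame.columns:
            v = frame.loc[label, col]
            if pd.isna(v):
                out.loc[label, col] = "undefined"
            elif attr in _CAT_PERCENT:
                out.loc[label, col] = f"{100 * v:.2f} %"
            else:
                out.loc[label, col] = f"{v:.2f}"
    return out


def _pov_text(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy().astype(object)
    for attr, label in _POV_ROWS:
        for col in frame.columns:
            v = frame.loc[label, col]
            relative = col[-1] == "relative"
            if pd.isna(v):
                out.loc[label, col] = "undefined"
            elif attr in _POV_PERCENT or relative:
                out.loc[label, col] = f"{100 * v:.2f} %"
            else:
                out.loc[label, col] = f"{v:.2f}"
    return out


def render_table(result, format: Format = "text") -> str:
    """Serialize results as csv, json (raw floats) or an aligned text table.

    ``result`` is a sequence of :class:`CatastrophicResult`, a single
    :class:`ImpoverishmentComparison`, or a sequence of comparisons (one
    column panel per poverty line).
    """
    if isinstance(result, ImpoverishmentComparison):
        result = [result]
    if isinstance(result, Sequence) and result and isinstance(result[0], ImpoverishmentComparison):
        frame = impoverishment_frame(result)
        text_frame = _pov_text(frame)
        flat = frame.copy()
        flat.columns = [f"{a}|{b}" for a, b in frame.columns]
    elif isinstance(result, Sequence) and result and isinstance(result[0], CatastrophicResult):
        frame = catastrophic_frame(result)
        text_frame = _cat_text(frame)
        flat = frame
    else:
        raise InputError(f"cannot render object of type {type(result).__name__}")

    if format == "csv":
        return flat.to_csv()
    if format == "json":
        payload = {c: {m: (None if pd.isna(v) else v) for m, v in flat[c].items()}
                   for c in flat.columns}
        return json.dumps(payload, indent=2)
    if format == "text":
        return text_frame.to_string()
    raise InputError(f"unknown output format: {format!r}")
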