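"""Household survey container, CSV ingestion and validation.

The unit of observation is the household: total expenditure ``x_i``, food
expenditure, out-of-pocket (OOP) health payments ``T_i``, household size
``s_i`` and an optional sampling weight, all for a common reference period
and currency.  Two derived living-standard measures are used throughout the
package:

* capacity to pay ``nf(x_i) = x_i - food_i`` (non-food expenditure), and
* per-capita expenditure ``y_i = x_i / s_i`` (optionally net of OOP).

Validation enforces the accounting identities the downstream measures
presuppose: OOP and food are components of total expenditure (``T_i <= x_i``,
``food_i <= x_i``), so budget shares and net-of-OOP expenditures stay
interpretable.  Monetary values are kept in input currency units; any
period harmonization is done at load time via per-column multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, ValidationError

__all__ = [
    "HouseholdRecord",
    "SurveyDataset",
    "LoadReport",
    "read_survey",
    "build_dataset",
    "capacity_to_pay",
    "per_capita_expenditure",
    "MANDATORY_FIELDS",
    "OPTIONAL_FIELDS",
]

MANDATORY_FIELDS = ("total_expenditure", "food_expenditure", "oop_health", "size")
OPTIONAL_FIELDS = ("weight", "urban", "used_outpatient", "used_inpatient")

ValidationPolicy = Literal["strict", "drop", "clamp"]


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household.

    Attributes
    ----------
    total_expenditure : float
        Total household expenditure per period (> 0).
    food_expenditure : float
        Food expenditure per period (>= 0, <= total).
    oop_health : float
        Out-of-pocket health payments per period (>= 0, <= total).
    size : int
        Number of household members (>= 1).
    weight : float
        Sampling weight (> 0, default 1).
    urban, used_outpatient, used_inpatient : int or None
        Optional binary stratum / utilization flags.
    """

    total_expenditure: float
    food_expenditure: float
    oop_health: float
    size: int
    weight: float = 1.0
    urban: int | None = None
    used_outpatient: int | None = None
    used_inpatient: int | None = None

    @property
    def capacity_to_pay(self) -> float:
        return self.total_expenditure - self.food_expenditure


@dataclass
class LoadReport:
    """Tally of what happened while reading and validating a CSV."""

    rows_read: int = 0
    rows_dropped: dict[str, int] = field(default_factory=dict)
    cells_clamped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.rows_dropped.values())

    @property
    def n_clamped(self) -> int:
        return sum(self.cells_clamped.values())

    def as_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "rows_dropped": dict(self.rows_dropped),
            "cells_clamped": dict(self.cells_clamped),
        }


@dataclass
class SurveyDataset:
    """A validated collection of household records.

    Backed by a :class:`pandas.DataFrame` with canonical column names
    (``total_expenditure``, ``food_expenditure``, ``oop_health``, ``size``,
    ``weight`` and the optional flags).  All rows satisfy the record
    invariants; constructing one through :func:`read_survey` or
    :func:`build_dataset` guarantees this.
    """

    frame: pd.DataFrame
    source_label: str = ""
    load_report: LoadReport | None = None

    @property
    def n_households(self) -> int:
        return len(self.frame)

    @property
    def total_expenditure(self) -> np.ndarray:
        return self.frame["total_expenditure"].to_numpy(dtype=float)

    @property
    def food_expenditure(self) -> np.ndarray:
        return self.frame["food_expenditure"].to_numpy(dtype=float)

    @property
    def oop_health(self) -> np.ndarray:
        return self.frame["oop_health"].to_numpy(dtype=float)

    @property
    def size(self) -> np.ndarray:
        return self.frame["size"].to_numpy(dtype=int)

    @property
    def weight(self) -> np.ndarray:
        return self.frame["weight"].to_numpy(dtype=float)

    def optional_column(self, name: str) -> np.ndarray | None:
        if name in self.frame.columns and not self.frame[name].isna().all():
            return self.frame[name].to_numpy()
        return None

    @property
    def records(self) -> Iterator[HouseholdRecord]:
        opt = {n: self.optional_column(n) for n in ("urban", "used_outpatient", "used_inpatient")}
        for i, row in enumerate(self.frame.itertuples(index=False)):
            yield HouseholdRecord(
                total_expenditure=float(row.total_expenditure),
                food_expenditure=float(row.food_expenditure),
                oop_health=float(row.oop_health),
                size=int(row.size),
                weight=float(row.weight),
                **{
                    k: (int(v[i]) if v is not None and not pd.isna(v[i]) else None)
                    for k, v in opt.items()
                },
            )

    def to_csv(self, path_or_buf=None, column_map: Mapping[str, str] | None = None):
        """Write the dataset back to CSV, optionally renaming to survey columns."""
        out = self.frame.copy()
        keep = [c for c in out.columns if not out[c].isna().all()]
        out = out[keep]
        if column_map:
            out = out.rename(columns={f: c for f, c in _names_only(column_map).items()})
        return out.to_csv(path_or_buf, index=False)


def _names_only(column_map: Mapping) -> dict[str, str]:
    """Column map values may be a name or (name, multiplier); return names."""
    names = {}
    for fld, spec in column_map.items():
        if isinstance(spec, (tuple, list)):
            names[fld] = spec[0]
        else:
            names[fld] = spec
    return names


def _multipliers(column_map: Mapping) -> dict[str, float]:
    mult = {}
    for fld, spec in column_map.items():
        if isinstance(spec, (tuple, list)) and len(spec) > 1:
            mult[fld] = float(spec[1])
    return mult


def read_survey(
    path,
    column_map: Mapping[str, str | tuple] | None = None,
    validation_policy: ValidationPolicy = "strict",
    source_label: str | None = None,
) -> SurveyDataset:
    """Read a household survey CSV into a validated :class:`SurveyDataset`.

    Parameters
    ----------
    path : str, Path or file-like
        CSV with a header row.
    column_map : mapping, optional
        Maps canonical field names (``total_expenditure`` ...) to the CSV's
        column names.  A value may also be a ``(name, multiplier)`` pair to
        rescale the column at load time (period harmonization, e.g. annual
        to monthly).  Defaults to identity mapping on the canonical names.
    validation_policy : {"strict", "drop", "clamp"}
        ``strict`` raises on any violated invariant; ``drop`` removes the
        offending rows; ``clamp`` repairs what it can (negatives floored at
        0, food and OOP capped at total) and drops only unfixable rows
        (non-positive total, size < 1, non-numeric cells).  A per-rule tally
        is kept in ``dataset.load_report``.
    """
    if column_map is None:
        column_map = {f: f for f in MANDATORY_FIELDS + OPTIONAL_FIELDS}
    missing = [f for f in MANDATORY_FIELDS if f not in column_map]
    if missing:
        raise ConfigurationError(
            f"column_map is missing mandatory field(s): {', '.join(missing)}"
        )

    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty survey file: {path!r}") from exc
    except OSError as exc:
        raise InputError(f"cannot read survey file {path!r}: {exc}") from exc
    if raw.empty:
        raise InputError(f"survey file has a header but no rows: {path!r}")

    names = _names_only(column_map)
    mult = _multipliers(column_map)
    for fld in MANDATORY_FIELDS:
        if names[fld] not in raw.columns:
            raise ConfigurationError(
                f"mandatory column {names[fld]!r} (field {fld!r}) not found in CSV header"
            )

    frame = pd.DataFrame(index=raw.index)
    for fld in MANDATORY_FIELDS + OPTIONAL_FIELDS:
        col = names.get(fld)
        if col is not None and col in raw.columns:
            frame[fld] = pd.to_numeric(raw[col], errors="coerce")
            if fld in mult:
                frame[fld] = frame[fld] * mult[fld]
        elif fld == "weight":
            frame[fld] = 1.0
        else:
            frame[fld] = np.nan
    if frame["weight"].isna().all():
        frame["weight"] = 1.0

    label = source_label if source_label is not None else str(getattr(path, "name", path))
    return build_dataset(frame, validation_policy=validation_policy, source_label=label)


def build_dataset(
    frame: pd.DataFrame,
    validation_policy: ValidationPolicy = "strict",
    source_label: str = "",
) -> SurveyDataset:
    """Validate a canonical-column DataFrame and wrap it as a SurveyDataset."""
    if validation_policy not in ("strict", "drop", "clamp"):
        raise ConfigurationError(f"unknown validation policy: {validation_policy!r}")
    report = LoadReport(rows_read=len(frame))
    f = frame.copy()
    if "weight" not in f.columns:
        f["weight"] = 1.0
    f["weight"] = f["weight"].fillna(1.0)

    def _violation(mask: pd.Series, rule: str, n: int):
        rows = f.index[mask][:5].tolist()
        raise ValidationError(f"rule {rule!r} violated by {n} row(s), e.g. rows {rows}")

    def _drop(mask: pd.Series, rule: str):
        nonlocal f
        n = int(mask.sum())
        if n == 0:
            return
        if validation_policy == "strict":
            _violation(mask, rule, n)
        report.rows_dropped[rule] = report.rows_dropped.get(rule, 0) + n
        f = f.loc[~mask]

    def _clamp(mask: pd.Series, rule: str, column: str, repaired: pd.Series):
        n = int(mask.sum())
        if n == 0:
            return
        if validation_policy == "strict":
            _violation(mask, rule, n)
        if validation_policy == "drop":
            _drop(mask, rule)
            return
        report.cells_clamped[rule] = report.cells_clamped.get(rule, 0) + n
        f.loc[mask, column] = repaired[mask]

    # unparseable / missing mandatory cells: never repairable
    _drop(f[list(MANDATORY_FIELDS)].isna().any(axis=1), "numeric")
    _drop(f["total_expenditure"] <= 0, "total>0")
    _drop((f["size"] < 1) | (f["size"] % 1 != 0), "size>=1")
    _drop(f["weight"] <= 0, "weight>0")

    _clamp(f["food_expenditure"] < 0, "food>=0", "food_expenditure",
           f["food_expenditure"].clip(lower=0.0))
    _clamp(f["oop_health"] < 0, "oop>=0", "oop_health",
           f["oop_health"].clip(lower=0.0))
    _clamp(f["food_expenditure"] > f["total_expenditure"], "food<=total",
           "food_expenditure", f["total_expenditure"])
    _clamp(f["oop_health"] > f["total_expenditure"], "oop<=total",
           "oop_health", f["total_expenditure"])

    f = f.reset_index(drop=True)
    if f.empty:
        raise InputError("no valid rows remain after validation")
    f["size"] = f["size"].astype(int)
    for c in ("total_expenditure", "food_expenditure", "oop_health", "weight"):
        f[c] = f[c].astype(float)
    return SurveyDataset(frame=f, source_label=source_label, load_report=report)


def capacity_to_pay(dataset: SurveyDataset) -> np.ndarray:
    """Non-food expenditure ``nf(x_i) = x_i - food_i`` per household."""
    return dataset.total_expenditure - dataset.food_expenditure


def per_capita_expenditure(dataset: SurveyDataset, net_of_oop: bool = False) -> np.ndarray:
    """Per-capita expenditure ``y_i = x_i / s_i``; net subtracts household OOP first."""
    x = dataset.total_expenditure
    if net_of_oop:
        x = x - dataset.oop_health
    return x / dataset.size


def dataset_from_records(records, source_label: str = "") -> SurveyDataset:
    """Convenience constructor from an iterable of HouseholdRecord (strict)."""
    rows = [
        {
            "total_expenditure": r.total_expenditure,
            "food_expenditure": r.food_expenditure,
            "oop_health": r.oop_health,
            "size": r.size,
            "weight": r.weight,
            "urban": np.nan if r.urban is None else r.urban,
            "used_outpatient": np.nan if r.used_outpatient is None else r.used_outpatient,
            "used_inpatient": np.nan if r.used_inpatient is None else r.used_inpatient,
        }
        for r in records
    ]
    if not rows:
        raise InputError("no records supplied")
    return build_dataset(pd.DataFrame(rows), "strict", source_label)
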