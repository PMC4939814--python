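"""Incidence and intensity of catastrophic health payments.

A household incurs catastrophic health expenditure when its out-of-pocket
(OOP) budget share ``T_i / x_i`` (or ``T_i / nf(x_i)`` with capacity to pay
as denominator) strictly exceeds a threshold ``z``.  The measures:

* head count ``H`` — fraction of households exceeding ``z``;
* overshoot ``O`` — mean excess share ``E_i * (share_i - z)`` over all
  households, with the mean positive overshoot ``MPO = O / H`` the average
  excess among exceeders only;
* concentration indices ``C_E`` and ``C_O`` — twice the covariance of the
  exceedance indicator (resp. overshoot) with the fractional living-standard
  rank, divided by the mean; positive values mean the burden is concentrated
  among the better-off;
* rank-weighted variants ``H_w = H * (1 - C_E)`` and ``O_w = O * (1 - C_O)``,
  equivalently a weighted mean with weights ``2 * (1 - r_i)`` that give the
  poorest household weight 2 declining to 0 for the richest.

All functions accept optional sampling weights; the default gives every
household equal weight, matching the plain ``1/N`` estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateDenominatorError, InputError, UndefinedIndexError
from .survey import SurveyDataset, capacity_to_pay

__all__ = [
    "Threshold",
    "CatastrophicResult",
    "DEFAULT_THRESHOLDS",
    "oop_share",
    "head_count",
    "overshoot",
    "fractional_rank",
    "concentration_index",
    "rank_weighted_measures",
    "catastrophic_table",
]

Denominator = Literal["total_expenditure", "capacity_to_pay"]


@dataclass(frozen=True)
class Threshold:
    """A budget-share threshold ``z`` in (0, 1) with its denominator."""

    z: float
    denominator: Denominator = "total_expenditure"

    def __post_init__(self):
        if not 0.0 < self.z < 1.0:
            raise InputError(f"threshold z must be in (0, 1), got {self.z}")
        if self.denominator not in ("total_expenditure", "capacity_to_pay"):
            raise InputError(f"unknown denominator: {self.denominator!r}")

    @property
    def label(self) -> str:
        kind = "total" if self.denominator == "total_expenditure" else "ctp"
        return f"{self.z:g}/{kind}"


#: Threshold grid used by default for the summary table: 5/10/15/25 % of
#: total expenditure and 15/25/40 % of capacity to pay.
DEFAULT_THRESHOLDS: tuple[Threshold, ...] = (
    Threshold(0.05, "total_expenditure"),
    Threshold(0.10, "total_expenditure"),
    Threshold(0.15, "total_expenditure"),
    Threshold(0.25, "total_expenditure"),
    Threshold(0.15, "capacity_to_pay"),
    Threshold(0.25, "capacity_to_pay"),
    Threshold(0.40, "capacity_to_pay"),
)


@dataclass
class CatastrophicResult:
    """All catastrophic-payment measures at one threshold."""

    threshold: Threshold
    head_count: float
    mean_overshoot: float
    mpo: float | None  # None when head_count == 0 (0/0 undefined)
    ci_incidence: float
    ci_overshoot: float | None
    weighted_head_count: float
    weighted_overshoot: float | None
    exceed_indicator: np.ndarray
    household_overshoot: np.ndarray

    @property
    def mpo_defined(self) -> bool:
        return self.mpo is not None


def _as_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise InputError(f"weights length {w.shape} does not match data length {n}")
    if np.any(w <= 0):
        raise InputError("weights must be strictly positive")
    return w


def oop_share(
    dataset: SurveyDataset,
    denominator: Denominator = "total_expenditure",
    on_degenerate: Literal["clamp", "strict"] = "clamp",
) -> np.ndarray:
    """OOP budget share per household, in [0, 1].

    With the capacity-to-pay denominator, a household whose OOP exceeds its
    non-food budget (food + OOP > total — possible because validation bounds
    each component by the total, not their sum) would have a share above 1;
    such shares are clamped to 1 with a warning so they stay interpretable
    as budget fractions, or raise under ``on_degenerate="strict"``.
    Households with a zero denominator and zero OOP get share 0.
    """
    t = dataset.oop_health
    if denominator == "total_expenditure":
        denom = dataset.total_expenditure
    elif denominator == "capacity_to_pay":
        denom = capacity_to_pay(dataset)
    else:
        raise InputError(f"unknown denominator: {denominator!r}")

    share = np.zeros(dataset.n_households)
    pos = denom > 0
    share[pos] = t[pos] / denom[pos]

    degenerate = (~pos) & (t > 0)
    over = share > 1.0
    if np.any(degenerate) or np.any(over):
        idx = np.flatnonzero(degenerate | over)
        if on_degenerate == "strict":
            raise DegenerateDenominatorError(
                f"OOP exceeds the {denominator} denominator for rows {idx[:10].tolist()}"
            )
        warnings.warn(
            f"{idx.size} household(s) with OOP above their {denominator}; "
            "shares clamped to 1.0",
            stacklevel=2,
        )
        share[degenerate] = 1.0
        np.clip(share, 0.0, 1.0, out=share)
    return share


def head_count(shares: Sequence[float], z: float, weights=None) -> float:
    """Catastrophic head count: (weighted) fraction of shares strictly above z."""
    s = np.asarray(shares, dtype=float)
    if s.size == 0:
        raise InputError("head_count needs at least one household")
    if not 0.0 < z < 1.0:
        raise InputError(f"threshold z must be in (0, 1), got {z}")
    w = _as_weights(weights, s.size)
    e = (s > z).astype(float)
    return float(np.sum(w * e) / np.sum(w))


def overshoot(
    shares: Sequence[float], z: float, weights=None
) -> tuple[np.ndarray, float, float | None]:
    """Household overshoots ``O_i = E_i (share_i - z)``, their mean, and MPO.

    Returns ``(O_i vector, O, MPO)``; MPO is ``O / H`` and is ``None`` when
    no household exceeds the threshold (H = 0 makes 0/0 undefined).
    """
    s = np.asarray(shares, dtype=float)
    if s.size == 0:
        raise InputError("overshoot needs at least one household")
    if not 0.0 < z < 1.0:
        raise InputError(f"threshold z must be in (0, 1), got {z}")
    w = _as_weights(weights, s.size)
    e = s > z
    o_i = np.where(e, s - z, 0.0)
    o = float(np.sum(w * o_i) / np.sum(w))
    h = float(np.sum(w * e) / np.sum(w))
    mpo = o / h if h > 0 else None
    return o_i, o, mpo


def fractional_rank(
    rank_variable: Sequence[float],
    weights=None,
    tie_rank: Literal["unit", "average"] = "unit",
) -> np.ndarray:
    """Weighted fractional rank in (0, 1), poorest near 0, richest near 1.

    ``r_i = (cumulative weight of units ranked strictly below i + w_i / 2) / W``
    after a stable ascending sort of ``rank_variable`` (ties keep input
    order).  With ``tie_rank="average"`` tied values share the midpoint rank
    of their tie group instead of per-unit ranks.  Equal weights reduce to
    the textbook ``(i - 1/2) / N``.  The weighted mean of the ranks is 1/2
    by construction, which is what makes the rank-weighted identities exact.
    """
    v = np.asarray(rank_variable, dtype=float)
    w = _as_weights(weights, v.size)
    order = np.argsort(v, kind="stable")
    w_sorted = w[order]
    total = w_sorted.sum()
    cum = np.cumsum(w_sorted) - w_sorted / 2.0
    r = np.empty_like(cum)
    r[order] = cum / total
    if tie_rank == "average":
        # midpoint of the tie group's weight span, same for every member
        v_sorted = v[order]
        start = np.r_[True, v_sorted[1:] != v_sorted[:-1]]
        group = np.cumsum(start) - 1
        csum = np.r_[0.0, np.cumsum(w_sorted)]
        first = np.flatnonzero(start)
        last = np.r_[first[1:], v.size] - 1
        mid = (csum[first[group]] + csum[last[group] + 1]) / 2.0 / total
        r[order] = mid
    return r


def concentration_index(
    outcome: Sequence[float],
    rank_variable: Sequence[float],
    weights=None,
    tie_rank: Literal["unit", "average"] = "unit",
) -> float:
    """Concentration index ``C = 2 cov_w(outcome, r) / mean_w(outcome)``.

    ``r`` is the weighted fractional rank of ``rank_variable`` (the living
    standard).  For non-negative outcomes the index lies in [-1, 1]:
    positive when the outcome is concentrated among the better-off.
    The covariance is the weighted population covariance, which makes
    ``H * (1 - C_E)`` identical to the direct rank-weighted mean.
    """
    y = np.asarray(outcome, dtype=float)
    if y.size < 2:
        raise InputError("concentration index needs at least 2 observations")
    w = _as_weights(weights, y.size)
    mu = float(np.sum(w * y) / np.sum(w))
    if mu == 0.0:
        raise UndefinedIndexError("concentration index undefined for zero-mean outcome")
    r = fractional_rank(rank_variable, w, tie_rank=tie_rank)
    r_bar = float(np.sum(w * r) / np.sum(w))
    cov = float(np.sum(w * (y - mu) * (r - r_bar)) / np.sum(w))
    return 2.0 * cov / mu


def rank_weighted_measures(
    head_count: float, mean_overshoot: float, ci_incidence: float, ci_overshoot: float
) -> tuple[float, float]:
    """Distribution-sensitive head count and overshoot.

    ``H_w = H * (1 - C_E)`` and ``O_w = O * (1 - C_O)``: the poorest
    household is weighted 2, the richest 0.  A negative concentration index
    (burden concentrated among the poor) inflates the weighted measure
    above its unweighted counterpart.
    """
    return head_count * (1.0 - ci_incidence), mean_overshoot * (1.0 - ci_overshoot)


def catastrophic_table(
    dataset: SurveyDataset,
    thresholds: Sequence[Threshold] = DEFAULT_THRESHOLDS,
    weights_mode: Literal["none", "sampling"] = "none",
    rank_variable: Sequence[float] | None = None,
    tie_rank: Literal["unit", "average"] = "unit",
) -> list[CatastrophicResult]:
    """Compute all catastrophic-payment measures at each threshold.

    The ranking variable for the concentration indices defaults to the same
    living-standard measure as the share denominator (total expenditure for
    total-expenditure shares, capacity to pay for capacity shares) at the
    household level; pass ``rank_variable`` to override.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise InputError("at least one threshold is required")
    w = dataset.weight if weights_mode == "sampling" else None

    shares_cache: dict[str, np.ndarray] = {}
    results = []
    for th in thresholds:
        if th.denominator not in shares_cache:
            shares_cache[th.denominator] = oop_share(dataset, th.denominator)
        shares = shares_cache[th.denominator]
        if rank_variable is not None:
            rank_var = np.asarray(rank_variable, dtype=float)
        elif th.denominator == "total_expenditure":
            rank_var = dataset.total_expenditure
        else:
            rank_var = capacity_to_pay(dataset)

        e = (shares > th.z).astype(float)
        h = head_count(shares, th.z, w)
        o_i, o, mpo = overshoot(shares, th.z, w)
        if h > 0:
            c_e = concentration_index(e, rank_var, w, tie_rank)
            h_w = h * (1.0 - c_e)
        else:
            c_e, h_w = 0.0, 0.0
        if o > 0:
            c_o = concentration_index(o_i, rank_var, w, tie_rank)
            o_w = o * (1.0 - c_o)
        else:
            c_o, o_w = None, 0.0
        results.append(
            CatastrophicResult(
                threshold=th,
                head_count=h,
                mean_overshoot=o,
                mpo=mpo,
                ci_incidence=c_e,
                ci_overshoot=c_o,
                weighted_head_count=h_w,
                weighted_overshoot=o_w,
                exceed_indicator=e,
                household_overshoot=o_i,
            )
        )
    return results
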