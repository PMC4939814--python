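"""Poverty measures gross and net of out-of-pocket health payments.

Poverty is assessed at the person level on per-capita household expenditure
``y_i = x_i / s_i``.  The "gross" measures use expenditure as observed; the
"net" measures first subtract the household's OOP health payments, spread
evenly over its members (``y_i^net = (x_i - T_i) / s_i``).  The difference
between the two is the impoverishing effect of paying for health care:
households just above the poverty line whose health spending pushed their
remaining consumption below it.

Measures (all person-weighted, i.e. household terms weighted by size
``s_i`` times the sampling weight):

* head count ``HP`` — share of people below the poverty line ``PL``
  (strict ``<``; a person exactly at the line is not poor);
* poverty gap ``G`` — mean shortfall ``p_i (PL - y_i)`` over *all* people;
* normalized gap ``NG = G / PL`` (unit-free, comparable across lines);
* normalized mean positive gap ``NMPG = NG / HP`` — mean relative shortfall
  among the poor only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InputError
from .survey import SurveyDataset, per_capita_expenditure

__all__ = [
    "PovertyLine",
    "PovertyResult",
    "ImpoverishmentComparison",
    "POVERTY_LINE_PRESETS",
    "poverty_head_count",
    "poverty_gap",
    "poverty_measures",
    "impoverishment_effect",
    "impoverished_population",
]

Basis = Literal["gross", "net"]


@dataclass(frozen=True)
class PovertyLine:
    """A per-person, per-period poverty line in the survey's currency units."""

    value: float
    label: str = ""

    def __post_init__(self):
        if self.value <= 0:
            raise InputError(f"poverty line must be positive, got {self.value}")


#: Named poverty lines shipped with the package (MNT per person per month,
#: 2012 prices): the Mongolian national line and the World Bank $1.90/day
#: (2011 PPP) line converted to MNT.  Any numeric line is equally accepted.
POVERTY_LINE_PRESETS: dict[str, PovertyLine] = {
    "mongolia_national_2012": PovertyLine(118_668.0, "mongolia_national_2012"),
    "worldbank_190ppp_2012": PovertyLine(34_769.6, "worldbank_190ppp_2012"),
}


@dataclass
class PovertyResult:
    """Head count, gap and normalized gaps for one basis and one line."""

    head_count: float
    gap: float
    normalized_gap: float
    normalized_mean_positive_gap: float | None  # None when head_count == 0
    basis: Basis
    line: PovertyLine


@dataclass
class ImpoverishmentComparison:
    """Paired gross/net poverty results with absolute and relative changes.

    ``absolute_change[m] = net - gross`` and ``relative_change[m] =
    (net - gross) / gross`` for each measure ``m``; a relative change is
    ``None`` where the gross measure is zero.
    """

    gross: PovertyResult
    net: PovertyResult
    absolute_change: dict[str, float | None]
    relative_change: dict[str, float | None]

    MEASURES = ("head_count", "gap", "normalized_gap", "normalized_mean_positive_gap")


def _per_capita(dataset: SurveyDataset, basis: Basis, floor_net_at_zero: bool) -> np.ndarray:
    if basis not in ("gross", "net"):
        raise InputError(f"basis must be 'gross' or 'net', got {basis!r}")
    y = per_capita_expenditure(dataset, net_of_oop=(basis == "net"))
    if basis == "net" and floor_net_at_zero:
        y = np.clip(y, 0.0, None)
    return y


def _person_weights(dataset: SurveyDataset) -> np.ndarray:
    return dataset.size * dataset.weight


def poverty_head_count(
    dataset: SurveyDataset,
    line: PovertyLine,
    basis: Basis = "gross",
    floor_net_at_zero: bool = False,
) -> float:
    """Person-weighted share of the population below the poverty line."""
    y = _per_capita(dataset, basis, floor_net_at_zero)
    sw = _person_weights(dataset)
    poor = y < line.value
    return float(np.sum(sw * poor) / np.sum(sw))


def poverty_gap(
    dataset: SurveyDataset,
    line: PovertyLine,
    basis: Basis = "gross",
    floor_net_at_zero: bool = False,
) -> tuple[float, float, float | None]:
    """Mean per-person shortfall below the line, over the whole population.

    Returns ``(G, NG, NMPG)``: the gap in currency units, the gap as a
    fraction of the line, and the mean relative shortfall among the poor
    (``None`` when nobody is poor).
    """
    y = _per_capita(dataset, basis, floor_net_at_zero)
    sw = _person_weights(dataset)
    poor = y < line.value
    g_i = np.where(poor, line.value - y, 0.0)
    gap = float(np.sum(sw * g_i) / np.sum(sw))
    ng = gap / line.value
    hp = float(np.sum(sw * poor) / np.sum(sw))
    nmpg = ng / hp if hp > 0 else None
    return gap, ng, nmpg


def poverty_measures(
    dataset: SurveyDataset,
    line: PovertyLine,
    basis: Basis = "gross",
    floor_net_at_zero: bool = False,
) -> PovertyResult:
    """Bundle head count and gap measures for one basis into a PovertyResult."""
    hp = poverty_head_count(dataset, line, basis, floor_net_at_zero)
    gap, ng, nmpg = poverty_gap(dataset, line, basis, floor_net_at_zero)
    return PovertyResult(
        head_count=hp,
        gap=gap,
        normalized_gap=ng,
        normalized_mean_positive_gap=nmpg,
        basis=basis,
        line=line,
    )


def impoverishment_effect(
    dataset: SurveyDataset,
    line: PovertyLine,
    floor_net_at_zero: bool = False,
) -> ImpoverishmentComparison:
    """Gross vs net poverty and the change attributable to OOP payments."""
    gross = poverty_measures(dataset, line, "gross", floor_net_at_zero)
    net = poverty_measures(dataset, line, "net", floor_net_at_zero)
    absolute: dict[str, float | None] = {}
    relative: dict[str, float | None] = {}
    for m in ImpoverishmentComparison.MEASURES:
        gv, nv = getattr(gross, m), getattr(net, m)
        if gv is None or nv is None:
            absolute[m] = None
            relative[m] = None
            continue
        absolute[m] = nv - gv
        relative[m] = (nv - gv) / gv if gv != 0 else None
    return ImpoverishmentComparison(
        gross=gross, net=net, absolute_change=absolute, relative_change=relative
    )


def impoverished_population(absolute_head_count_change: float, population: float) -> int:
    """People pushed into poverty: head-count change times a population figure.

    The population total is supplied by the caller (it is external to the
    survey); the result is rounded to the nearest person.
    """
    if population <= 0:
        raise InputError(f"population must be positive, got {population}")
    return int(round(absolute_head_count_change * population))
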