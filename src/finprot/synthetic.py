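"""Seeded generator of synthetic household expenditure surveys.

Emulates the statistical structure a financial-protection analysis assumes
of a household budget survey: right-skewed (log-normal) per-capita
expenditure, an Engel-curve food share that declines with the log of
per-capita expenditure, and zero-inflated OOP health payments whose level
rises faster than proportionally with total expenditure (elasticity > 1),
so the catastrophic burden concentrates among the better-off and the
richest quintile spends roughly an order of magnitude more on health than
the poorest.  An urban stratum carries an OOP multiplier.

The default parameter set ships as the preset ``hses2012-like``: a
12,811-household survey in MNT per month whose headline measures land near
a head count of ~5.5 % at the 10 %-of-total-expenditure threshold and a
gross poverty head count of ~22 % at a 118,668-per-person line.  It is a
qualitative calibration of scale and shape, not a reproduction of any real
survey: within-household correlation, survey design effects, item-level
consumption structure and reporting error are all absent.

Randomness is a single ``numpy`` Generator stream seeded from ``seed``,
with a fixed draw order (household sizes, per-capita expenditure, OOP-zero
indicators, OOP noise, urban indicators — food shares are deterministic
given expenditure), so identical seed + config always yields an identical
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

from .catastrophic import head_count, oop_share
from .errors import CalibrationError, ConfigurationError
from .survey import SurveyDataset, build_dataset

__all__ = ["GeneratorConfig", "PRESETS", "generate_survey", "generate_calibrated"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic survey generator.

    Monetary scale is arbitrary but the defaults are tuned to MNT per month
    circa 2012.  ``oop_elasticity`` > 1 makes OOP a luxury (rises faster
    than expenditure); ``oop_zero_prob`` is the share of households with no
    health spending in the period.
    """

    n_households: int = 12_811
    seed: int = 2012
    log_pc_expenditure_mean: float = 12.10
    log_pc_expenditure_sd: float = 0.55
    household_size_mean: float = 3.6
    engel_base: float = 1.55
    engel_slope: float = 0.10
    oop_zero_prob: float = 0.35
    oop_elasticity: float = 1.6
    oop_scale: float = 5.8e-06
    oop_noise_sd: float = 1.0
    urban_prob: float = 0.63
    urban_oop_multiplier: float = 1.5

    def validate(self) -> None:
        if self.n_households < 1:
            raise ConfigurationError("n_households must be >= 1")
        for p in ("oop_zero_prob", "urban_prob"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{p} must be in [0, 1], got {v}")
        for p in ("log_pc_expenditure_sd", "oop_noise_sd"):
            if getattr(self, p) < 0:
                raise ConfigurationError(f"{p} must be >= 0")
        if self.household_size_mean < 1:
            raise ConfigurationError("household_size_mean must be >= 1")
        if self.oop_scale < 0 or self.urban_oop_multiplier < 0:
            raise ConfigurationError("oop_scale and urban_oop_multiplier must be >= 0")


PRESETS: dict[str, GeneratorConfig] = {"hses2012-like": GeneratorConfig()}


def generate_survey(config: GeneratorConfig) -> SurveyDataset:
    """Draw one synthetic survey; identical seed + config gives identical data.

    Per household: size is 1 + Poisson(mean - 1); per-capita expenditure is
    log-normal; total = per-capita x size; food = Engel share x total with
    share = clip(engel_base - engel_slope * log(per-capita), 0.05, 0.95);
    OOP is zero with probability ``oop_zero_prob``, otherwise
    ``oop_scale * total**oop_elasticity`` times log-normal noise and the
    urban multiplier, capped at non-food expenditure so every record passes
    strict validation (T <= nf(x) <= x).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_households

    size = 1 + rng.poisson(config.household_size_mean - 1.0, n)
    pc = rng.lognormal(config.log_pc_expenditure_mean, config.log_pc_expenditure_sd, n)
    zero = rng.random(n) < config.oop_zero_prob
    noise = rng.lognormal(0.0, config.oop_noise_sd, n)
    urban = (rng.random(n) < config.urban_prob).astype(int)

    total = pc * size
    food_share = np.clip(
        config.engel_base - config.engel_slope * np.log(pc), 0.05, 0.95
    )
    food = food_share * total
    level = config.oop_scale * total**config.oop_elasticity * noise
    level = np.where(urban == 1, level * config.urban_oop_multiplier, level)
    oop = np.where(zero, 0.0, np.minimum(level, total - food))

    frame = pd.DataFrame(
        {
            "total_expenditure": total,
            "food_expenditure": food,
            "oop_health": oop,
            "size": size,
            "weight": 1.0,
            "urban": urban,
            "used_outpatient": np.nan,
            "used_inpatient": np.nan,
        }
    )
    return build_dataset(
        frame, "strict", source_label=f"synthetic(seed={config.seed}, n={n})"
    )


def generate_calibrated(
    config: GeneratorConfig,
    target_head_count: float,
    z: float = 0.10,
    denominator: Literal["total_expenditure", "capacity_to_pay"] = "total_expenditure",
    tolerance: float = 0.005,
    max_iter: int = 60,
) -> tuple[SurveyDataset, float]:
    """Rescale ``oop_scale`` by bisection until the realized catastrophic
    head count at ``(z, denominator)`` matches ``target_head_count``.

    The random draws are held fixed (same seed), so the head count is a
    deterministic non-decreasing function of the scale and bisection
    converges to within one household's weight.  Returns the calibrated
    dataset and the achieved head count.
    """
    if not 0.0 <= target_head_count < 1.0:
        raise ConfigurationError("target head count must be in [0, 1)")
    if tolerance <= 0:
        raise ConfigurationError("tolerance must be positive")

    def realized(scale: float) -> tuple[SurveyDataset, float]:
        ds = generate_survey(replace(config, oop_scale=scale))
        return ds, head_count(oop_share(ds, denominator), z)

    if target_head_count == 0.0:
        return realized(0.0)
    ds, h = realized(config.oop_scale)
    if abs(h - target_head_count) <= tolerance:
        return ds, h

    trace: list[tuple[float, float]] = [(config.oop_scale, h)]
    lo, hi = 0.0, config.oop_scale
    h_hi = h
    expansions = 0
    while h_hi < target_head_count:
        lo, hi = hi, hi * 2.0
        ds, h_hi = realized(hi)
        trace.append((hi, h_hi))
        expansions += 1
        if expansions > 40:
            raise CalibrationError(
                f"could not bracket target {target_head_count}; trace={trace}"
            )

    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        ds, h = realized(mid)
        trace.append((mid, h))
        if abs(h - target_head_count) <= tolerance:
            return ds, h
        if h < target_head_count:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach target {target_head_count} +/- {tolerance} "
        f"in {max_iter} iterations; last trace entries {trace[-5:]}"
    )
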