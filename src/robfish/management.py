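"""TAC accounting and the harvest control rule governing the transition to MSY.

After a forced phase with fixed TACs, each population's annual quota is set
by an ICES-style rule: the target fishing mortality blends the realized F of
the last forced year with F_MSY, moving linearly over the transition period
(a 5-year transition shifts 20 percentage points of weight per year).  The
target is capped at the precautionary F_pa, reduced linearly below the
MSY B_trigger spawning-biomass level, converted to a TAC by a one-year
deterministic Baranov forecast, and finally bounded to a maximum relative
year-to-year change (reference 15%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .errors import ConfigError
from .popdyn import (KG_PER_TONNE, PopulationConfig, age_and_recruit,
                     baranov_annual_catch)


@dataclass
class HcrRule:
    """Per-population harvest-control-rule reference points."""

    fmsy: float                   # target F at MSY (1/yr)
    fpa: float                    # precautionary F cap (1/yr)
    msy_btrigger: float           # SSB trigger (t)
    fixed_tacs: tuple[float, ...] # forced-phase TACs (t), one per forced year
    min_landing_size: float       # cm

    def __post_init__(self):
        if self.fmsy < 0 or self.fpa < 0:
            raise ConfigError("Fmsy and Fpa must be non-negative")
        if self.fmsy > self.fpa:
            warnings.warn(f"Fmsy ({self.fmsy}) exceeds Fpa ({self.fpa}); "
                          "the precautionary cap will bind every year")
        if self.msy_btrigger < 0:
            raise ConfigError("MsyBtrigger must be non-negative")


@dataclass
class HcrConfig:
    """Management configuration: per-population rules plus shared settings."""

    rules: dict[str, HcrRule]
    transition_years: float = 5.0
    var_tac: float = 0.15           # max relative yearly TAC change
    btrigger_mode: str = "linear"   # "linear" advice rule | "hard_floor" (TAC = 0 below)

    def __post_init__(self):
        if self.transition_years < 1:
            raise ConfigError("transition_years must be >= 1")
        if self.var_tac < 0:
            raise ConfigError("var_tac must be non-negative")
        if self.btrigger_mode not in ("linear", "hard_floor"):
            raise ConfigError(f"unknown btrigger_mode {self.btrigger_mode!r}")


@dataclass
class TacState:
    """Per-population quota accounting within a year."""

    tac: float
    landings: float = 0.0

    @property
    def closed(self) -> bool:
        return self.landings >= self.tac


@dataclass
class TacDecision:
    """One year's TAC computation trail for the log."""

    target_f: float
    proposed: float
    bounded: float
    applied: float


def hcr_blend_weight(year_in_transition: int, transition_years: float) -> float:
    """Weight on Fmsy in transition year ``y`` (1-based): ``min(1, y / duration)``.

    For a 5-year transition the weight grows by exactly 0.20 per year; the
    complementary weight falls on the pre-transition F.
    """
    if transition_years < 1:
        raise ConfigError("transition_years must be >= 1")
    if year_in_transition < 1:
        raise ConfigError("year_in_transition must be >= 1")
    return min(1.0, year_in_transition / transition_years)


def hcr_target_f(
    year_in_transition: int,
    f2010: float,
    rule: HcrRule,
    ssb: float,
    transition_years: float = 5.0,
    btrigger_mode: str = "linear",
) -> float:
    """Annual target fishing mortality under the MSY-transition rule.

    ``F = min(Fpa, (1 - w) * F2010 + w * Fmsy)`` with blend weight ``w``;
    below the trigger biomass the target is scaled by ``SSB / MsyBtrigger``
    (linear advice rule) or set to zero (hard floor).  In the final
    transition year with SSB at or above the trigger the target equals Fmsy
    exactly (when Fmsy <= Fpa).
    """
    if f2010 < 0 or ssb < 0:
        raise ConfigError("f2010 and ssb must be non-negative")
    w = hcr_blend_weight(year_in_transition, transition_years)
    target = min(rule.fpa, (1.0 - w) * f2010 + w * rule.fmsy)
    if rule.msy_btrigger > 0 and ssb < rule.msy_btrigger:
        if btrigger_mode == "hard_floor":
            return 0.0
        target *= ssb / rule.msy_btrigger
    return target


def f_to_tac(
    f_target: float,
    population: PopulationConfig,
    abundance: np.ndarray,
    f_pattern: np.ndarray | None = None,
) -> float:
    """Deterministic one-year Baranov forecast of the catch (t) at ``f_target``.

    The scalar target is spread over ages by the realized F-at-age pattern
    (normalised to mean one over the fbar range); zero at ``f_target = 0`` and
    monotone non-decreasing in it.
    """
    if f_target < 0:
        raise ConfigError("f_target must be non-negative")
    if f_target == 0:
        return 0.0
    if f_pattern is None:
        f_pattern = np.ones(population.n_ages)
    f_at_age = f_target * np.asarray(f_pattern, dtype=float)
    catch_n = baranov_annual_catch(abundance, f_at_age, population.ndr)
    return float(np.sum(catch_n * population.weights())) / KG_PER_TONNE


def apply_tac_bound(previous_tac: float, proposed_tac: float, var_tac: float) -> float:
    """Clamp the proposal to within ``±var_tac`` of last year's TAC."""
    if previous_tac <= 0:
        raise ConfigError("previous_tac must be positive")
    lo = previous_tac * (1.0 - var_tac)
    hi = previous_tac * (1.0 + var_tac)
    return min(max(proposed_tac, lo), hi)


def landing_filter(length, min_landing_size: float):
    """Retention flag: kept iff at or above the minimum landing size."""
    return np.asarray(length, dtype=float) >= min_landing_size


def annual_management_update(
    year: int,
    population: PopulationConfig,
    abundance: np.ndarray,
    ssb: float,
    cfg: HcrConfig,
    forced_years: int,
    f2010: float | None,
    previous_tac: float | None,
    f_pattern: np.ndarray | None = None,
) -> TacDecision:
    """TAC for simulated ``year`` (1-based): fixed in the forced phase, HCR after.

    The HCR chain is target F -> one-year forecast -> year-to-year bound,
    anchored on the last forced-phase TAC.
    """
    rule = cfg.rules.get(population.name)
    if rule is None:
        raise ConfigError(f"no management rule for population {population.name!r}")
    if year <= forced_years:
        if year > len(rule.fixed_tacs):
            raise ConfigError(
                f"{population.name}: no fixed TAC for forced year {year}")
        tac = float(rule.fixed_tacs[year - 1])
        return TacDecision(target_f=float("nan"), proposed=tac, bounded=tac, applied=tac)

    if f2010 is None:
        raise ConfigError("HCR phase requires the realized F of the last forced year")
    if previous_tac is None:
        previous_tac = float(rule.fixed_tacs[-1])
    target = hcr_target_f(
        year - forced_years, f2010, rule, ssb,
        transition_years=cfg.transition_years, btrigger_mode=cfg.btrigger_mode)
    proposed = f_to_tac(target, population, abundance, f_pattern)
    bounded = apply_tac_bound(previous_tac, proposed, cfg.var_tac)
    return TacDecision(target_f=target, proposed=proposed, bounded=bounded, applied=bounded)
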