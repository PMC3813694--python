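"""Deterministic monthly-step age-structured population dynamics.

Several populations (e.g. sole and plaice in ICES division 7D) are exploited
by several fleets, each practising a yearly strategy of *métiers* (gear +
target species + season).  Dynamics follow standard exponential-survival /
Baranov catch accounting with monthly fractions of annual rates; each
population occupies a single homogeneous zone.  Fleet effort is shared
between métiers by a gravity model blending habits and last year's
value-per-unit-effort, and métiers close (with effort re-allocation and
bycatch discarding) when the quota of their target species is exhausted.

All rates (``F``, ``NDR``) are annual (1/yr); a month applies ``rate / 12``.
Weights are kilograms per fish, biomasses and catches are reported in tonnes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigError, SimulationError

MONTHS = range(1, 13)
KG_PER_TONNE = 1000.0


# ---------------------------------------------------------------------------
# growth and selectivity
# ---------------------------------------------------------------------------

def length_at_age(age, k: float, linf: float, t0: float):
    """Von Bertalanffy mean length (cm) at ``age`` (yr).

    ``L(a) = Linf * (1 - exp(-K * (a - T0)))``; strictly increasing in age and
    bounded above by ``Linf``.
    """
    if k <= 0 or linf <= 0:
        raise ConfigError(f"von Bertalanffy parameters must be positive (K={k}, Linf={linf})")
    age = np.asarray(age, dtype=float)
    return linf * (1.0 - np.exp(-k * (age - t0)))


@dataclass(frozen=True)
class Selectivity:
    """Length-based gear selectivity: logistic ``(L50, slope)`` or knife-edge at ``L50``."""

    kind: str = "logistic"  # "logistic" | "knife_edge"
    l50: float = 0.0
    slope: float = 1.0

    def __post_init__(self):
        if self.kind not in ("logistic", "knife_edge"):
            raise ConfigError(f"unknown selectivity kind {self.kind!r}")
        if self.kind == "logistic" and self.slope <= 0:
            raise ConfigError("logistic selectivity slope must be positive")

    def at_length(self, length):
        length = np.asarray(length, dtype=float)
        if self.kind == "knife_edge":
            return (length >= self.l50).astype(float)
        return 1.0 / (1.0 + np.exp(-self.slope * (length - self.l50)))


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class RecruitmentSchedule:
    """Per-year recruit numbers: forced values for the first years, then a constant."""

    forced: tuple[float, ...]
    after: float

    def value(self, year: int, multiplier: float = 1.0) -> float:
        """Recruits entering in simulated ``year`` (1-based).

        The forced years are treated as data and are not rescaled; the
        post-forcing constant is multiplied by ``multiplier`` (the RE axis).
        """
        if year < 1:
            raise ConfigError(f"year index must be >= 1, got {year}")
        if year <= len(self.forced):
            return float(self.forced[year - 1])
        return float(self.after) * multiplier


@dataclass
class PopulationConfig:
    """Life history, fishery and valuation parameters of one population."""

    name: str
    recruit_age: int
    plus_age: int
    k: float                      # von Bertalanffy growth rate (1/yr)
    linf: float                   # asymptotic length (cm)
    t0: float                     # age at zero length (yr)
    weight_at_age: np.ndarray     # kg per fish, one entry per age
    maturity_at_age: np.ndarray   # proportion mature per age, in [0, 1]
    ndr: float                    # natural death rate (1/yr)
    catchability: float           # dimensionless scaler of effort -> F
    recruitment: RecruitmentSchedule
    initial_abundance: np.ndarray
    discard_survival: float = 0.0
    price: float = 0.0            # currency per kg
    mean_weight_multiplier: float = 1.0   # MW axis
    recruitment_multiplier: float = 1.0   # RE axis (post-forcing years only)
    fbar_min_age: int = 2         # mean F averaged over ages >= this

    def __post_init__(self):
        self.weight_at_age = np.asarray(self.weight_at_age, dtype=float)
        self.maturity_at_age = np.asarray(self.maturity_at_age, dtype=float)
        self.initial_abundance = np.asarray(self.initial_abundance, dtype=float)
        self.validate()

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.recruit_age, self.plus_age + 1)

    @property
    def n_ages(self) -> int:
        return self.plus_age - self.recruit_age + 1

    def lengths(self) -> np.ndarray:
        return length_at_age(self.ages.astype(float), self.k, self.linf, self.t0)

    def weights(self) -> np.ndarray:
        return self.weight_at_age * self.mean_weight_multiplier

    def validate(self) -> None:
        if self.plus_age < self.recruit_age:
            raise ConfigError(f"{self.name}: plus_age < recruit_age")
        n = self.n_ages
        for label, arr in (("weight_at_age", self.weight_at_age),
                           ("maturity_at_age", self.maturity_at_age),
                           ("initial_abundance", self.initial_abundance)):
            if arr.shape != (n,):
                raise ConfigError(f"{self.name}: {label} must have {n} entries, got {arr.shape}")
            if np.any(arr < 0):
                raise ConfigError(f"{self.name}: {label} has negative entries")
        if np.any(self.maturity_at_age > 1):
            raise ConfigError(f"{self.name}: maturity_at_age exceeds 1")
        if not 0 <= self.discard_survival <= 1:
            raise ConfigError(f"{self.name}: discard_survival must lie in [0, 1]")
        if self.ndr < 0 or self.catchability < 0 or self.price < 0:
            raise ConfigError(f"{self.name}: rates, catchability and price must be non-negative")
        if self.k <= 0 or self.linf <= 0:
            raise ConfigError(f"{self.name}: K and Linf must be positive")


@dataclass
class MetierConfig:
    """A fishing activity: gear, selectivity, per-population targeting, season."""

    name: str
    gear: str
    selectivity: Selectivity
    target_factors: dict[str, float]   # population name -> dimensionless TF
    target_population: str
    months_active: frozenset[int] = frozenset(MONTHS)

    def __post_init__(self):
        self.months_active = frozenset(self.months_active)
        if any(tf < 0 for tf in self.target_factors.values()):
            raise ConfigError(f"{self.name}: target factors must be non-negative")
        if not self.months_active <= frozenset(MONTHS):
            raise ConfigError(f"{self.name}: months_active must be within 1..12")


@dataclass
class FleetConfig:
    """A group of similar vessels: total monthly effort, habitual strategy, inertia."""

    name: str
    monthly_effort: float
    strategy: dict[int, str]      # month -> habitual métier name
    habit: float = 1.0            # share of attractivity coming from habits

    def __post_init__(self):
        if not 0 <= self.habit <= 1:
            raise ConfigError(f"{self.name}: habit must lie in [0, 1]")
        if set(self.strategy) != set(MONTHS):
            raise ConfigError(f"{self.name}: strategy must cover all 12 months")
        if self.monthly_effort < 0:
            raise ConfigError(f"{self.name}: monthly_effort must be non-negative")

    def metier_names(self) -> list[str]:
        seen: list[str] = []
        for m in MONTHS:
            name = self.strategy[m]
            if name not in seen:
                seen.append(name)
        return seen

    def historical_shares(self) -> dict[str, float]:
        """Share of the year each métier occupies in the habitual strategy."""
        shares = {name: 0.0 for name in self.metier_names()}
        for m in MONTHS:
            shares[self.strategy[m]] += 1.0 / 12.0
        return shares


@dataclass
class PopulationState:
    """Abundance-at-age plus the simulation clock."""

    abundance: np.ndarray
    year: int = 1
    month: int = 1

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=float)
        if np.any(self.abundance < 0):
            raise SimulationError("negative abundance in state")


# ---------------------------------------------------------------------------
# elemental dynamics
# ---------------------------------------------------------------------------

def fishing_mortality_components(
    pop: PopulationConfig,
    metiers: Mapping[str, MetierConfig],
    efforts: Mapping[str, float],
) -> dict[str, np.ndarray]:
    """Per-métier fishing mortality at age (annual rates).

    ``F_m(a) = Q * TF_m * sel_gear(L(a)) * E_m`` — linear in each effort.
    """
    lengths = pop.lengths()
    out: dict[str, np.ndarray] = {}
    for name, effort in efforts.items():
        if effort < 0:
            raise ConfigError(f"negative effort for métier {name!r}")
        if name not in metiers:
            raise ConfigError(f"unknown métier {name!r}")
        met = metiers[name]
        tf = met.target_factors.get(pop.name, 0.0)
        out[name] = pop.catchability * tf * met.selectivity.at_length(lengths) * effort
    return out


def fishing_mortality_at_age(
    pop: PopulationConfig,
    metiers: Mapping[str, MetierConfig],
    efforts: Mapping[str, float],
) -> np.ndarray:
    """Total per-age fishing mortality (1/yr) across métiers."""
    comps = fishing_mortality_components(pop, metiers, efforts)
    if not comps:
        return np.zeros(pop.n_ages)
    return np.sum(list(comps.values()), axis=0)


def step_month(n: np.ndarray, f: np.ndarray, ndr: float):
    """Advance one month under annual rates ``f`` and ``ndr``.

    Returns ``(survivors, catch_numbers, natural_death_numbers)`` with exact
    number balance ``N = N' + C + D`` (Baranov over a 1/12-yr interval).
    """
    n = np.asarray(n, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or ndr < 0:
        raise ConfigError("mortality rates must be non-negative")
    z = f + ndr
    dt = 1.0 / 12.0
    decay = np.exp(-z * dt)
    removed = n * (1.0 - decay)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_f = np.where(z > 0, f / np.where(z > 0, z, 1.0), 0.0)
    catch = frac_f * removed
    deaths = removed - catch
    survivors = n * decay
    if np.any(~np.isfinite(survivors)) or np.any(survivors < 0):
        raise SimulationError("invalid abundance after monthly step")
    return survivors, catch, deaths


def age_and_recruit(
    n: np.ndarray,
    pop: PopulationConfig,
    year: int,
) -> np.ndarray:
    """January bookkeeping: shift ages by one, accumulate the plus group,
    and place the scheduled recruitment in the recruit-age slot."""
    n = np.asarray(n, dtype=float)
    shifted = np.zeros_like(n)
    shifted[1:] = n[:-1]
    shifted[-1] += n[-1]  # plus group accumulates
    shifted[0] = pop.recruitment.value(year, pop.recruitment_multiplier)
    return shifted


def spawning_biomass(n: np.ndarray, pop: PopulationConfig) -> float:
    """SSB (t) = sum over ages of N * maturity * weight * MW."""
    return float(np.sum(np.asarray(n) * pop.maturity_at_age * pop.weights())) / KG_PER_TONNE


def total_biomass(n: np.ndarray, pop: PopulationConfig) -> float:
    return float(np.sum(np.asarray(n) * pop.weights())) / KG_PER_TONNE


def allocate_effort(
    fleet: FleetConfig,
    revenue_by_metier: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Gravity-model attractivities for one fleet, summing to 1.

    ``attractivity_m = habit * historical_share_m + (1 - habit) * revenue_share_m``
    where revenue shares are last year's per-métier revenue normalised to sum
    one.  With no history (first year) or all-zero revenues, habit shares are
    used alone.
    """
    shares = fleet.historical_shares()
    if revenue_by_metier is None:
        return dict(shares)
    total_rev = sum(max(revenue_by_metier.get(m, 0.0), 0.0) for m in shares)
    if total_rev <= 0:
        return dict(shares)
    rev_share = {m: max(revenue_by_metier.get(m, 0.0), 0.0) / total_rev for m in shares}
    return {m: fleet.habit * shares[m] + (1.0 - fleet.habit) * rev_share[m] for m in shares}


def apply_discarding(
    catch_numbers: np.ndarray,
    retained_mask: np.ndarray,
    bycatch_closed: bool,
    discard_survival: float,
):
    """Partition catch-at-age numbers into landings, dead discards and returns.

    Undersized fish (``retained_mask`` False) are always discarded; when the
    population's quota is exhausted and it is a bycatch of the métier, the
    whole catch is discarded.  A fraction ``discard_survival`` of discarded
    fish survives and is returned to its year class.  Mass balance is exact:
    ``catch = landings + dead + returned``.
    """
    catch_numbers = np.asarray(catch_numbers, dtype=float)
    if bycatch_closed:
        landed = np.zeros_like(catch_numbers)
    else:
        landed = catch_numbers * retained_mask
    discarded = catch_numbers - landed
    returned = discarded * discard_survival
    dead = discarded - returned
    return landed, dead, returned


def baranov_annual_catch(
    n: np.ndarray,
    f_at_age: np.ndarray,
    ndr: float,
) -> np.ndarray:
    """One-year Baranov catch numbers at age from abundance ``n``."""
    z = np.asarray(f_at_age, dtype=float) + ndr
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(z > 0, f_at_age / np.where(z > 0, z, 1.0), 0.0)
    return frac * (1.0 - np.exp(-z)) * np.asarray(n, dtype=float)


def invert_baranov_f(catch: float, n0: float, ndr: float) -> float:
    """Solve the annual Baranov equation ``C = F/Z (1 - e^-Z) N0`` for F.

    Used to report a catch-consistent realized annual F per cohort.  Returns
    0 when no catch was taken; falls back to the upper bracket if the catch
    exceeds what any finite F could produce (possible when discarded
    survivors were returned to the cohort during the year).
    """
    if catch <= 0 or n0 <= 0:
        return 0.0
    if ndr == 0:
        # C = (1 - e^-F) N0 solves in closed form
        frac = catch / n0
        if frac >= 1.0 - 1e-15:
            return 50.0
        return float(-np.log1p(-frac))

    def g(f):
        z = f + ndr
        return f / z * (1.0 - np.exp(-z)) * n0 - catch

    hi = 50.0
    if g(hi) < 0:
        return hi
    return float(brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-12))


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

@dataclass
class AnnualOutputs:
    """Per-(year, population) results of a run."""

    year: int
    population: str
    biomass: float         # t, 1 January
    ssb: float             # t, 1 January
    f: float               # mean realized annual F over the fbar age range
    catch: float           # t, landings + discards
    landings: float        # t
    discards: float        # t (dead + returned survivors)


@dataclass
class SimulationResult:
    """Annual outputs, TAC decisions and diagnostics of one deterministic run."""

    annual: pd.DataFrame
    tac_log: pd.DataFrame
    f_at_age: dict[str, np.ndarray]        # final-year realized F at age per population
    balance_residual: float                # max relative monthly number-balance error
    final_states: dict[str, np.ndarray]

    def final_year(self) -> pd.DataFrame:
        last = self.annual["year"].max()
        return self.annual[self.annual["year"] == last]

    def output(self, population: str, variable: str) -> float:
        """Final-year value of ``variable`` in {B, SSB, F, Y} for ``population``."""
        column = {"B": "B_t", "SSB": "SSB_t", "F": "F", "Y": "Y_t",
                  "landings": "landings_t", "discards": "discards_t"}[variable]
        row = self.final_year().set_index("population")
        return float(row.loc[population, column])


def _monthly_efforts(
    fleets: Sequence[FleetConfig],
    metiers: Mapping[str, MetierConfig],
    attractivities: Mapping[str, Mapping[str, float]],
    month: int,
    closed_pops: set[str],
) -> dict[str, float]:
    """Effort per métier for one month, honouring seasons and closures.

    A métier whose target population's quota is exhausted stops; its effort
    moves to the highest-attractivity métier of the same fleet using the same
    gear whose target is still open, else it is lost (inactivity).
    """
    efforts = {name: 0.0 for name in metiers}
    for fleet in fleets:
        attract = attractivities[fleet.name]
        stopped: dict[str, float] = {}
        for mname, a in attract.items():
            met = metiers[mname]
            if month not in met.months_active:
                continue
            e = fleet.monthly_effort * a
            if met.target_population in closed_pops:
                stopped[mname] = e
            else:
                efforts[mname] += e
        for mname, e in stopped.items():
            gear = metiers[mname].gear
            candidates = [
                alt for alt, a in attract.items()
                if alt != mname
                and metiers[alt].gear == gear
                and month in metiers[alt].months_active
                and metiers[alt].target_population not in closed_pops
            ]
            if candidates:
                best = max(candidates, key=lambda alt: (attract[alt], alt))
                efforts[best] += e
            # else: inactivity — effort is lost for the month
    return efforts


def run_simulation(scenario, horizon_years: int | None = None) -> SimulationResult:
    """Run the deterministic multi-population, multi-fleet simulation.

    The first ``scenario.forced_years`` years use fixed TACs and forced
    recruitment; afterwards the harvest control rule sets annual TACs.
    Identical inputs give bit-identical outputs.
    """
    from . import management as mgmt

    horizon = int(horizon_years or scenario.horizon_years)
    if horizon < scenario.forced_years:
        raise ConfigError("horizon shorter than the forced phase")

    pops: dict[str, PopulationConfig] = {p.name: p for p in scenario.populations}
    metiers: dict[str, MetierConfig] = {m.name: m for m in scenario.metiers}
    fleets: list[FleetConfig] = list(scenario.fleets)
    cfg = scenario.management

    states = {name: p.initial_abundance.astype(float).copy() for name, p in pops.items()}
    prev_tac: dict[str, float] = {}
    f2010: dict[str, float] = {}
    fbar_pattern: dict[str, np.ndarray] = {name: np.ones(p.n_ages) for name, p in pops.items()}
    revenue_prev: dict[str, dict[str, float]] | None = None

    rows: list[AnnualOutputs] = []
    tac_rows: list[dict] = []
    max_residual = 0.0
    final_f_at_age: dict[str, np.ndarray] = {}

    for year in range(1, horizon + 1):
        # --- January: ageing + recruitment; B and SSB snapshots -------------
        jan_n: dict[str, np.ndarray] = {}
        ssb_now: dict[str, float] = {}
        b_now: dict[str, float] = {}
        for name, p in pops.items():
            states[name] = age_and_recruit(states[name], p, year)
            jan_n[name] = states[name].copy()
            ssb_now[name] = spawning_biomass(states[name], p)
            b_now[name] = total_biomass(states[name], p)

        # --- annual management update ---------------------------------------
        tacs: dict[str, float] = {}
        for name, p in pops.items():
            decision = mgmt.annual_management_update(
                year=year,
                population=p,
                abundance=states[name],
                ssb=ssb_now[name],
                cfg=cfg,
                forced_years=scenario.forced_years,
                f2010=f2010.get(name),
                previous_tac=prev_tac.get(name),
                f_pattern=fbar_pattern[name],
            )
            tacs[name] = decision.applied
            tac_rows.append({
                "year": year, "population": name,
                "proposed": decision.proposed, "bounded": decision.bounded,
                "applied": decision.applied, "target_f": decision.target_f,
            })
        prev_tac = dict(tacs)

        # --- yearly gravity-model effort allocation --------------------------
        attractivities = {
            fleet.name: allocate_effort(
                fleet, None if revenue_prev is None else revenue_prev.get(fleet.name))
            for fleet in fleets
        }

        # --- monthly loop -----------------------------------------------------
        landings_t = {name: 0.0 for name in pops}
        discards_t = {name: 0.0 for name in pops}
        dead_discards_t = {name: 0.0 for name in pops}
        catch_numbers_year = {name: np.zeros(p.n_ages) for name, p in pops.items()}
        f_monthly_sum = {name: np.zeros(p.n_ages) for name, p in pops.items()}
        revenue_now: dict[str, dict[str, float]] = {
            fleet.name: {m: 0.0 for m in attractivities[fleet.name]} for fleet in fleets
        }
        closed: set[str] = set()

        for month in MONTHS:
            efforts = _monthly_efforts(fleets, metiers, attractivities, month, closed)
            # per-fleet share of each métier's effort (for revenue attribution)
            fleet_shares: dict[str, dict[str, float]] = {}
            for fleet in fleets:
                attract = attractivities[fleet.name]
                for mname in attract:
                    if efforts.get(mname, 0.0) > 0 and month in metiers[mname].months_active:
                        contrib = fleet.monthly_effort * attract[mname]
                        if metiers[mname].target_population in closed:
                            contrib = 0.0
                        fleet_shares.setdefault(mname, {})[fleet.name] = contrib

            for name, p in pops.items():
                n_before = states[name].copy()
                comps = fishing_mortality_components(p, metiers, efforts)
                f_total = (np.sum(list(comps.values()), axis=0)
                           if comps else np.zeros(p.n_ages))
                survivors, catch, deaths = step_month(n_before, f_total, p.ndr)
                f_monthly_sum[name] += f_total / 12.0

                retained = p.lengths() >= cfg.rules[name].min_landing_size
                returned_total = np.zeros(p.n_ages)
                weights = p.weights()
                for mname, f_m in comps.items():
                    with np.errstate(invalid="ignore", divide="ignore"):
                        share = np.where(f_total > 0, f_m / np.where(f_total > 0, f_total, 1.0), 0.0)
                    catch_m = catch * share
                    if not np.any(catch_m):
                        continue
                    bycatch_closed = (name in closed
                                      and metiers[mname].target_population != name)
                    landed, dead, ret = apply_discarding(
                        catch_m, retained, bycatch_closed, p.discard_survival)
                    landed_w = float(np.sum(landed * weights)) / KG_PER_TONNE
                    landings_t[name] += landed_w
                    disc_w = float(np.sum((dead + ret) * weights)) / KG_PER_TONNE
                    discards_t[name] += disc_w
                    dead_discards_t[name] += float(np.sum(dead * weights)) / KG_PER_TONNE
                    returned_total += ret
                    # revenue attributed to fleets by effort contribution
                    shares = fleet_shares.get(mname, {})
                    tot = sum(shares.values())
                    if tot > 0:
                        for fname, contrib in shares.items():
                            revenue_now[fname][mname] += (
                                p.price * landed_w * KG_PER_TONNE * contrib / tot)

                new_n = survivors + returned_total
                # exact number balance: N = N' + deaths + catch - returned
                residual = np.abs(n_before - (new_n + deaths + catch - returned_total))
                scale = np.maximum(n_before, 1.0)
                max_residual = max(max_residual, float(np.max(residual / scale)))
                states[name] = new_n
                catch_numbers_year[name] += catch
                if np.any(~np.isfinite(new_n)):
                    raise SimulationError(f"non-finite abundance for {name} "
                                          f"(year {year}, month {month})")

            # quota accounting at month end
            for name in pops:
                if name not in closed and landings_t[name] >= tacs[name]:
                    closed.add(name)

        revenue_prev = revenue_now

        # --- realized annual F (catch-consistent Baranov inversion) ----------
        for name, p in pops.items():
            f_real = np.array([
                invert_baranov_f(catch_numbers_year[name][a], jan_n[name][a], p.ndr)
                for a in range(p.n_ages)
            ])
            # fall back to summed monthly rates where inversion is degenerate
            fallback = f_monthly_sum[name]
            f_real = np.where(np.isfinite(f_real), f_real, fallback)
            mask = p.ages >= p.fbar_min_age
            fbar = float(np.mean(f_real[mask])) if np.any(mask) else float(np.mean(f_real))
            if np.any(f_real > 0):
                ref = np.mean(f_real[mask]) if np.any(mask) and np.mean(f_real[mask]) > 0 \
                    else np.mean(f_real)
                fbar_pattern[name] = f_real / ref if ref > 0 else np.ones(p.n_ages)
            final_f_at_age[name] = f_real

            if year == scenario.forced_years:
                f2010[name] = fbar

            rows.append(AnnualOutputs(
                year=year, population=name,
                biomass=b_now[name], ssb=ssb_now[name], f=fbar,
                catch=landings_t[name] + discards_t[name],
                landings=landings_t[name], discards=discards_t[name],
            ))

    annual = pd.DataFrame(
        [{"year": r.year, "population": r.population, "B_t": r.biomass,
          "SSB_t": r.ssb, "F": r.f, "Y_t": r.catch,
          "landings_t": r.landings, "discards_t": r.discards} for r in rows]
    )
    return SimulationResult(
        annual=annual,
        tac_log=pd.DataFrame(tac_rows),
        f_at_age=final_f_at_age,
        balance_residual=max_residual,
        final_states=states,
    )
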