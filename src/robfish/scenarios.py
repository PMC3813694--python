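"""Scenario schema, YAML I/O, demonstration and toy fixtures.

A :class:`Scenario` bundles everything one campaign needs: populations,
métiers and fleets, the management configuration, the exploration axes and
the success rules (management goals).  The demonstration scenario is a
reduced Eastern English Channel flatfish fishery — sole and plaice in ICES
division 7D, exploited by netters (sole-focused) and beam trawlers (both
species) — carrying the published recruitments, fixed TACs, HCR reference
points and minimum landing sizes; life-history values that are not published
(weights, maturities, selectivities, efforts) are synthetic placeholders and
are flagged as such in the YAML file.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .exploration import ParameterAxis, ParameterSpace, SuccessRule, build_space, lhs_sample
from .management import HcrConfig, HcrRule
from .popdyn import (FleetConfig, MetierConfig, PopulationConfig,
                     RecruitmentSchedule, Selectivity, run_simulation)


@dataclass
class Scenario:
    """A full simulation + exploration configuration."""

    name: str
    populations: list[PopulationConfig]
    metiers: list[MetierConfig]
    fleets: list[FleetConfig]
    management: HcrConfig
    axes: list[ParameterAxis] = field(default_factory=list)
    success_rules: list[SuccessRule] = field(default_factory=list)
    horizon_years: int = 10
    forced_years: int = 3
    window: float = 0.5
    design_n: int = 5000
    seed: int = 0
    synthetic_fields: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        pop_names = {p.name for p in self.populations}
        met_names = {m.name for m in self.metiers}
        if len(pop_names) != len(self.populations):
            raise ConfigError("population names must be unique")
        if self.horizon_years < self.forced_years:
            raise ConfigError("horizon_years must cover the forced phase")
        for m in self.metiers:
            if m.target_population not in pop_names:
                raise ConfigError(
                    f"métier {m.name!r}: unknown target population {m.target_population!r}")
            unknown = set(m.target_factors) - pop_names
            if unknown:
                raise ConfigError(f"métier {m.name!r}: unknown populations {sorted(unknown)}")
        for f in self.fleets:
            missing = set(f.strategy.values()) - met_names
            if missing:
                raise ConfigError(f"fleet {f.name!r}: unknown métiers {sorted(missing)}")
        for p in self.populations:
            if p.name not in self.management.rules:
                raise ConfigError(
                    f"population {p.name!r}: missing management rule "
                    "(fmsy/fpa/msy_btrigger/fixed_tacs)")
            rule = self.management.rules[p.name]
            if len(rule.fixed_tacs) < self.forced_years:
                raise ConfigError(
                    f"population {p.name!r}: fixed_tacs must cover the "
                    f"{self.forced_years} forced years")
        for r in self.success_rules:
            if r.population not in pop_names:
                raise ConfigError(f"success rule: unknown population {r.population!r}")
        names = [a.name for a in self.axes]
        if len(set(names)) != len(names):
            raise ConfigError("axis names must be unique")

    def space(self) -> ParameterSpace:
        return build_space(self, self.window)


# ---------------------------------------------------------------------------
# applying explored parameters to a scenario
# ---------------------------------------------------------------------------

def apply_parameters(scenario: Scenario, values: Mapping[str, float]) -> Scenario:
    """Return a deep copy of ``scenario`` with axis values (natural units) applied.

    Axis targets:

    - ``("population", name, field)`` — any numeric PopulationConfig field
    - ``("all_populations", field)`` — e.g. the shared discard-survival rate
    - ``("metier", name, "l50")`` — selectivity L50 of that métier's gear
    - ``("metier", name, "target_factor", pop)`` — per-population TF
    - ``("fleet", name, "habit")``
    - ``("rule", pop, field)`` — fmsy, fpa, msy_btrigger, min_landing_size
    - ``("rule", pop, "fmsy_fpa")`` — joint axis: sets fmsy and scales fpa
      by the reference fpa/fmsy ratio (the two are varied together)
    - ``("management", field)`` — transition_years, var_tac
    """
    sc = copy.deepcopy(scenario)
    axes = {a.name: a for a in sc.axes}
    pops = {p.name: p for p in sc.populations}
    mets = {m.name: m for m in sc.metiers}
    fleets = {f.name: f for f in sc.fleets}
    for name, value in values.items():
        if name not in axes:
            raise ConfigError(f"unknown axis {name!r}")
        target = tuple(axes[name].target)
        kind = target[0]
        if kind == "population":
            _, pname, fld = target
            if pname not in pops:
                raise ConfigError(f"axis {name!r}: unknown population {pname!r}")
            setattr(pops[pname], fld, float(value))
        elif kind == "all_populations":
            _, fld = target
            for p in sc.populations:
                setattr(p, fld, float(value))
        elif kind == "metier":
            if target[2:3] == ("target_factor",):
                _, mname, _, pname = target
                mets[mname].target_factors[pname] = float(value)
            else:
                _, mname, fld = target
                if fld != "l50":
                    raise ConfigError(f"axis {name!r}: unsupported métier field {fld!r}")
                sel = mets[mname].selectivity
                mets[mname].selectivity = Selectivity(sel.kind, float(value), sel.slope)
        elif kind == "fleet":
            _, fname, fld = target
            setattr(fleets[fname], fld, float(value))
        elif kind == "rule":
            _, pname, fld = target
            rule = sc.management.rules[pname]
            if fld == "fmsy_fpa":
                ratio = rule.fpa / rule.fmsy if rule.fmsy > 0 else 1.0
                rule.fmsy = float(value)
                rule.fpa = float(value) * ratio
            else:
                setattr(rule, fld, float(value))
        elif kind == "management":
            _, fld = target
            setattr(sc.management, fld, float(value))
        else:
            raise ConfigError(f"axis {name!r}: unknown target kind {kind!r}")
    for p in sc.populations:
        p.validate()
    return sc


def make_evaluator(
    scenario: Scenario,
    horizon_years: int | None = None,
    from_year: int | None = None,
) -> Callable[[np.ndarray], dict[str, float]]:
    """Wrap the simulator as a campaign evaluator over normalized coordinates.

    Outputs the final-year B, SSB, F and Y per population (columns like
    ``SSB_Sole7D``).  With ``from_year`` set, additional ``SSBmin_*`` columns
    carry the minimum SSB from that simulated year on, for goals phrased as
    "every year from ... on".
    """
    space = scenario.space()

    def evaluate(theta: np.ndarray) -> dict[str, float]:
        natural = space.denormalize_row(theta)
        sc = apply_parameters(scenario, natural)
        result = run_simulation(sc, horizon_years)
        out: dict[str, float] = {}
        final = result.final_year().set_index("population")
        for p in sc.populations:
            row = final.loc[p.name]
            out[f"B_{p.name}"] = float(row["B_t"])
            out[f"SSB_{p.name}"] = float(row["SSB_t"])
            out[f"F_{p.name}"] = float(row["F"])
            out[f"Y_{p.name}"] = float(row["Y_t"])
            if from_year is not None:
                tail = result.annual.query("population == @p.name and year >= @from_year")
                out[f"SSBmin_{p.name}"] = float(tail["SSB_t"].min())
        return out

    return evaluate


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------

def _pop_to_dict(p: PopulationConfig) -> dict:
    return {
        "name": p.name, "recruit_age": p.recruit_age, "plus_age": p.plus_age,
        "k": p.k, "linf": p.linf, "t0": p.t0,
        "weight_at_age": [float(w) for w in p.weight_at_age],
        "maturity_at_age": [float(m) for m in p.maturity_at_age],
        "ndr": p.ndr, "catchability": p.catchability,
        "recruitment": {"forced": [float(v) for v in p.recruitment.forced],
                        "after": float(p.recruitment.after)},
        "initial_abundance": [float(v) for v in p.initial_abundance],
        "discard_survival": p.discard_survival, "price": p.price,
        "mean_weight_multiplier": p.mean_weight_multiplier,
        "recruitment_multiplier": p.recruitment_multiplier,
        "fbar_min_age": p.fbar_min_age,
    }


def scenario_to_dict(sc: Scenario) -> dict:
    return {
        "name": sc.name,
        "horizon_years": sc.horizon_years,
        "forced_years": sc.forced_years,
        "window": sc.window,
        "design_n": sc.design_n,
        "seed": sc.seed,
        "populations": [_pop_to_dict(p) for p in sc.populations],
        "metiers": [{
            "name": m.name, "gear": m.gear,
            "selectivity": {"kind": m.selectivity.kind, "l50": m.selectivity.l50,
                            "slope": m.selectivity.slope},
            "target_factors": dict(m.target_factors),
            "target_population": m.target_population,
            "months_active": sorted(m.months_active),
        } for m in sc.metiers],
        "fleets": [{
            "name": f.name, "monthly_effort": f.monthly_effort,
            "strategy": {int(k): v for k, v in f.strategy.items()},
            "habit": f.habit,
        } for f in sc.fleets],
        "management": {
            "transition_years": sc.management.transition_years,
            "var_tac": sc.management.var_tac,
            "btrigger_mode": sc.management.btrigger_mode,
            "rules": {
                name: {"fmsy": r.fmsy, "fpa": r.fpa, "msy_btrigger": r.msy_btrigger,
                       "fixed_tacs": [float(t) for t in r.fixed_tacs],
                       "min_landing_size": r.min_landing_size}
                for name, r in sc.management.rules.items()
            },
        },
        "axes": [{
            "name": a.name, "group": a.group, "reference": a.reference,
            "target": list(a.target), "lower": a.lower, "upper": a.upper,
            "synthetic": a.synthetic,
        } for a in sc.axes],
        "success_rules": [{
            "output": r.output, "population": r.population,
            "threshold": r.threshold, "direction": r.direction,
        } for r in sc.success_rules],
        "synthetic_fields": {k: list(v) for k, v in sc.synthetic_fields.items()},
    }


def scenario_from_dict(d: dict) -> Scenario:
    try:
        populations = [PopulationConfig(
            name=p["name"], recruit_age=p["recruit_age"], plus_age=p["plus_age"],
            k=p["k"], linf=p["linf"], t0=p["t0"],
            weight_at_age=np.array(p["weight_at_age"], dtype=float),
            maturity_at_age=np.array(p["maturity_at_age"], dtype=float),
            ndr=p["ndr"], catchability=p["catchability"],
            recruitment=RecruitmentSchedule(tuple(p["recruitment"]["forced"]),
                                            p["recruitment"]["after"]),
            initial_abundance=np.array(p["initial_abundance"], dtype=float),
            discard_survival=p.get("discard_survival", 0.0),
            price=p.get("price", 0.0),
            mean_weight_multiplier=p.get("mean_weight_multiplier", 1.0),
            recruitment_multiplier=p.get("recruitment_multiplier", 1.0),
            fbar_min_age=p.get("fbar_min_age", 2),
        ) for p in d["populations"]]
        metiers = [MetierConfig(
            name=m["name"], gear=m["gear"],
            selectivity=Selectivity(m["selectivity"]["kind"], m["selectivity"]["l50"],
                                    m["selectivity"].get("slope", 1.0)),
            target_factors=dict(m["target_factors"]),
            target_population=m["target_population"],
            months_active=frozenset(m.get("months_active", range(1, 13))),
        ) for m in d["metiers"]]
        fleets = [FleetConfig(
            name=f["name"], monthly_effort=f["monthly_effort"],
            strategy={int(k): v for k, v in f["strategy"].items()},
            habit=f.get("habit", 1.0),
        ) for f in d["fleets"]]
        mgmt = d["management"]
        management = HcrConfig(
            rules={name: HcrRule(
                fmsy=r["fmsy"], fpa=r["fpa"], msy_btrigger=r["msy_btrigger"],
                fixed_tacs=tuple(r["fixed_tacs"]),
                min_landing_size=r["min_landing_size"],
            ) for name, r in mgmt["rules"].items()},
            transition_years=mgmt.get("transition_years", 5.0),
            var_tac=mgmt.get("var_tac", 0.15),
            btrigger_mode=mgmt.get("btrigger_mode", "linear"),
        )
        axes = [ParameterAxis(
            name=a["name"], group=a["group"], reference=a["reference"],
            target=tuple(a["target"]), lower=a.get("lower"), upper=a.get("upper"),
            synthetic=a.get("synthetic", False),
        ) for a in d.get("axes", [])]
        rules = [SuccessRule(
            output=r["output"], population=r["population"],
            threshold=r["threshold"], direction=r.get("direction", ">="),
        ) for r in d.get("success_rules", [])]
    except KeyError as exc:
        raise ConfigError(f"scenario is missing required field {exc.args[0]!r}") from exc
    return Scenario(
        name=d.get("name", "scenario"),
        populations=populations, metiers=metiers, fleets=fleets,
        management=management, axes=axes, success_rules=rules,
        horizon_years=d.get("horizon_years", 10),
        forced_years=d.get("forced_years", 3),
        window=d.get("window", 0.5),
        design_n=d.get("design_n", 5000),
        seed=d.get("seed", 0),
        synthetic_fields={k: list(v) for k, v in d.get("synthetic_fields", {}).items()},
    )


def save_scenario(sc: Scenario, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(sc), fh, sort_keys=False)


def load_scenario(path: str) -> Scenario:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: not a scenario mapping")
    return scenario_from_dict(data)


def scenario_hash(sc: Scenario) -> str:
    """Hash of the canonicalized scenario, identifying a campaign."""
    canon = yaml.safe_dump(scenario_to_dict(sc), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# demonstration scenario (Eastern Channel 7D flatfish)
# ---------------------------------------------------------------------------

def make_demo_scenario() -> Scenario:
    """Reduced Eastern Channel demonstration: sole 7D and plaice 7D.

    Published values: recruitment forcing, fixed 2008-2010 TACs, HCR
    reference points (Fmsy, Fpa, MSY Btrigger, 15% TAC bound, 5-yr
    transition, discard-survival window), minimum landing sizes (24 cm sole,
    27 cm plaice) and the 8000 t spawning-biomass goals.  Life-history
    vectors, selectivities, efforts and catchabilities are synthetic
    placeholders chosen to give both stocks plausible dynamics (sole close
    to its goal, plaice overexploited); they are flagged in
    ``synthetic_fields``.
    """
    sole = PopulationConfig(
        name="Sole7D", recruit_age=1, plus_age=8,
        k=0.3, linf=39.0, t0=-0.4,
        weight_at_age=np.array([0.03, 0.08, 0.15, 0.22, 0.29, 0.35, 0.40, 0.45]),
        maturity_at_age=np.array([0.0, 0.25, 0.75, 1.0, 1.0, 1.0, 1.0, 1.0]),
        ndr=0.1, catchability=2.6e-4,
        recruitment=RecruitmentSchedule((2.395e7, 5.298e7, 2.817e7), 2.353e7),
        initial_abundance=2.4e7 * np.exp(-0.45 * np.arange(8)),
        discard_survival=0.0, price=10.0,
    )
    plaice = PopulationConfig(
        name="Plaice7D", recruit_age=1, plus_age=8,
        k=0.23, linf=50.0, t0=-0.6,
        weight_at_age=np.array([0.05, 0.12, 0.22, 0.33, 0.45, 0.55, 0.65, 0.75]),
        maturity_at_age=np.array([0.0, 0.2, 0.6, 1.0, 1.0, 1.0, 1.0, 1.0]),
        ndr=0.1, catchability=6.9e-4,
        recruitment=RecruitmentSchedule((1.157e7, 2.343e7, 1.498e7), 1.216e7),
        initial_abundance=1.2e7 * np.exp(-0.55 * np.arange(8)),
        discard_survival=0.0, price=2.5,
    )
    metiers = [
        MetierConfig(
            name="netting", gear="net",
            selectivity=Selectivity("logistic", l50=26.0, slope=0.5),
            target_factors={"Sole7D": 1.0, "Plaice7D": 0.1},
            target_population="Sole7D",
        ),
        MetierConfig(
            name="beam_trawl", gear="beam",
            selectivity=Selectivity("logistic", l50=22.0, slope=0.4),
            target_factors={"Sole7D": 0.9, "Plaice7D": 0.9},
            target_population="Sole7D",
        ),
        MetierConfig(
            name="other_metiers", gear="other",
            selectivity=Selectivity("logistic", l50=24.0, slope=0.4),
            target_factors={"Sole7D": 0.3, "Plaice7D": 0.5},
            target_population="Plaice7D",
        ),
    ]
    fleets = [
        FleetConfig(name="netters", monthly_effort=1000.0,
                    strategy={m: "netting" for m in range(1, 13)}, habit=0.6),
        FleetConfig(name="beam_trawlers", monthly_effort=1000.0,
                    strategy={**{m: "beam_trawl" for m in range(1, 9)},
                              **{m: "other_metiers" for m in range(9, 13)}},
                    habit=0.6),
    ]
    management = HcrConfig(
        rules={
            "Sole7D": HcrRule(fmsy=0.29, fpa=0.4, msy_btrigger=8000.0,
                              fixed_tacs=(6593.0, 5274.0, 4219.0),
                              min_landing_size=24.0),
            "Plaice7D": HcrRule(fmsy=0.23, fpa=0.45, msy_btrigger=8000.0,
                                fixed_tacs=(3500.0, 3500.0, 3400.0),
                                min_landing_size=27.0),
        },
        transition_years=5.0,
        var_tac=0.15,
    )

    axes: list[ParameterAxis] = []
    for p, tag in ((sole, "S7D"), (plaice, "P7D")):
        axes += [
            ParameterAxis(f"Q{tag}", "biological", p.catchability,
                          ("population", p.name, "catchability"), synthetic=True),
            ParameterAxis(f"MW{tag}", "biological", 1.0,
                          ("population", p.name, "mean_weight_multiplier")),
            ParameterAxis(f"RE{tag}", "biological", 1.0,
                          ("population", p.name, "recruitment_multiplier")),
            ParameterAxis(f"NDR{tag}", "biological", p.ndr,
                          ("population", p.name, "ndr"), synthetic=True),
            ParameterAxis(f"K{tag}", "biological", p.k,
                          ("population", p.name, "k"), synthetic=True),
            ParameterAxis(f"Linf{tag}", "biological", p.linf,
                          ("population", p.name, "linf"), synthetic=True),
            ParameterAxis(f"T0{tag}", "biological", p.t0,
                          ("population", p.name, "t0"), synthetic=True),
            ParameterAxis(f"P{tag}", "biological", p.price,
                          ("population", p.name, "price"), synthetic=True),
        ]
    axes += [
        ParameterAxis("SBT7D", "technical", 22.0, ("metier", "beam_trawl", "l50"),
                      synthetic=True),
        ParameterAxis("SN7D", "technical", 26.0, ("metier", "netting", "l50"),
                      synthetic=True),
        ParameterAxis("SO7D", "technical", 24.0, ("metier", "other_metiers", "l50"),
                      synthetic=True),
        ParameterAxis("TFB7DS", "technical", 0.9,
                      ("metier", "beam_trawl", "target_factor", "Sole7D"), synthetic=True),
        ParameterAxis("TFB7DP", "technical", 0.9,
                      ("metier", "beam_trawl", "target_factor", "Plaice7D"), synthetic=True),
        ParameterAxis("TFN7DS", "technical", 1.0,
                      ("metier", "netting", "target_factor", "Sole7D"), synthetic=True),
        ParameterAxis("TFO7DS", "technical", 0.3,
                      ("metier", "other_metiers", "target_factor", "Sole7D"), synthetic=True),
        ParameterAxis("TFO7DP", "technical", 0.5,
                      ("metier", "other_metiers", "target_factor", "Plaice7D"), synthetic=True),
        ParameterAxis("habitN", "technical", 0.6, ("fleet", "netters", "habit"),
                      synthetic=True),
        ParameterAxis("habitB", "technical", 0.6, ("fleet", "beam_trawlers", "habit"),
                      synthetic=True),
        # management axes (published reference values)
        ParameterAxis("MinSizeS7DE", "management", 24.0,
                      ("rule", "Sole7D", "min_landing_size")),
        ParameterAxis("MinSizeP7DE", "management", 27.0,
                      ("rule", "Plaice7D", "min_landing_size")),
        ParameterAxis("Trans", "management", 5.0, ("management", "transition_years")),
        ParameterAxis("PropSurv", "management", 0.25,
                      ("all_populations", "discard_survival"), lower=0.0, upper=0.5),
        ParameterAxis("varTAC", "management", 0.15, ("management", "var_tac")),
        ParameterAxis("FmsyFpaS7D", "management", 0.29, ("rule", "Sole7D", "fmsy_fpa")),
        ParameterAxis("FmsyFpaP7D", "management", 0.23, ("rule", "Plaice7D", "fmsy_fpa")),
        ParameterAxis("MsyBtS7D", "management", 8000.0,
                      ("rule", "Sole7D", "msy_btrigger")),
        ParameterAxis("MsyBtP7D", "management", 8000.0,
                      ("rule", "Plaice7D", "msy_btrigger")),
    ]
    rules = [
        SuccessRule(output="SSB", population="Sole7D", threshold=8000.0),
        SuccessRule(output="SSB", population="Plaice7D", threshold=8000.0),
    ]
    synthetic = {
        "Sole7D": ["weight_at_age", "maturity_at_age", "initial_abundance",
                   "k", "linf", "t0", "ndr", "catchability", "price"],
        "Plaice7D": ["weight_at_age", "maturity_at_age", "initial_abundance",
                     "k", "linf", "t0", "ndr", "catchability", "price"],
        "fleets": ["monthly_effort", "strategy", "habit"],
        "metiers": ["selectivity", "target_factors"],
    }
    return Scenario(
        name="eastern-channel-7d-demo",
        populations=[sole, plaice], metiers=metiers, fleets=fleets,
        management=management, axes=axes, success_rules=rules,
        horizon_years=10, forced_years=3, window=0.5,
        synthetic_fields=synthetic,
    )


# ---------------------------------------------------------------------------
# toy scenarios with analytically known behaviour
# ---------------------------------------------------------------------------

@dataclass
class ToyScenario:
    """An analytic stand-in for the simulator, for oracle tests of the
    exploration/tree stages: labels are a known function of the normalized
    coordinates."""

    kind: str
    space: ParameterSpace
    noise: float = 0.0   # probability a record's label is replaced by a coin flip

    def labels(self, design: np.ndarray, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        theta = np.atleast_2d(design)
        if self.kind == "box-recovery":
            q1 = theta[:, self.space.names.index("q1")]
            u1 = theta[:, self.space.names.index("u1")]
            y = (q1 < 0.4) & (u1 > 0.3)
        elif self.kind == "null-calibration":
            y = rng.random(len(theta)) < 0.5
        else:
            raise ConfigError(f"toy scenario {self.kind!r} has no analytic labels")
        if self.noise > 0:
            replace = rng.random(len(theta)) < self.noise
            coin = rng.random(len(theta)) < 0.5
            y = np.where(replace, coin, y)
        return y.astype(bool)

    def records(self, n: int, seed: int) -> pd.DataFrame:
        """LHS design plus success labels, in campaign-record layout."""
        design = lhs_sample(self.space, n, seed)
        df = pd.DataFrame(design, columns=self.space.names)
        df.insert(0, "run_id", np.arange(n))
        df["success"] = self.labels(design, seed + 1)
        return df


def make_toy_scenario(kind: str, noise: float = 0.01):
    """Fixtures with analytically known behaviour.

    - ``"single-cohort-analytic"``: a real one-population scenario (single
      exploited cohort, zero natural mortality, full selectivity and
      retention) whose annual catch has the closed Baranov form
      ``(1 - e^-F) * B0``.
    - ``"box-recovery"``: analytic labels, success iff ``q1 < 0.4`` and
      ``u1 > 0.3``, with 1% of labels replaced by coin flips.
    - ``"null-calibration"``: labels independent of every axis.
    """
    if kind == "single-cohort-analytic":
        pop = PopulationConfig(
            name="cohort", recruit_age=1, plus_age=2,
            k=1.0, linf=50.0, t0=0.0,
            weight_at_age=np.array([1.0, 1.0]),
            maturity_at_age=np.array([1.0, 1.0]),
            ndr=0.0, catchability=1.0,
            recruitment=RecruitmentSchedule((0.0,), 0.0),
            initial_abundance=np.array([0.0, 1.0e6]),
            price=1.0,
        )
        metier = MetierConfig(
            name="trawl", gear="trawl",
            selectivity=Selectivity("knife_edge", l50=0.0),
            target_factors={"cohort": 1.0},
            target_population="cohort",
        )
        fleet = FleetConfig(name="boat", monthly_effort=0.2,
                            strategy={m: "trawl" for m in range(1, 13)})
        management = HcrConfig(
            rules={"cohort": HcrRule(fmsy=0.2, fpa=0.4, msy_btrigger=0.0,
                                     fixed_tacs=(1e12,), min_landing_size=0.0)},
        )
        return Scenario(
            name="single-cohort-analytic",
            populations=[pop], metiers=[metier], fleets=[fleet],
            management=management, horizon_years=1, forced_years=1,
        )
    if kind in ("box-recovery", "null-calibration"):
        def axis(name, group):
            return ParameterAxis(name, group, 0.5, ("analytic", name),
                                 lower=0.0, upper=1.0, synthetic=True)
        space = ParameterSpace([
            axis("q1", "management"), axis("q2", "management"),
            axis("u1", "biological"), axis("u2", "biological"),
        ])
        return ToyScenario(kind=kind, space=space,
                           noise=noise if kind == "box-recovery" else 0.0)
    raise ConfigError(f"unknown toy scenario kind {kind!r}")
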