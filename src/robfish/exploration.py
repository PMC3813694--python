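"""Normalized uncertainty space, Latin-Hypercube designs and campaign running.

Every explored parameter is an axis with a reference value and an exploration
window (by default ±50% of the reference); an affine transform maps the
window onto [0, 1] so that the reference parameterisation sits at 0.5 on
every axis.  Management axes form the decision set Q, biological and
technical axes the states-of-Nature set U.  A campaign evaluates the
deterministic model once per design row and labels each run as a success or
failure against the management goals (the critical reward value rc).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import ConfigError

logger = logging.getLogger(__name__)

RUN_ID = "run_id"


@dataclass
class ParameterAxis:
    """One explored parameter: reference, window and normalization.

    ``target`` addresses the scenario slot the axis writes to, e.g.
    ``("population", "Sole7D", "catchability")`` — see
    :func:`robfish.scenarios.apply_parameters`.
    """

    name: str
    group: str                       # "biological" | "technical" | "management"
    reference: float
    target: tuple[str, ...]
    lower: float | None = None       # natural units; None -> relative window
    upper: float | None = None
    synthetic: bool = False          # reference not taken from published values

    GROUPS = ("biological", "technical", "management")

    def __post_init__(self):
        if self.group not in self.GROUPS:
            raise ConfigError(f"axis {self.name!r}: unknown group {self.group!r}")

    @property
    def has_bounds(self) -> bool:
        return self.lower is not None and self.upper is not None

    def with_window(self, window: float) -> "ParameterAxis":
        """Resolve missing bounds to ``reference * (1 ± window)``."""
        if self.has_bounds:
            axis = self
        else:
            if self.reference == 0:
                raise ConfigError(
                    f"axis {self.name!r}: reference 0 needs an explicit range")
            lo, hi = sorted((self.reference * (1 - window),
                             self.reference * (1 + window)))
            axis = ParameterAxis(self.name, self.group, self.reference,
                                 self.target, lo, hi, self.synthetic)
        if not axis.lower < axis.upper:
            raise ConfigError(f"axis {axis.name!r}: lower must be below upper")
        if not axis.lower <= axis.reference <= axis.upper:
            raise ConfigError(f"axis {axis.name!r}: reference outside bounds")
        return axis

    def normalize(self, value):
        self._require_bounds()
        return (np.asarray(value, dtype=float) - self.lower) / (self.upper - self.lower)

    def denormalize(self, u):
        self._require_bounds()
        return self.lower + np.asarray(u, dtype=float) * (self.upper - self.lower)

    def _require_bounds(self):
        if not self.has_bounds:
            raise ConfigError(f"axis {self.name!r}: bounds unresolved "
                              "(call build_space / with_window first)")


@dataclass
class ParameterSpace:
    """Ordered axes partitioned into management (Q) and natural (U) subsets."""

    axes: list[ParameterAxis]

    def __post_init__(self):
        names = [a.name for a in self.axes]
        if len(set(names)) != len(names):
            raise ConfigError("axis names must be unique")

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.axes]

    @property
    def dim(self) -> int:
        return len(self.axes)

    def axis(self, name: str) -> ParameterAxis:
        for a in self.axes:
            if a.name == name:
                return a
        raise ConfigError(f"unknown axis {name!r}")

    @property
    def management_names(self) -> list[str]:
        return [a.name for a in self.axes if a.group == "management"]

    @property
    def natural_names(self) -> list[str]:
        return [a.name for a in self.axes if a.group != "management"]

    def denormalize_row(self, theta: Sequence[float]) -> dict[str, float]:
        return {a.name: float(a.denormalize(t)) for a, t in zip(self.axes, theta)}


def build_space(scenario, window: float = 0.5) -> ParameterSpace:
    """Resolve the scenario's axes into a normalized exploration space.

    Axes without explicit bounds get ``[ref*(1-window), ref*(1+window)]``
    (the ±50% default); explicitly ranged axes (e.g. discard survival on
    [0, 0.5]) keep their range.  ``normalize(reference) = 0.5`` for symmetric
    windows.
    """
    return ParameterSpace([axis.with_window(window) for axis in scenario.axes])


def lhs_sample(space: ParameterSpace, n: int, seed: int) -> np.ndarray:
    """Latin-Hypercube design (n x d) on the unit cube.

    Exactly one point per axis falls in each of the n equal-width strata,
    uniformly placed within its stratum; reproducible for a given seed.
    """
    if n < 1:
        raise ConfigError("design size must be >= 1")
    sampler = qmc.LatinHypercube(d=space.dim, seed=seed)
    return sampler.random(n=n)


@dataclass(frozen=True)
class SuccessRule:
    """Management goal: output variable vs critical value rc.

    ``direction=">="`` flags a run as success when the output is equal to or
    above the threshold (non-strict, matching "equal to or above").
    """

    output: str                 # e.g. "SSB"
    population: str
    threshold: float            # the critical value rc
    direction: str = ">="

    def __post_init__(self):
        if self.direction not in (">=", "<="):
            raise ConfigError(f"unknown direction {self.direction!r}")
        if not np.isfinite(self.threshold):
            raise ConfigError("threshold must be finite")

    @property
    def column(self) -> str:
        return f"{self.output}_{self.population}"

    def evaluate(self, values):
        values = np.asarray(values, dtype=float)
        if self.direction == ">=":
            return values >= self.threshold
        return values <= self.threshold


def run_campaign(
    design: np.ndarray,
    evaluate: Callable[[np.ndarray], Mapping[str, float]],
    space: ParameterSpace,
    out_csv: str | None = None,
    resume: bool = False,
    flush_every: int = 200,
) -> pd.DataFrame:
    """Evaluate the model once per design row.

    Returns one record per row: ``run_id``, the normalized coordinates (one
    column per axis) and the evaluator's output columns, plus a ``failed``
    flag for rows whose evaluation raised (logged, campaign continues).
    Runs are independent; with ``out_csv`` partial results are flushed after
    every row and ``resume=True`` skips already-completed run ids.
    """
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.size == 0:
        design = design.reshape(0, space.dim)
    if design.shape[1] != space.dim:
        raise ConfigError(f"design has {design.shape[1]} columns, space has {space.dim}")

    done: dict[int, dict] = {}
    if resume and out_csv is not None:
        try:
            prior = pd.read_csv(out_csv)
            done = {int(r[RUN_ID]): r.to_dict() for _, r in prior.iterrows()}
            logger.info("resuming campaign: %d rows already complete", len(done))
        except FileNotFoundError:
            pass

    rows: list[dict] = []
    for i, theta in enumerate(design):
        if i in done:
            rows.append(done[i])
            continue
        row: dict = {RUN_ID: i}
        row.update({name: float(t) for name, t in zip(space.names, theta)})
        try:
            outputs = evaluate(theta)
            row.update({k: float(v) for k, v in outputs.items()})
            row["failed"] = False
        except Exception:
            logger.exception("run %d failed; recording as failed row", i)
            row["failed"] = True
        rows.append(row)
        if out_csv is not None and len(rows) % flush_every == 0:
            pd.DataFrame(rows).to_csv(out_csv, index=False)

    columns = [RUN_ID, *space.names]
    records = pd.DataFrame(rows, columns=None)
    if records.empty:
        records = pd.DataFrame(columns=[*columns, "failed"])
    if out_csv is not None:
        records.to_csv(out_csv, index=False)
    return records


def label_success(records: pd.DataFrame, rules: SuccessRule | Sequence[SuccessRule]) -> pd.DataFrame:
    """Attach per-rule success flags and their conjunction (``success``)."""
    if isinstance(rules, SuccessRule):
        rules = [rules]
    records = records.copy()
    overall = np.ones(len(records), dtype=bool)
    for rule in rules:
        if rule.column not in records.columns:
            raise ConfigError(f"records lack output column {rule.column!r}")
        flag = rule.evaluate(records[rule.column].to_numpy())
        records[f"ok_{rule.column}"] = flag
        overall &= flag
    if "failed" in records.columns:
        overall &= ~records["failed"].astype(bool).to_numpy()
    records["success"] = overall
    return records
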