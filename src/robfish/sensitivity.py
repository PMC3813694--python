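"""Variance-decomposition sensitivity ranking of exploration axes.

The primary estimator is the binned correlation ratio: with the input
partitioned into equal-count bins, ``S_i = Var(E[Y | X_i]) / Var(Y)`` is
estimated by the between-bin variance of the bin means.  It runs directly on
the Latin-Hypercube campaign, so one exploration feeds both the ranking and
the tree stage.  First-order interaction indices use the analogous 2-D
binning.  A pick-freeze Sobol estimator (which needs its own paired design)
is provided as an independent cross-check backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateOutputError

logger = logging.getLogger(__name__)


def _check_output(y: np.ndarray) -> float:
    var = float(np.var(y))
    if var <= 0 or not np.isfinite(var):
        raise DegenerateOutputError("degenerate output: Var(Y) must be positive and finite")
    return var


def default_bins(n: int) -> int:
    """Default equal-count bin number: max(10, n // 100)."""
    return max(10, n // 100)


def _equal_count_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Bin labels 0..bins-1 with (near-)equal counts, by rank."""
    order = np.argsort(x, kind="stable")
    labels = np.empty(len(x), dtype=np.int64)
    labels[order] = (np.arange(len(x)) * bins) // len(x)
    return labels


def first_order_index(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """First-order index ``S_i = Var(E[Y|X_i]) / Var(Y)`` by binned correlation ratio.

    ``S_i = sum_b (n_b/n) (mean_b(Y) - mean(Y))^2 / Var(Y)``, clipped to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 50:
        raise ConfigError("need at least 50 records for a sensitivity index")
    var_y = _check_output(y)
    if bins is None:
        bins = default_bins(n)
    labels = _equal_count_bins(x, bins)
    counts = np.bincount(labels, minlength=bins)
    sums = np.bincount(labels, weights=y, minlength=bins)
    keep = counts > 0
    means = sums[keep] / counts[keep]
    between = np.sum(counts[keep] / n * (means - y.mean()) ** 2)
    return float(np.clip(between / var_y, 0.0, 1.0))


def interaction_index(
    x_i: np.ndarray,
    x_j: np.ndarray,
    y: np.ndarray,
    bins: int | None = None,
) -> float:
    """Pairwise interaction ``S_ij = Var(E[Y|X_i,X_j])/Var(Y) - S_i - S_j``.

    Estimated on a 2-D equal-count grid; near zero for additive models.  The
    marginal indices are computed on the grid's marginals so the three terms
    share the same partition.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 50:
        raise ConfigError("need at least 50 records for a sensitivity index")
    var_y = _check_output(y)
    if bins is None:
        bins = max(5, int(np.sqrt(n / 20)))
    li = _equal_count_bins(x_i, bins)
    lj = _equal_count_bins(x_j, bins)
    joint = li * bins + lj

    def closed(labels, size):
        counts = np.bincount(labels, minlength=size)
        sums = np.bincount(labels, weights=y, minlength=size)
        keep = counts > 0
        means = sums[keep] / counts[keep]
        return float(np.sum(counts[keep] / n * (means - y.mean()) ** 2) / var_y)

    s_joint = closed(joint, bins * bins)
    s_i = closed(li, bins)
    s_j = closed(lj, bins)
    return float(s_joint - s_i - s_j)


def compute_indices(
    records: pd.DataFrame,
    axes: Sequence[str],
    outputs: Sequence[str],
    bins: int | None = None,
) -> pd.DataFrame:
    """First-order index table: one row per (axis, output), with per-output rank."""
    rows = []
    for output in outputs:
        if output not in records.columns:
            raise ConfigError(f"records lack output column {output!r}")
        y = records[output].to_numpy(dtype=float)
        for axis in axes:
            if axis not in records.columns:
                raise ConfigError(f"records lack axis column {axis!r}")
            s = first_order_index(records[axis].to_numpy(dtype=float), y, bins)
            rows.append({"axis": axis, "output": output, "S_i": s})
    table = pd.DataFrame(rows)
    table["rank"] = table.groupby("output")["S_i"].rank(ascending=False, method="first").astype(int)
    return table


@dataclass
class Selection:
    """Axes retained for the subtree stage plus the variance they explain."""

    output: str
    selected: list[str]
    indices: dict[str, float]
    explained: float
    policy: str


def rank_and_select(
    table: pd.DataFrame,
    output: str,
    policy: str = "elbow",
    top_k: int | None = None,
    threshold: float | None = None,
) -> Selection:
    """Pick the axes that stand out for one output.

    Policies: ``"elbow"`` cuts at the largest relative gap in the sorted
    indices (all-equal indices select everything, with a warning);
    ``"top_k"`` keeps the best k; ``"threshold"`` keeps ``S_i >= threshold``.
    """
    sub = table[table["output"] == output].sort_values(
        ["S_i", "axis"], ascending=[False, True])
    if sub.empty:
        raise ConfigError(f"no indices for output {output!r}")
    names = sub["axis"].tolist()
    values = sub["S_i"].to_numpy(dtype=float)

    if policy == "top_k":
        if not top_k or top_k < 1:
            raise ConfigError("top_k policy needs top_k >= 1")
        cut = min(top_k, len(names))
    elif policy == "threshold":
        if threshold is None:
            raise ConfigError("threshold policy needs a threshold")
        cut = int(np.sum(values >= threshold))
    elif policy == "elbow":
        eps = 1e-12
        gaps = (values[:-1] - values[1:]) / np.maximum(values[:-1], eps)
        # ignore gaps inside the negligible tail (relative gaps between two
        # near-zero indices are pure noise)
        floor = 0.05 * values[0]
        gaps = np.where(values[:-1] >= floor, gaps, -np.inf)
        if len(gaps) == 0 or np.all(gaps < eps):
            logger.warning("all indices equal for %s; elbow policy selects every axis", output)
            cut = len(names)
        else:
            cut = int(np.argmax(gaps)) + 1
    else:
        raise ConfigError(f"unknown selection policy {policy!r}")

    selected = names[:cut]
    return Selection(
        output=output,
        selected=selected,
        indices=dict(zip(names, values.tolist())),
        explained=float(values[:cut].sum()),
        policy=policy,
    )


def sobol_pick_freeze(
    evaluate: Callable[[np.ndarray], float],
    dim: int,
    n: int,
    seed: int,
) -> np.ndarray:
    """First-order Sobol indices by the pick-freeze (Saltelli) scheme.

    Uses two independent uniform designs A and B on the unit cube and the
    hybrid matrices ``AB_i`` (column i of A frozen into B); requires
    ``n * (dim + 2)`` evaluations of a scalar model.  Cross-check backend
    only — the campaign-reuse estimator is :func:`first_order_index`.
    """
    rng = np.random.default_rng(seed)
    a = rng.random((n, dim))
    b = rng.random((n, dim))
    ya = np.array([evaluate(row) for row in a], dtype=float)
    yb = np.array([evaluate(row) for row in b], dtype=float)
    var = _check_output(np.concatenate([ya, yb]))
    out = np.empty(dim)
    for i in range(dim):
        ab = b.copy()
        ab[:, i] = a[:, i]
        yab = np.array([evaluate(row) for row in ab], dtype=float)
        # Jansen estimator: Var(E[Y|X_i]) ~ Var(Y) - mean((ya - yab)^2) / 2
        out[i] = 1.0 - np.mean((ya - yab) ** 2) / (2.0 * var)
    return out


def heatmap(table: pd.DataFrame, path: str) -> None:
    """Write an axes-by-outputs heatmap of first-order indices (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.pivot(index="axis", columns="output", values="S_i")
    fig, ax = plt.subplots(
        figsize=(2 + 1.2 * pivot.shape[1], 1 + 0.28 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="first-order index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
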