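"""Conditional-inference classification trees and isles-of-robustness extraction.

The exploration campaign is partitioned by a two-stage tree procedure.  A
*main tree* is grown on the management axes Q alone; each of its leaves is a
box of management configurations whose records mix successes and failures.
Leaves whose success proportion reaches a threshold (reference 99%) with
enough weight are *robust*; for every non-robust leaf a *subtree* is grown
on the sensitive natural axes U, and robust subtree leaves delimit the
uncertainty on Nature that the corresponding management box tolerates.

Splits follow the conditional-inference framework: at each node every
candidate axis is tested for association with the binary response using a
standardized linear (correlation) statistic whose p-value comes from a
Monte-Carlo permutation distribution (or an asymptotic normal
approximation), Bonferroni-adjusted across axes.  The node stops when the
smallest adjusted p-value exceeds alpha; otherwise the winning axis is split
at the cutpoint maximizing the standardized two-sample statistic, subject to
a minimum leaf size.  This significance-based stopping avoids the
overfitting and variable-selection bias of exhaustive-search trees.

A resampling stability assessment refits the tree on many random subsets and
reports the modal topology with per-node split-value means and standard
deviations; an info-gap robustness-horizon estimator measures the largest
symmetric deviation from the reference state of Nature within which no
explored scenario fails.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError
from .exploration import ParameterSpace

logger = logging.getLogger(__name__)

LEAF = "<leaf>"


# ---------------------------------------------------------------------------
# configuration and node/tree types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeConfig:
    """Fitting controls for conditional trees."""

    alpha: float = 0.05          # significance level for the stop criterion
    min_leaf: int = 50           # smallest admissible child size
    n_perm: int = 9999           # Monte-Carlo permutation draws
    test: str = "permutation"    # "permutation" | "asymptotic"
    seed: int = 0                # seeds the permutation draws only
    max_depth: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.min_leaf < 1:
            raise ConfigError("min_leaf must be >= 1")
        if self.test not in ("permutation", "asymptotic"):
            raise ConfigError(f"unknown test {self.test!r}")


@dataclass
class TreeNode:
    node_id: int
    n: int
    successes: int
    depth: int
    box: dict[str, tuple[float, float]]
    axis: str | None = None              # split axis (None for leaves)
    value: float | None = None           # split point, normalized units
    p_value: float | None = None         # adjusted p of the winning test
    children: list["TreeNode"] = field(default_factory=list)
    indices: np.ndarray | None = None    # record row positions reaching this node
    robust: bool | None = None
    robust_reason: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def proportion(self) -> float:
        return self.successes / self.n if self.n else float("nan")


@dataclass
class Tree:
    root: TreeNode
    axes: list[str]
    config: TreeConfig
    response: str = "success"

    def nodes(self) -> list[TreeNode]:
        """Breadth-first node list."""
        out, queue = [], [self.root]
        while queue:
            node = queue.pop(0)
            out.append(node)
            queue.extend(node.children)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def fingerprint(self) -> tuple:
        """Depth-tagged breadth-first sequence of split axes (topology id)."""
        return tuple((n.depth, n.axis if n.axis is not None else LEAF)
                     for n in self.nodes())

    def split_values(self) -> list[float]:
        """Split points of internal nodes, in breadth-first order."""
        return [n.value for n in self.nodes() if not n.is_leaf]

    def apply(self, records: pd.DataFrame) -> np.ndarray:
        """Leaf node_id reached by each record."""
        x = records[self.axes].to_numpy(dtype=float)
        out = np.empty(len(records), dtype=np.int64)
        for i, row in enumerate(x):
            node = self.root
            while not node.is_leaf:
                j = self.axes.index(node.axis)
                node = node.children[0] if row[j] <= node.value else node.children[1]
            out[i] = node.node_id
        return out


# ---------------------------------------------------------------------------
# association test and split search
# ---------------------------------------------------------------------------

def _association_pvalues(
    x: np.ndarray, y: np.ndarray, cfg: TreeConfig, rng: np.random.Generator,
) -> np.ndarray:
    """Per-axis p-value of the standardized linear statistic |cor(X_j, y)|.

    Monte-Carlo permutation p-values use ``(1 + exceedances) / (1 + n_perm)``;
    constant columns get p = 1.  No multiplicity adjustment here.
    """
    n, d = x.shape
    yc = y - y.mean()
    sy = float(np.sqrt(np.sum(yc**2)))
    xc = x - x.mean(axis=0)
    sx = np.sqrt(np.sum(xc**2, axis=0))
    valid = (sx > 0) & (sy > 0)
    pvals = np.ones(d)
    if not np.any(valid):
        return pvals
    denom = np.where(valid, sx * sy, 1.0)
    stat = np.abs(yc @ xc) / denom

    if cfg.test == "asymptotic":
        z = stat * np.sqrt(max(n - 1, 1))
        pvals[valid] = 2.0 * (1.0 - norm.cdf(z[valid]))
        return pvals

    exceed = np.zeros(d)
    chunk = max(1, min(cfg.n_perm, int(2e7 // max(n, 1))))
    done = 0
    while done < cfg.n_perm:
        m = min(chunk, cfg.n_perm - done)
        perm = rng.permuted(np.broadcast_to(yc, (m, n)).copy(), axis=1)
        s = np.abs(perm @ xc) / denom
        exceed += np.sum(s >= stat - 1e-12, axis=0)
        done += m
    pvals[valid] = (1.0 + exceed[valid]) / (1.0 + cfg.n_perm)
    return pvals


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int) -> float | None:
    """Cutpoint on one axis maximizing the standardized two-sample statistic.

    Candidates are midpoints between consecutive distinct sorted values with
    both children >= min_leaf.  The statistic is |sum_left(y) - n_left*mean(y)|
    / sqrt(n_left (1 - n_left/n)); ties break toward the cut closest to the
    axis median (then the smaller value).  Returns None when no candidate.
    """
    n = len(y)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    csum = np.cumsum(ys)
    k = np.arange(1, n)                      # left-child sizes
    boundary = xs[:-1] < xs[1:]              # distinct-value boundaries
    ok = boundary & (k >= min_leaf) & (n - k >= min_leaf)
    if not np.any(ok):
        return None
    ybar = y.mean()
    num = np.abs(csum[:-1] - k * ybar)
    var = k * (1.0 - k / n)
    stat = np.where(ok, num / np.sqrt(np.maximum(var, 1e-300)), -np.inf)
    best = stat.max()
    cand = np.flatnonzero(stat >= best - 1e-12)
    mids = (xs[cand] + xs[cand + 1]) / 2.0
    med = float(np.median(x))
    pick = cand[np.lexsort((mids, np.abs(mids - med)))[0]]
    return float((xs[pick] + xs[pick + 1]) / 2.0)


def fit_ctree(
    records: pd.DataFrame,
    axes: Sequence[str],
    config: TreeConfig | None = None,
    response: str = "success",
) -> Tree:
    """Grow a conditional-inference classification tree on ``axes``.

    The response column must be binary (bool or {0, 1}).  Splitting recurses
    while some Bonferroni-adjusted association p-value is below alpha and
    both children can hold ``min_leaf`` records.  Deterministic for a given
    ``config.seed``.
    """
    config = config or TreeConfig()
    axes = list(axes)
    for a in axes:
        if a not in records.columns:
            raise ConfigError(f"records lack axis column {a!r}")
    if response not in records.columns:
        raise ConfigError(f"records lack response column {response!r}")
    y_raw = records[response].to_numpy()
    uniq = np.unique(y_raw)
    if not np.all(np.isin(uniq, [0, 1, True, False])):
        raise ConfigError(f"response {response!r} must be binary")
    y = y_raw.astype(float)
    x = records[axes].to_numpy(dtype=float)
    n = len(y)
    if n < 2 * config.min_leaf:
        raise ConfigError(f"need at least {2 * config.min_leaf} records")
    rng = np.random.default_rng(config.seed)

    counter = {"id": 0}

    def grow(idx: np.ndarray, depth: int, box: dict) -> TreeNode:
        node = TreeNode(
            node_id=counter["id"], n=len(idx), successes=int(y[idx].sum()),
            depth=depth, box=dict(box), indices=idx,
        )
        counter["id"] += 1
        ysub = y[idx]
        stop = (
            len(idx) < 2 * config.min_leaf
            or ysub.min() == ysub.max()
            or (config.max_depth is not None and depth >= config.max_depth)
        )
        if stop:
            return node
        pvals = _association_pvalues(x[idx], ysub, config, rng)
        adjusted = np.minimum(1.0, pvals * len(axes))
        j = int(np.argmin(adjusted))
        if adjusted[j] > config.alpha:
            return node
        cut = _best_split(x[idx, j], ysub, config.min_leaf)
        if cut is None:
            return node
        node.axis = axes[j]
        node.value = cut
        node.p_value = float(adjusted[j])
        left = idx[x[idx, j] <= cut]
        right = idx[x[idx, j] > cut]
        lo, hi = box.get(axes[j], (0.0, 1.0))
        lbox = dict(box); lbox[axes[j]] = (lo, min(hi, cut))
        rbox = dict(box); rbox[axes[j]] = (max(lo, cut), hi)
        node.children = [grow(left, depth + 1, lbox), grow(right, depth + 1, rbox)]
        return node

    root = grow(np.arange(n), 0, {})
    return Tree(root=root, axes=axes, config=config, response=response)


# ---------------------------------------------------------------------------
# robust-leaf labelling, subtrees, regions
# ---------------------------------------------------------------------------

def label_robust_leaves(
    tree: Tree,
    success_threshold: float = 0.99,
    min_weight: float = 0.05,
) -> Tree:
    """Mark each leaf robust iff its success proportion reaches the threshold
    AND its share of the root's records reaches ``min_weight``."""
    root_n = tree.root.n
    for leaf in tree.leaves():
        prop_ok = leaf.proportion >= success_threshold
        weight_ok = leaf.n / root_n >= min_weight
        leaf.robust = bool(prop_ok and weight_ok)
        if leaf.robust:
            leaf.robust_reason = "robust"
        elif prop_ok:
            leaf.robust_reason = "low weight"
        else:
            leaf.robust_reason = "success proportion below threshold"
    return tree


def grow_subtrees(
    main_tree: Tree,
    records: pd.DataFrame,
    u_axes: Sequence[str],
    config: TreeConfig | None = None,
    success_threshold: float = 0.99,
    min_weight: float = 0.05,
) -> dict[int, Tree]:
    """Fit a subtree on the natural axes for every non-robust main-tree leaf.

    Main-tree leaves must have been labelled (or are labelled here with the
    given thresholds); robust leaves get no subtree, and leaves too small to
    split are skipped with a log message.  Subtree leaves are labelled with
    the same thresholds, their weight measured against the subtree root.
    """
    config = config or main_tree.config
    u_axes = list(u_axes)
    overlap = set(u_axes) & set(main_tree.axes)
    if overlap:
        raise ConfigError(f"natural axes overlap the main tree's axes: {sorted(overlap)}")
    if any(leaf.robust is None for leaf in main_tree.leaves()):
        label_robust_leaves(main_tree, success_threshold, min_weight)
    subtrees: dict[int, Tree] = {}
    for leaf in main_tree.leaves():
        if leaf.robust:
            continue
        if leaf.n < 2 * config.min_leaf:
            logger.info("leaf %d too small for a subtree (n=%d)", leaf.node_id, leaf.n)
            continue
        sub_records = records.iloc[leaf.indices]
        sub = fit_ctree(sub_records, u_axes, config, main_tree.response)
        label_robust_leaves(sub, success_threshold, min_weight)
        subtrees[leaf.node_id] = sub
    return subtrees


@dataclass
class RobustRegion:
    """A robust box: management constraints plus tolerated natural uncertainty.

    Margins are per-natural-axis Chebyshev distances from the reference
    coordinate 0.5 to the nearest binding bound (normalized units), also
    expressed as a percentage of the reference value in natural units.
    """

    name: str
    main_leaf: int
    sub_leaf: int | None
    n: int
    successes: int
    management_bounds: dict[str, tuple[float, float]]          # normalized
    natural_bounds: dict[str, tuple[float, float]]             # normalized
    management_bounds_natural: dict[str, tuple[float, float]]  # natural units
    natural_bounds_natural: dict[str, tuple[float, float]]
    margins: dict[str, float]           # normalized distance 0.5 -> binding bound
    margins_pct: dict[str, float]       # as % of the reference value
    contains_reference: bool

    @property
    def proportion(self) -> float:
        return self.successes / self.n if self.n else float("nan")


def _margin(bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if not lo <= 0.5 <= hi:
        return 0.0
    return min(0.5 - lo, hi - 0.5)


def extract_regions(
    main_tree: Tree,
    subtrees: Mapping[int, Tree],
    space: ParameterSpace,
) -> list[RobustRegion]:
    """One region per robust leaf (of the main tree or of a subtree).

    Each region conjoins the ancestor constraints of its leaves; normalized
    bounds are converted to natural units through the axes' affine
    transforms, and the margin percentage uses the axis window:
    ``pct = distance * (upper - lower) / reference * 100``.
    """
    regions: list[RobustRegion] = []

    def pct(axis_name: str, distance: float) -> float:
        axis = space.axis(axis_name)
        if axis.reference == 0:
            return float("nan")
        return distance * (axis.upper - axis.lower) / abs(axis.reference) * 100.0

    def natural(bounds: dict[str, tuple[float, float]]) -> dict:
        out = {}
        for name, (lo, hi) in bounds.items():
            axis = space.axis(name)
            a, b = float(axis.denormalize(lo)), float(axis.denormalize(hi))
            out[name] = (min(a, b), max(a, b))
        return out

    def build(main_leaf, sub_leaf, q_box, u_box, n, successes) -> RobustRegion:
        natural_axes = space.natural_names
        full_u = {name: u_box.get(name, (0.0, 1.0)) for name in natural_axes}
        margins = {name: _margin(b) for name, b in full_u.items()}
        contains = all(lo <= 0.5 <= hi for lo, hi in full_u.values())
        label = (f"main-leaf {main_leaf}" if sub_leaf is None
                 else f"main-leaf {main_leaf} / sub-leaf {sub_leaf}")
        return RobustRegion(
            name=label, main_leaf=main_leaf, sub_leaf=sub_leaf,
            n=n, successes=successes,
            management_bounds=dict(q_box), natural_bounds=dict(u_box),
            management_bounds_natural=natural(q_box),
            natural_bounds_natural=natural(u_box),
            margins=margins,
            margins_pct={k: pct(k, v) for k, v in margins.items()},
            contains_reference=contains,
        )

    for leaf in main_tree.leaves():
        if leaf.robust:
            regions.append(build(leaf.node_id, None, leaf.box, {}, leaf.n, leaf.successes))
        elif leaf.node_id in subtrees:
            for sleaf in subtrees[leaf.node_id].leaves():
                if sleaf.robust:
                    regions.append(build(leaf.node_id, sleaf.node_id, leaf.box,
                                         sleaf.box, sleaf.n, sleaf.successes))
    return regions


# ---------------------------------------------------------------------------
# stability assessment
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Topology frequencies over resampled refits, with modal split statistics."""

    frequencies: dict[tuple, int]
    modal: tuple
    modal_count: int
    node_stats: pd.DataFrame     # BFS position, axis, mean split, SD
    b: int
    frac: float

    def modal_frequency(self) -> float:
        return self.modal_count / self.b


def stability_analysis(
    records: pd.DataFrame,
    axes: Sequence[str],
    config: TreeConfig | None = None,
    b: int = 500,
    frac: float = 0.95,
    seed: int = 0,
    response: str = "success",
) -> StabilityReport:
    """Refit the tree on ``b`` random subsets of ``ceil(frac * n)`` records.

    Topologies are fingerprinted by their depth-tagged breadth-first
    split-axis sequence (split values ignored); the modal fingerprint (ties
    broken lexicographically) is reported with per-internal-node mean split
    values and standard deviations over the matching replicates.
    """
    config = config or TreeConfig()
    if not 0 < frac <= 1:
        raise ConfigError("frac must lie in (0, 1]")
    n = len(records)
    m = int(np.ceil(frac * n))
    rng = np.random.default_rng(seed)

    fingerprints: list[tuple] = []
    values: list[list[float]] = []
    axes_seq: list[list[str]] = []
    for rep in range(b):
        idx = rng.choice(n, size=m, replace=False)
        sub = records.iloc[np.sort(idx)]
        tree = fit_ctree(sub, axes, config, response)
        fingerprints.append(tree.fingerprint())
        values.append(tree.split_values())
        axes_seq.append([node.axis for node in tree.nodes() if not node.is_leaf])

    counts = Counter(fingerprints)
    top = max(counts.values())
    modal = min(fp for fp, c in counts.items() if c == top)

    matching = [i for i, fp in enumerate(fingerprints) if fp == modal]
    stats_rows = []
    if matching:
        n_internal = len(values[matching[0]])
        for pos in range(n_internal):
            vals = np.array([values[i][pos] for i in matching], dtype=float)
            stats_rows.append({
                "position": pos,
                "axis": axes_seq[matching[0]][pos],
                "mean_split": float(vals.mean()),
                "sd_split": float(vals.std(ddof=0)),
            })
    return StabilityReport(
        frequencies=dict(counts), modal=modal, modal_count=top,
        node_stats=pd.DataFrame(stats_rows, columns=["position", "axis",
                                                     "mean_split", "sd_split"]),
        b=b, frac=frac,
    )


# ---------------------------------------------------------------------------
# info-gap robustness horizon
# ---------------------------------------------------------------------------

def robustness_horizon(
    records: pd.DataFrame,
    natural_axes: Sequence[str],
    management_filter: Mapping[str, tuple[float, float]] | None = None,
    reference: float = 0.5,
    response: str = "success",
) -> float:
    """Empirical info-gap robustness: the largest symmetric deviation from the
    reference state of Nature with no observed failure.

    Records are optionally restricted to a management box; each record's
    Chebyshev distance ``max_i |u_i - reference|`` over the natural axes is
    computed, and the horizon is the distance of the nearest failure (0.5,
    the full half-window, when every retained record is a success).
    """
    mask = np.ones(len(records), dtype=bool)
    if management_filter:
        for name, (lo, hi) in management_filter.items():
            if name not in records.columns:
                raise ConfigError(f"records lack axis column {name!r}")
            x = records[name].to_numpy(dtype=float)
            mask &= (x >= lo) & (x <= hi)
    sub = records[mask]
    if sub.empty:
        raise ConfigError("no records inside the management filter")
    u = sub[list(natural_axes)].to_numpy(dtype=float)
    dist = np.max(np.abs(u - reference), axis=1)
    success = sub[response].to_numpy(dtype=bool)
    if success.all():
        return 0.5
    return float(dist[~success].min())


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _node_to_dict(node: TreeNode) -> dict:
    d = {
        "node_id": node.node_id, "n": node.n, "successes": node.successes,
        "depth": node.depth, "box": {k: list(v) for k, v in node.box.items()},
        "axis": node.axis, "value": node.value, "p_value": node.p_value,
        "robust": node.robust, "robust_reason": node.robust_reason,
        "children": [_node_to_dict(c) for c in node.children],
    }
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        node_id=d["node_id"], n=d["n"], successes=d["successes"],
        depth=d["depth"], box={k: tuple(v) for k, v in d["box"].items()},
        axis=d["axis"], value=d["value"], p_value=d["p_value"],
        robust=d["robust"], robust_reason=d["robust_reason"],
    )
    node.children = [_node_from_dict(c) for c in d["children"]]
    return node


def tree_to_json(tree: Tree) -> str:
    payload = {
        "axes": tree.axes,
        "response": tree.response,
        "config": {
            "alpha": tree.config.alpha, "min_leaf": tree.config.min_leaf,
            "n_perm": tree.config.n_perm, "test": tree.config.test,
            "seed": tree.config.seed, "max_depth": tree.config.max_depth,
        },
        "root": _node_to_dict(tree.root),
    }
    return json.dumps(payload, indent=2)


def tree_from_json(text: str) -> Tree:
    payload = json.loads(text)
    return Tree(
        root=_node_from_dict(payload["root"]),
        axes=payload["axes"],
        config=TreeConfig(**payload["config"]),
        response=payload["response"],
    )


def tree_to_dot(tree: Tree, name: str = "tree") -> str:
    """Graphviz DOT rendering of the fitted tree."""
    lines = [f"digraph {name} {{", "  node [shape=box];"]
    for node in tree.nodes():
        if node.is_leaf:
            robust = "" if node.robust is None else f"\\n{node.robust_reason}"
            label = (f"leaf {node.node_id}\\nn={node.n}"
                     f"\\np(success)={node.proportion:.3f}{robust}")
        else:
            label = (f"{node.axis} <= {node.value:.3f}"
                     f"\\nn={node.n}, p={node.p_value:.2g}")
        lines.append(f'  n{node.node_id} [label="{label}"];')
        for child in node.children:
            lines.append(f"  n{node.node_id} -> n{child.node_id};")
    lines.append("}")
    return "\n".join(lines)
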