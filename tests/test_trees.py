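"""Conditional-tree, stability and robustness-horizon tests.

Oracles: an independent exhaustive scan of the two-sample split statistic,
a brute-force scan for the info-gap horizon, and (as an external reference)
a depth-1 scikit-learn decision tree on cleanly separable data.
"""

import numpy as np
import pandas as pd
import pytest

import robfish as rf
from robfish import trees
from robfish.errors import ConfigError

FAST = rf.TreeConfig(alpha=0.05, min_leaf=50, n_perm=499, seed=1)


def _records(x, y, names=None):
    names = names or [f"x{i}" for i in range(x.shape[1])]
    df = pd.DataFrame(x, columns=names)
    df["success"] = y.astype(bool)
    return df


def oracle_best_split(x, y, min_leaf):
    """Independent exhaustive scan of the standardized two-sample statistic."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(y)
    best, best_cut = -np.inf, None
    for k in range(min_leaf, n - min_leaf + 1):
        if k < n and xs[k - 1] == xs[k]:
            continue
        stat = abs(ys[:k].sum() - k * y.mean()) / np.sqrt(k * (1 - k / n))
        if stat > best + 1e-12:
            best, best_cut = stat, (xs[k - 1] + xs[k]) / 2
    return best_cut


def oracle_horizon(records, natural_axes, response="success"):
    """Brute-force horizon: scan every symmetric box around 0.5."""
    u = records[list(natural_axes)].to_numpy(dtype=float)
    ok = records[response].to_numpy(dtype=bool)
    dist = np.max(np.abs(u - 0.5), axis=1)
    best = 0.5
    for alpha in np.unique(dist):
        inside = dist <= alpha
        if not ok[inside].all():
            best = min(best, alpha)
    return best if not ok.all() else 0.5


class TestFitCtree:
    def test_pure_node_is_leaf(self):
        rng = np.random.default_rng(0)
        df = _records(rng.random((200, 2)), np.ones(200))
        tree = rf.fit_ctree(df, ["x0", "x1"], FAST)
        assert tree.root.is_leaf
        assert tree.root.successes == 200

    def test_noise_free_threshold_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.random((2000, 3))
        y = x[:, 0] < 0.4
        df = _records(x, y)
        tree = rf.fit_ctree(df, ["x0", "x1", "x2"], FAST)
        assert tree.root.axis == "x0"
        # the fitted cut must agree with the independent exhaustive scan
        expected = oracle_best_split(x[:, 0], y.astype(float), FAST.min_leaf)
        assert tree.root.value == pytest.approx(expected, abs=1e-12)
        # and sit within one inter-point gap of the true boundary
        gap = np.max(np.diff(np.sort(x[:, 0])))
        assert abs(tree.root.value - 0.4) <= 2 * gap + 1e-9

    def test_sklearn_reference_split(self):
        sklearn = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(2)
        x = rng.random((3000, 2))
        y = x[:, 0] < 0.35
        df = _records(x, y)
        tree = rf.fit_ctree(df, ["x0", "x1"], FAST)
        ref = sklearn.DecisionTreeClassifier(max_depth=1, random_state=0).fit(x, y)
        assert tree.root.axis == "x0"
        assert tree.root.value == pytest.approx(ref.tree_.threshold[0], abs=0.01)

    def test_partition_identities(self, box_records):
        tree = rf.fit_ctree(box_records, ["q1", "q2"], FAST)
        for node in tree.nodes():
            if not node.is_leaf:
                assert node.n == sum(c.n for c in node.children)
                assert node.successes == sum(c.successes for c in node.children)
                for child in node.children:
                    for axis, (lo, hi) in node.box.items():
                        clo, chi = child.box.get(axis, (0.0, 1.0))
                        assert clo >= lo - 1e-12 and chi <= hi + 1e-12

    def test_every_record_reaches_one_leaf(self, box_records):
        tree = rf.fit_ctree(box_records, ["q1", "q2"], FAST)
        leaf_ids = tree.apply(box_records)
        counts = pd.Series(leaf_ids).value_counts()
        assert counts.sum() == len(box_records)
        for leaf in tree.leaves():
            assert counts.get(leaf.node_id, 0) == leaf.n

    def test_same_seed_same_tree(self, box_records):
        a = rf.fit_ctree(box_records, ["q1", "q2"], FAST)
        b = rf.fit_ctree(box_records, ["q1", "q2"], FAST)
        assert a.fingerprint() == b.fingerprint()
        assert a.split_values() == b.split_values()

    def test_non_binary_response_rejected(self):
        df = pd.DataFrame({"x0": [0.1, 0.2, 0.3], "success": [0.0, 0.5, 1.0]})
        with pytest.raises(ConfigError, match="binary"):
            rf.fit_ctree(df, ["x0"], rf.TreeConfig(min_leaf=1))

    def test_asymptotic_backend_agrees_on_strong_signal(self):
        rng = np.random.default_rng(3)
        x = rng.random((1000, 2))
        y = x[:, 1] > 0.6
        df = _records(x, y)
        perm = rf.fit_ctree(df, ["x0", "x1"], FAST)
        asym = rf.fit_ctree(df, ["x0", "x1"],
                            rf.TreeConfig(min_leaf=50, test="asymptotic"))
        assert perm.root.axis == asym.root.axis == "x1"
        assert perm.root.value == pytest.approx(asym.root.value, abs=1e-12)


class TestRobustLeaves:
    def _single_leaf_tree(self, successes, n=1000):
        y = np.zeros(n, dtype=bool)
        y[:successes] = True
        rng = np.random.default_rng(4)
        df = _records(rng.random((n, 1)), rng.permutation(y))
        tree = rf.fit_ctree(df, ["x0"], rf.TreeConfig(min_leaf=50, alpha=1e-6,
                                                      n_perm=199, seed=0))
        return tree

    def test_ninety_nine_percent_boundary(self):
        robust = rf.label_robust_leaves(self._single_leaf_tree(990))
        assert all(l.robust for l in robust.leaves() if l.n == 1000)
        not_robust = rf.label_robust_leaves(self._single_leaf_tree(989))
        assert not any(l.robust for l in not_robust.leaves())

    def test_strict_threshold_rejects_any_failure(self):
        tree = rf.label_robust_leaves(self._single_leaf_tree(999),
                                      success_threshold=1.0)
        assert not any(l.robust for l in tree.leaves())

    def test_low_weight_flagged(self, box_records):
        tree = rf.fit_ctree(box_records, ["q1", "u1"], FAST)
        rf.label_robust_leaves(tree, min_weight=0.99)
        flagged = [l for l in tree.leaves()
                   if l.proportion >= 0.99 and not l.robust]
        assert all(l.robust_reason == "low weight" for l in flagged)
        assert not any(l.robust for l in tree.leaves())


@pytest.fixture(scope="module")
def pipeline(box_records):
    main = rf.fit_ctree(box_records, ["q1", "q2"], FAST)
    rf.label_robust_leaves(main)
    subs = rf.grow_subtrees(main, box_records, ["u1", "u2"], FAST)
    return main, subs


class TestSubtreesAndRegions:
    def test_only_non_robust_leaves_get_subtrees(self, pipeline):
        main, subs = pipeline
        expected = {l.node_id for l in main.leaves()
                    if not l.robust and l.n >= 2 * FAST.min_leaf}
        assert set(subs) == expected

    def test_subtree_counts_sum_to_leaf(self, pipeline):
        main, subs = pipeline
        for leaf in main.leaves():
            if leaf.node_id in subs:
                assert subs[leaf.node_id].root.n == leaf.n

    def test_overlapping_axes_rejected(self, pipeline, box_records):
        main, _ = pipeline
        with pytest.raises(ConfigError, match="overlap"):
            rf.grow_subtrees(main, box_records, ["q1", "u1"], FAST)

    def test_extract_regions_margins(self, pipeline, box_records):
        main, subs = pipeline
        toy = rf.make_toy_scenario("box-recovery")
        regions = rf.extract_regions(main, subs, toy.space)
        assert regions, "the success box must yield at least one robust region"
        # the good region: q1 below ~0.4 (management), u1 above ~0.3 (Nature)
        region = max(regions, key=lambda r: r.n)
        q1 = region.management_bounds.get("q1", (0.0, 1.0))
        assert q1[1] == pytest.approx(0.4, abs=0.05)
        u1 = region.natural_bounds.get("u1", (0.0, 1.0))
        assert u1[0] == pytest.approx(0.3, abs=0.05)
        # margin = distance from the reference 0.5 to the binding bound
        assert region.margins["u1"] == pytest.approx(0.5 - u1[0], abs=1e-12)
        # u2 unconstrained: full half-window margin
        assert region.margins["u2"] == 0.5
        assert region.contains_reference

    def test_region_excluding_reference_is_flagged(self):
        space = rf.make_toy_scenario("box-recovery").space
        node = trees.TreeNode(0, 100, 100, 0, box={"u1": (0.6, 1.0)}, robust=True)
        tree = trees.Tree(root=node, axes=["u1"], config=FAST)
        # wrap as a subtree of a non-robust main leaf
        main_leaf = trees.TreeNode(0, 100, 50, 0, box={"q1": (0.0, 0.5)}, robust=False)
        main = trees.Tree(root=main_leaf, axes=["q1"], config=FAST)
        regions = rf.extract_regions(main, {0: tree}, space)
        assert len(regions) == 1
        assert not regions[0].contains_reference
        assert regions[0].margins["u1"] == 0.0

    def test_margin_pct_uses_axis_window(self, demo_space):
        # MW axis: +/-50% window; normalized margin 0.24 <-> 24% of reference
        node = trees.TreeNode(0, 100, 100, 0, box={"MWS7D": (0.26, 1.0)}, robust=True)
        sub = trees.Tree(root=node, axes=["MWS7D"], config=FAST)
        main_leaf = trees.TreeNode(0, 100, 50, 0, box={}, robust=False)
        main = trees.Tree(root=main_leaf, axes=["Trans"], config=FAST)
        regions = rf.extract_regions(main, {0: sub}, demo_space)
        assert regions[0].margins["MWS7D"] == pytest.approx(0.24)
        assert regions[0].margins_pct["MWS7D"] == pytest.approx(24.0)


class TestStability:
    def test_single_replicate(self, clean_box_records):
        report = rf.stability_analysis(clean_box_records, ["q1", "q2"],
                                       FAST, b=1, frac=0.95, seed=0)
        assert len(report.frequencies) == 1
        assert report.modal_count == 1

    def test_frequencies_sum_to_b(self, box_records):
        sub = box_records.iloc[:800]
        report = rf.stability_analysis(sub, ["q1", "u1"],
                                       rf.TreeConfig(min_leaf=50, test="asymptotic"),
                                       b=25, frac=0.9, seed=3)
        assert sum(report.frequencies.values()) == 25

    def test_noise_free_is_perfectly_stable(self, clean_box_records):
        cfg = rf.TreeConfig(min_leaf=50, test="asymptotic")
        report = rf.stability_analysis(clean_box_records, ["q1", "q2"],
                                       cfg, b=30, frac=0.95, seed=5)
        assert report.modal_count == 30
        gap = np.max(np.diff(np.sort(clean_box_records["q1"].to_numpy())))
        assert np.all(report.node_stats["sd_split"].to_numpy() <= 2 * gap)

    def test_seed_reproducible(self, clean_box_records):
        cfg = rf.TreeConfig(min_leaf=50, test="asymptotic")
        a = rf.stability_analysis(clean_box_records, ["q1", "q2"], cfg, b=10, seed=6)
        b = rf.stability_analysis(clean_box_records, ["q1", "q2"], cfg, b=10, seed=6)
        assert a.frequencies == b.frequencies
        pd.testing.assert_frame_equal(a.node_stats, b.node_stats)

    def test_modal_topology_matches_full_data_fit(self, clean_box_records):
        cfg = rf.TreeConfig(min_leaf=50, test="asymptotic")
        full = rf.fit_ctree(clean_box_records, ["q1", "q2"], cfg)
        report = rf.stability_analysis(clean_box_records, ["q1", "q2"],
                                       cfg, b=20, frac=0.95, seed=7)
        assert report.modal == full.fingerprint()


class TestRobustnessHorizon:
    def test_all_successes_full_half_window(self):
        rng = np.random.default_rng(8)
        df = _records(rng.random((100, 2)), np.ones(100), ["u1", "u2"])
        assert rf.robustness_horizon(df, ["u1", "u2"]) == 0.5

    def test_failure_at_reference_gives_zero(self):
        df = pd.DataFrame({"u1": [0.5, 0.1], "success": [False, True]})
        assert rf.robustness_horizon(df, ["u1"]) == 0.0

    def test_synthetic_band_rule(self):
        # failures exactly when any natural axis < 0.2 or > 0.8 -> horizon 0.3
        rng = np.random.default_rng(9)
        u = rng.random((20_000, 2))
        y = np.all((u >= 0.2) & (u <= 0.8), axis=1)
        df = _records(u, y, ["u1", "u2"])
        got = rf.robustness_horizon(df, ["u1", "u2"])
        assert got == pytest.approx(0.3, abs=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.random((500, 3))
        y = rng.random(500) < 0.8
        df = _records(u, y, ["u1", "u2", "u3"])
        assert rf.robustness_horizon(df, ["u1", "u2", "u3"]) == oracle_horizon(
            df, ["u1", "u2", "u3"])

    def test_management_filter(self, box_records):
        got = rf.robustness_horizon(box_records, ["u1", "u2"],
                                    management_filter={"q1": (0.0, 0.39)})
        assert got == oracle_horizon(box_records[box_records["q1"] <= 0.39],
                                     ["u1", "u2"])

    def test_empty_filter_rejected(self, box_records):
        with pytest.raises(ConfigError, match="no records"):
            rf.robustness_horizon(box_records, ["u1"],
                                  management_filter={"q1": (2.0, 3.0)})


class TestSerialization:
    def test_json_round_trip(self, box_records):
        tree = rf.fit_ctree(box_records, ["q1", "q2"], FAST)
        rf.label_robust_leaves(tree)
        text = trees.tree_to_json(tree)
        back = trees.tree_from_json(text)
        assert back.fingerprint() == tree.fingerprint()
        assert back.split_values() == tree.split_values()
        assert [l.robust for l in back.leaves()] == [l.robust for l in tree.leaves()]
        np.testing.assert_array_equal(back.apply(box_records), tree.apply(box_records))

    def test_dot_export_mentions_every_node(self, box_records):
        tree = rf.fit_ctree(box_records, ["q1", "q2"], FAST)
        dot = trees.tree_to_dot(tree)
        for node in tree.nodes():
            assert f"n{node.node_id}" in dot
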