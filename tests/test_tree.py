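"""Conditional inference tree: permutation tests, split search, growth,
routing, serialization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mcart.tree import (
    STOP,
    SubgroupTree,
    TreeParams,
    best_split,
    grow_tree,
    independence_test,
    predict_node,
    select_variable,
)


def test_params_validation():
    with pytest.raises(ValueError):
        TreeParams(alpha=0.0)
    with pytest.raises(ValueError):
        TreeParams(min_split=10, min_leaf=7)
    with pytest.raises(ValueError):
        TreeParams(adjust="fdr")


# --- independence test ------------------------------------------------------


def test_constant_response_is_uninformative():
    assert independence_test([1.0, 2.0, 3.0], [0, 0, 0])[1] == 1.0
    assert independence_test([1.0, 1.0, 1.0], [-1, 0, 1])[1] == 1.0


def _oracle_exact_p(x, y):
    """All-n! enumeration of the permutation distribution of the
    standardized quadratic statistic (numeric x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    ybar, sx = y.mean(), x.sum()
    vh = ((y - ybar) ** 2).sum() / n
    var = n / (n - 1) * vh * (x ** 2).sum() - vh * sx ** 2 / (n - 1)
    t_obs = (x * y).sum()
    c_obs = (t_obs - sx * ybar) ** 2 / var
    hits = total = 0
    for perm in itertools.permutations(y):
        c = ((x * np.array(perm)).sum() - sx * ybar) ** 2 / var
        hits += c >= c_obs - 1e-9
        total += 1
    return hits / total


@pytest.mark.parametrize("y", [(-1, -1, 0, 0, 1, 1), (-1, 0, 0, 0, 0, 1),
                               (1, 1, 1, 0, -1, 0)])
def test_exact_p_equals_full_enumeration(y):
    x = np.array([0.3, -1.2, 0.8, 1.9, -0.4, 0.0])
    _, p = independence_test(x, np.array(y, dtype=float))
    assert p == pytest.approx(_oracle_exact_p(x, y), abs=1e-12)


def test_exact_p_equals_enumeration_small_n():
    rng = np.random.default_rng(8)
    for n in (4, 6, 8):
        x = rng.normal(size=n)
        y = rng.choice([-1.0, 0.0, 1.0], size=n)
        if np.ptp(y) == 0:
            continue
        _, p = independence_test(x, y)
        assert p == pytest.approx(_oracle_exact_p(x, y), abs=1e-12)


def test_asymptotic_p_matches_monte_carlo():
    """chi-square p at n=200 agrees with a 50,000-draw permutation
    Monte-Carlo estimate within 0.02 under independence."""
    rng = np.random.default_rng(123)
    n = 200
    x = rng.normal(size=n)
    y = rng.choice([-1.0, 0.0, 1.0], size=n, p=[0.3, 0.4, 0.3])
    _, p_asym = independence_test(x, y)
    ybar, sx = y.mean(), x.sum()
    vh = ((y - ybar) ** 2).sum() / n
    var = n / (n - 1) * vh * (x ** 2).sum() - vh * sx ** 2 / (n - 1)
    c_obs = ((x * y).sum() - sx * ybar) ** 2 / var
    perms = rng.permuted(np.tile(y, (50_000, 1)), axis=1)
    c_mc = ((perms @ x) - sx * ybar) ** 2 / var
    assert p_asym == pytest.approx(float((c_mc >= c_obs).mean()), abs=0.02)


def test_categorical_test_detects_level_shift():
    rng = np.random.default_rng(1)
    x = np.array(["a"] * 50 + ["b"] * 50)
    y = np.concatenate([rng.choice([-1.0, 0, 1], 50, p=[0.8, 0.1, 0.1]),
                        rng.choice([-1.0, 0, 1], 50, p=[0.1, 0.1, 0.8])])
    _, p = independence_test(x, y, kind="categorical")
    assert p < 1e-6


# --- variable selection -----------------------------------------------------


def _frame(cols):
    return pd.DataFrame(cols)


def test_small_node_stops():
    df = _frame({"x": np.arange(10.0)})
    y = np.tile([-1.0, 1.0], 5)
    assert select_variable(df, y, ["x"], {"x": "numeric"},
                           TreeParams(min_split=20)) is STOP


def test_bonferroni_arithmetic():
    rng = np.random.default_rng(5)
    n = 80
    x_signal = np.repeat([0.0, 1.0], n // 2)
    y = x_signal * 2 - 1 + rng.normal(0, 0.8, n)
    noise = {f"n{i}": rng.normal(size=n) for i in range(9)}
    df = _frame({"x": x_signal, **noise})
    kinds = {c: "numeric" for c in df.columns}
    _, p_raw = independence_test(x_signal, y)
    var, p_adj = select_variable(df, y, list(df.columns), kinds, TreeParams())
    assert var == "x"
    assert p_adj == pytest.approx(min(10 * p_raw, 1.0))
    # single-candidate selection is the identity adjustment
    _, p_single = select_variable(df[["x"]], y, ["x"], kinds, TreeParams())
    assert p_single == pytest.approx(p_raw)


# --- split search -----------------------------------------------------------


def test_perfect_separation_midpoint():
    rule = best_split(np.array([1.0, 2.0, 3.0, 4.0]), np.array([-1.0, -1.0, 1.0, 1.0]),
                      "numeric", TreeParams(min_split=4, min_leaf=2))
    assert rule == {"threshold": 2.5}


def test_min_leaf_blocks_unbalanced_split():
    x = np.array([1.0] * 3 + [0.0] * 17)
    y = np.array([-1.0] * 3 + [1.0] * 17)
    assert best_split(x, y, "numeric", TreeParams(min_leaf=7)) is STOP


def test_threshold_equals_exhaustive_oracle():
    rng = np.random.default_rng(2)
    x = rng.normal(size=12)
    y = rng.choice([-1.0, 0.0, 1.0], 12)
    params = TreeParams(min_split=4, min_leaf=2)
    rule = best_split(x, y, "numeric", params)
    # independent oracle: score every midpoint directly
    n, ybar = len(y), y.mean()
    ssy = ((y - ybar) ** 2).sum()
    xs = np.sort(np.unique(x))
    best_score, best_cut = -np.inf, None
    for lo, hi in zip(xs[:-1], xs[1:]):
        cut = (lo + hi) / 2
        left = x <= cut
        nl = left.sum()
        if nl < 2 or n - nl < 2:
            continue
        var = ssy / (n * (n - 1)) * nl * (n - nl)
        score = abs(y[left].sum() - nl * ybar) / np.sqrt(var)
        if score > best_score:
            best_score, best_cut = score, cut
    assert rule["threshold"] == pytest.approx(best_cut)


def test_categorical_split_by_level_subset():
    x = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
    y = np.array([-1.0] * 20 + [1.0] * 10)
    rule = best_split(x, y, "categorical", TreeParams(min_split=6, min_leaf=3))
    assert set(rule["levels"]) in ({"a", "b"}, {"c"})


def test_too_many_levels_refused():
    x = np.array([str(i) for i in range(12)] * 3)
    y = np.tile([-1.0, 0.0, 1.0], 12)
    with pytest.raises(ValueError, match="levels refused"):
        best_split(x, y, "categorical", TreeParams(min_split=4, min_leaf=2))


# --- growth -----------------------------------------------------------------


def test_noise_rarely_splits():
    """Under the null the root should stay terminal in >= 90 of 100
    replicates at alpha = 0.05 (Bonferroni across 10 variables)."""
    rng = np.random.default_rng(77)
    splits = 0
    for _ in range(100):
        df = pd.DataFrame({f"x{i}": rng.normal(size=500) for i in range(10)})
        y = rng.choice([-1.0, 0.0, 1.0], 500)
        tree = grow_tree(df, y, {c: "numeric" for c in df.columns})
        splits += tree.n_subgroups > 1
    assert splits <= 10


def test_global_null_split_rate_within_alpha_band():
    """P(any split) <= alpha + 0.03 across 200 seeded replicates."""
    rng = np.random.default_rng(99)
    splits = 0
    for _ in range(200):
        df = pd.DataFrame({f"x{i}": rng.normal(size=300) for i in range(5)})
        y = rng.permutation(np.repeat([-1.0, 0.0, 1.0], 100))
        tree = grow_tree(df, y, {c: "numeric" for c in df.columns})
        splits += tree.n_subgroups > 1
    assert splits / 200 <= 0.05 + 0.03


def test_perfect_binary_signal_single_split():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 2, 100).astype(float)
    df = pd.DataFrame({"x": x, "noise": rng.normal(size=100)})
    y = np.where(x == 1, -1.0, 0.0)
    tree = grow_tree(df, y, {"x": "numeric", "noise": "numeric"})
    assert tree.n_subgroups == 2
    assert tree.root.var == "x"


def test_terminal_nodes_partition_data():
    rng = np.random.default_rng(4)
    df = pd.DataFrame({"a": rng.normal(size=400), "b": rng.integers(0, 2, 400).astype(float)})
    y = np.where(df["b"] == 1, 1.0, -1.0) * (rng.random(400) < 0.8)
    tree = grow_tree(df, y, {"a": "numeric", "b": "numeric"})
    ids = predict_node(tree, df)
    assert sorted(pd.unique(ids)) == tree.terminal_ids
    sizes = {nid: tree.nodes[nid].n for nid in tree.terminal_ids}
    assert sum(sizes.values()) == 400
    for nid in tree.terminal_ids:
        assert (ids == nid).sum() == sizes[nid]


def test_smaller_alpha_prunes_tree():
    rng = np.random.default_rng(6)
    x = rng.normal(size=600)
    z = rng.integers(0, 2, 600).astype(float)
    y = np.where(z == 1, 0.5, -0.5) + np.where(x > 0, 0.3, -0.3) + rng.normal(0, 1, 600)
    df = pd.DataFrame({"x": x, "z": z})
    kinds = {"x": "numeric", "z": "numeric"}
    loose = grow_tree(df, y, kinds, TreeParams(alpha=0.05))
    strict = grow_tree(df, y, kinds, TreeParams(alpha=0.01))
    assert strict.n_subgroups <= loose.n_subgroups

    def split_set(tree):
        return {(n.var, n.threshold) for n in tree.nodes.values() if not n.is_terminal}

    assert split_set(strict) <= split_set(loose)


# --- routing and serialization ---------------------------------------------


def test_routing_matches_hand_written_evaluator():
    rng = np.random.default_rng(11)
    df = pd.DataFrame({
        "egfr": rng.normal(72, 20, 100),
        "aspirin": rng.integers(0, 2, 100).astype(float),
        "smoking": rng.choice(["never", "former", "current"], 100)})
    y = (np.where(df["aspirin"] == 1, 0.3, -0.3)
         + np.where(df["egfr"] > 72, 0.2, -0.2) + rng.normal(0, 0.1, 100))
    kinds = {"egfr": "numeric", "aspirin": "numeric", "smoking": "categorical"}
    tree = grow_tree(df, y, kinds, TreeParams(min_split=10, min_leaf=5))
    assert tree.n_subgroups >= 2

    def route(row):
        nid = 1
        while not tree.nodes[nid].is_terminal:
            node = tree.nodes[nid]
            if node.kind == "numeric":
                left = row[node.var] <= node.threshold
            else:
                left = str(row[node.var]) in node.levels
            nid = node.left if left else node.right
        return nid

    got = predict_node(tree, df)
    expected = df.apply(route, axis=1).to_numpy()
    np.testing.assert_array_equal(got, expected)


def test_boundary_routes_left():
    from mcart.tree import Node

    nodes = {
        1: Node(1, 0, 4, 0.0, None, var="egfr", kind="numeric",
                threshold=72.743, p_value=0.01, left=2, right=3),
        2: Node(2, 1, 2, -1.0, None),
        3: Node(3, 1, 2, 1.0, None),
    }
    tree = SubgroupTree(nodes, TreeParams(), ["egfr"], {"egfr": "numeric"})
    df = pd.DataFrame({"egfr": [60.0, 80.0, 72.743, 72.7431]})
    ids = predict_node(tree, df)
    np.testing.assert_array_equal(ids, [2, 3, 2, 3])  # x == c goes left


def test_single_node_tree_routes_everything_to_root():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    tree = grow_tree(df, np.zeros(3), {"x": "numeric"})
    assert tree.n_subgroups == 1
    assert (predict_node(tree, df) == 1).all()


def test_json_round_trip():
    rng = np.random.default_rng(13)
    df = pd.DataFrame({"x": rng.normal(size=200),
                       "g": rng.choice(["u", "v"], 200)})
    y = np.where(df["g"] == "u", 1.0, -1.0) + rng.normal(0, 0.3, 200)
    tree = grow_tree(df, y, {"x": "numeric", "g": "categorical"})
    back = SubgroupTree.from_json(tree.to_json())
    np.testing.assert_array_equal(predict_node(tree, df), predict_node(back, df))
    assert back.to_json() == tree.to_json()
    assert tree.to_text()  # renders without error
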