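"""Conditional inference trees for subgroup discovery.

The learner recursively partitions a dataset by, at each node,

1. testing each candidate covariate for independence against the
   response with a permutation-based linear statistic (asymptotic
   chi-square reference; exact enumeration on tiny nodes),
2. Bonferroni-adjusting the per-variable p-values and stopping unless
   the smallest adjusted p-value is below ``alpha``, and
3. splitting the selected covariate at the cutpoint (or level subset)
   maximizing the standardized two-sample difference in mean response.

Separating variable selection (step 1-2) from cutpoint search (step 3)
avoids the variable-selection bias of exhaustive-search CART and gives
the tree a statistical stopping rule: under the null of no association
the probability of any split is approximately ``alpha``.

The response here is typically the matched-pair effect sign
``delta_g`` in {-1, 0, 1}, treated as numeric so the test targets a
mean shift in the treatment effect; a continuous response (e.g. a
model's per-participant effect estimate) works identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from scipy.stats import chi2

from .matching import AveragedDataset

__all__ = [
    "TreeParams",
    "Node",
    "SubgroupTree",
    "independence_test",
    "select_variable",
    "best_split",
    "grow",
    "grow_tree",
    "predict_node",
]

_EXACT_N = 10  # at or below this node size, enumerate permutations exactly
_MAX_EXACT_PERMS = 200_000
_MAX_CAT_LEVELS = 10


@dataclass(frozen=True)
class TreeParams:
    """Stopping and adjustment parameters for tree growth.

    alpha: significance level a Bonferroni-adjusted variable test must
        reach for a node to split.
    min_split: smallest node that is even considered for splitting.
    min_leaf: smallest admissible child node.
    adjust: multiplicity adjustment across candidate variables
        ("bonferroni" or "none").
    """

    alpha: float = 0.05
    min_split: int = 20
    min_leaf: int = 7
    adjust: str = "bonferroni"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.min_split < 2 * self.min_leaf:
            raise ValueError("min_split must be >= 2 * min_leaf")
        if self.adjust not in ("bonferroni", "none"):
            raise ValueError("adjust must be 'bonferroni' or 'none'")


# ---------------------------------------------------------------------------
# Independence test
# ---------------------------------------------------------------------------


def _influence_matrix(x: np.ndarray, kind: str) -> np.ndarray:
    """Map a covariate to its transformation g: identity column for
    numeric, one indicator column per observed level for categorical."""
    if kind == "numeric":
        return np.asarray(x, dtype=float)[:, None]
    levels = sorted(map(str, pd.unique(np.asarray(x, dtype=object))))
    xs = np.asarray(x).astype(str)
    return np.column_stack([(xs == lv).astype(float) for lv in levels])


def _linear_statistic_moments(g: np.ndarray, y: np.ndarray):
    """Observed statistic T = g'y with its conditional (permutation)
    mean and covariance, following the standardization of linear rank
    statistics."""
    n = len(y)
    ybar = y.mean()
    vh = ((y - ybar) ** 2).sum() / n
    gsum = g.sum(axis=0)
    t = g.T @ y
    mu = gsum * ybar
    sigma = (n / (n - 1)) * vh * (g.T @ g) - (1 / (n - 1)) * vh * np.outer(gsum, gsum)
    return t, mu, np.atleast_2d(sigma)


def _quadratic_form(t, mu, sigma):
    sig_pinv = pinvh(sigma)
    dev = t - mu
    c = float(dev @ sig_pinv @ dev)
    df = int(np.linalg.matrix_rank(sigma, hermitian=True))
    return max(c, 0.0), df, sig_pinv


def _multiset_permutations(values: np.ndarray) -> Iterator[tuple]:
    """Distinct permutations of a multiset, lexicographic order."""
    from itertools import permutations  # local: only tiny n reaches here

    counts: dict = {}
    for v in values.tolist():
        counts[v] = counts.get(v, 0) + 1
    keys = sorted(counts)
    n = len(values)
    out: list = []

    def rec(prefix: list) -> None:
        if len(prefix) == n:
            out.append(tuple(prefix))
            return
        for k in keys:
            if counts[k] > 0:
                counts[k] -= 1
                prefix.append(k)
                rec(prefix)
                prefix.pop()
                counts[k] += 1

    rec([])
    return iter(out)


def _n_distinct_perms(y: np.ndarray) -> int:
    _, counts = np.unique(y, return_counts=True)
    total = math.factorial(len(y))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def independence_test(x, y, kind: str = "numeric") -> tuple[float, float]:
    """Permutation test of independence between one covariate and the
    response; returns (chi-square-type statistic, p-value).

    A zero-variance covariate or response carries no information and
    yields p = 1.  For node sizes <= 10 the permutation distribution is
    enumerated exactly (over distinct rearrangements of y); larger nodes
    use the asymptotic chi-square reference with degrees of freedom
    equal to the rank of the conditional covariance.
    """
    x = np.asarray(x)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(x):
        raise ValueError("x and y must have equal length")
    if n < 2:
        return 0.0, 1.0
    if np.ptp(y) == 0:
        return 0.0, 1.0
    g = _influence_matrix(x, kind)
    if kind == "numeric" and np.ptp(g) == 0:
        return 0.0, 1.0
    if kind != "numeric" and g.shape[1] < 2:
        return 0.0, 1.0

    t, mu, sigma = _linear_statistic_moments(g, y)
    c, df, sig_pinv = _quadratic_form(t, mu, sigma)
    if df == 0:
        return 0.0, 1.0

    if n <= _EXACT_N and _n_distinct_perms(y) <= _MAX_EXACT_PERMS:
        perms = np.array(list(_multiset_permutations(y)), dtype=float)
        t_all = perms @ g  # (m, p)
        dev = t_all - mu
        c_all = np.einsum("ij,jk,ik->i", dev, sig_pinv, dev)
        p = float(np.mean(c_all >= c - 1e-9))
    else:
        p = float(chi2.sf(c, df))
    return c, p


# ---------------------------------------------------------------------------
# Variable selection and cutpoint search
# ---------------------------------------------------------------------------

STOP = None  # sentinel returned when no admissible split exists


def select_variable(
    node_data: pd.DataFrame,
    y: np.ndarray,
    candidates: list[str],
    kinds: dict[str, str],
    params: TreeParams,
):
    """Pick the covariate most associated with the response, or STOP.

    Returns ``(variable, adjusted_p)`` when the node is large enough and
    the smallest Bonferroni-adjusted p-value is <= alpha; ties keep the
    earliest candidate in schema order.
    """
    n = len(node_data)
    if n < params.min_split:
        return STOP
    k = len(candidates)
    best_var, best_p = None, np.inf
    for var in candidates:
        _, p = independence_test(node_data[var].to_numpy(), y, kinds[var])
        if params.adjust == "bonferroni":
            p = min(p * k, 1.0)
        if p < best_p:
            best_var, best_p = var, p
    if best_var is None or best_p > params.alpha:
        return STOP
    return best_var, best_p


def _two_sample_stat(t_left, n_left, n, ybar, ssy) -> np.ndarray:
    """|standardized| statistic for mean-response difference across an
    indicator split; vectorized over candidate splits."""
    var = ssy / (n * (n - 1)) * n_left * (n - n_left)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(t_left - n_left * ybar) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def best_split(x, y, kind: str, params: TreeParams):
    """Exhaustive cutpoint (numeric) or level-subset (categorical)
    search maximizing the standardized mean-difference statistic,
    honoring ``min_leaf``; returns a rule dict or STOP.

    Numeric rules are ``{"threshold": c}`` meaning "x <= c goes left",
    with c the midpoint between consecutive distinct observed values
    (ties on the statistic keep the smallest threshold).  Categorical
    rules are ``{"levels": (...)}``, the left child's level set
    (lexicographically first maximizer kept).
    """
    x = np.asarray(x)
    y = np.asarray(y, dtype=float)
    n = len(y)
    ybar = y.mean()
    ssy = ((y - ybar) ** 2).sum()
    if ssy == 0:
        return STOP

    if kind == "numeric":
        order = np.argsort(x, kind="mergesort")
        xs, ys = np.asarray(x, dtype=float)[order], y[order]
        csum = np.cumsum(ys)
        # admissible boundaries: between distinct x values, both children >= min_leaf
        k = np.arange(1, n)
        ok = (xs[1:] != xs[:-1]) & (k >= params.min_leaf) & (n - k >= params.min_leaf)
        if not ok.any():
            return STOP
        kk = k[ok]
        z = _two_sample_stat(csum[kk - 1], kk, n, ybar, ssy)
        best = int(np.argmax(z))  # argmax keeps first (= smallest threshold) on ties
        cut = kk[best]
        return {"threshold": float((xs[cut - 1] + xs[cut]) / 2.0)}

    xs = np.asarray(x).astype(str)
    levels = sorted(pd.unique(xs))
    nl = len(levels)
    if nl < 2:
        return STOP
    if nl > _MAX_CAT_LEVELS:
        raise ValueError(f"categorical split with {nl} levels refused (max {_MAX_CAT_LEVELS})")
    level_t = np.array([y[xs == lv].sum() for lv in levels])
    level_n = np.array([(xs == lv).sum() for lv in levels])
    best_rule, best_z = None, -np.inf
    # masks over sorted levels; excluding the last level from every subset
    # enumerates each binary partition exactly once, in lexicographic order
    for mask in range(1, 2 ** (nl - 1)):
        sel = [(mask >> i) & 1 == 1 for i in range(nl - 1)] + [False]
        n_left = int(level_n[sel].sum())
        if n_left < params.min_leaf or n - n_left < params.min_leaf:
            continue
        z = float(_two_sample_stat(level_t[sel].sum(), n_left, n, ybar, ssy))
        if z > best_z + 1e-12:
            best_z = z
            best_rule = {"levels": tuple(lv for lv, s in zip(levels, sel) if s)}
    return best_rule if best_rule is not None else STOP


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------


@dataclass
class Node:
    node_id: int
    depth: int
    n: int
    mean: float
    dist: dict[int, float] | None  # delta_g frequencies when response is in {-1,0,1}
    var: str | None = None
    kind: str | None = None
    threshold: float | None = None
    levels: tuple[str, ...] | None = None
    p_value: float | None = None  # adjusted selection p-value at this node
    left: int | None = None
    right: int | None = None

    @property
    def is_terminal(self) -> bool:
        return self.var is None

    def rule_str(self, negate: bool = False) -> str:
        if self.is_terminal:
            return ""
        if self.kind == "numeric":
            op = ">" if negate else "<="
            return f"{self.var} {op} {self.threshold:g}"
        levels = set(self.levels)
        if negate:
            return f"{self.var} not in {{{', '.join(sorted(levels))}}}"
        return f"{self.var} in {{{', '.join(sorted(levels))}}}"


@dataclass
class SubgroupTree:
    """A fitted recursive binary partition; node ids are depth-first
    preorder, the root is node 1."""

    nodes: dict[int, Node]
    params: TreeParams
    variables: list[str]
    kinds: dict[str, str]

    @property
    def root(self) -> Node:
        return self.nodes[1]

    @property
    def terminal_ids(self) -> list[int]:
        return [nid for nid, node in sorted(self.nodes.items()) if node.is_terminal]

    @property
    def n_subgroups(self) -> int:
        return len(self.terminal_ids)

    @property
    def split_variables(self) -> set[str]:
        return {n.var for n in self.nodes.values() if not n.is_terminal}

    def node_path(self, node_id: int) -> str:
        """Human-readable conjunction of rules from root to the node."""
        parents = {n.left: (nid, False) for nid, n in self.nodes.items() if n.left}
        parents.update({n.right: (nid, True) for nid, n in self.nodes.items() if n.right})
        parts: list[str] = []
        cur = node_id
        while cur in parents:
            pid, negate = parents[cur]
            parts.append(self.nodes[pid].rule_str(negate))
            cur = pid
        return " & ".join(reversed(parts)) if parts else "(all)"

    # -- serialization ------------------------------------------------------

    def to_text(self) -> str:
        lines: list[str] = []

        def walk(nid: int, indent: int, label: str) -> None:
            node = self.nodes[nid]
            head = f"[{nid}] {label}" if label else f"[{nid}]"
            if node.is_terminal:
                lines.append("  " * indent + f"{head} n={node.n} mean_delta={node.mean:.4f}")
            else:
                lines.append("  " * indent + f"{head} split {node.rule_str()} (p={node.p_value:.4g})")
                walk(node.left, indent + 1, node.rule_str())
                walk(node.right, indent + 1, node.rule_str(negate=True))

        walk(1, 0, "")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "params": vars(self.params).copy() if not isinstance(self.params, TreeParams)
            else {"alpha": self.params.alpha, "min_split": self.params.min_split,
                  "min_leaf": self.params.min_leaf, "adjust": self.params.adjust},
            "variables": self.variables,
            "kinds": self.kinds,
            "nodes": [
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(n).items()}
                for _, n in sorted(self.nodes.items())
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SubgroupTree":
        payload = json.loads(text)
        nodes = {}
        for nd in payload["nodes"]:
            nd = dict(nd)
            if nd.get("levels") is not None:
                nd["levels"] = tuple(nd["levels"])
            if nd.get("dist") is not None:
                nd["dist"] = {int(k): v for k, v in nd["dist"].items()}
            nodes[nd["node_id"]] = Node(**nd)
        return cls(nodes, TreeParams(**payload["params"]),
                   payload["variables"], payload["kinds"])


def _delta_dist(y: np.ndarray) -> dict[int, float] | None:
    vals = set(np.unique(y).tolist())
    if vals <= {-1.0, 0.0, 1.0}:
        return {k: float(np.mean(y == k)) for k in (-1, 0, 1)}
    return None


def grow_tree(
    x: pd.DataFrame,
    y: np.ndarray,
    kinds: dict[str, str],
    params: TreeParams | None = None,
    variables: list[str] | None = None,
) -> SubgroupTree:
    """Grow a conditional inference tree on an arbitrary frame/response.

    Growth is iterative (explicit stack) so deep trees on large inputs
    cannot hit the interpreter recursion limit; node ids are assigned in
    depth-first preorder.
    """
    params = params or TreeParams()
    variables = list(variables) if variables is not None else list(x.columns)
    y = np.asarray(y, dtype=float)
    nodes: dict[int, Node] = {}
    counter = {"next": 1}

    def new_node(idx: np.ndarray, depth: int) -> int:
        nid = counter["next"]
        counter["next"] += 1
        ys = y[idx]
        nodes[nid] = Node(nid, depth, len(idx), float(ys.mean()), _delta_dist(ys))
        return nid

    root_idx = np.arange(len(x))
    stack: list[tuple[int, np.ndarray]] = [(new_node(root_idx, 0), root_idx)]
    while stack:
        nid, idx = stack.pop()
        node = nodes[nid]
        sub = x.iloc[idx]
        ys = y[idx]
        sel = select_variable(sub, ys, variables, kinds, params)
        if sel is STOP:
            continue
        var, adj_p = sel
        rule = best_split(sub[var].to_numpy(), ys, kinds[var], params)
        if rule is STOP:
            continue
        if "threshold" in rule:
            left_mask = sub[var].to_numpy(dtype=float) <= rule["threshold"]
            node.kind = "numeric"
            node.threshold = rule["threshold"]
        else:
            left_mask = np.isin(sub[var].astype(str).to_numpy(), rule["levels"])
            node.kind = "categorical"
            node.levels = rule["levels"]
        node.var, node.p_value = var, adj_p
        left_idx, right_idx = idx[left_mask], idx[~left_mask]
        # preorder: materialize left subtree before right
        node.left = new_node(left_idx, node.depth + 1)
        left_entry = (node.left, left_idx)
        node.right = new_node(right_idx, node.depth + 1)
        stack.append((node.right, right_idx))
        stack.append(left_entry)
    # renumber preorder (creation order interleaves left/right ids)
    return _renumber_preorder(SubgroupTree(nodes, params, variables, kinds))


def _renumber_preorder(tree: SubgroupTree) -> SubgroupTree:
    mapping: dict[int, int] = {}
    order: list[int] = []

    def walk(nid: int) -> None:
        mapping[nid] = len(mapping) + 1
        order.append(nid)
        node = tree.nodes[nid]
        if not node.is_terminal:
            walk(node.left)
            walk(node.right)

    # root is always id 1 by construction
    walk(1)
    new_nodes = {}
    for old in order:
        node = tree.nodes[old]
        node.node_id = mapping[old]
        node.left = mapping[node.left] if node.left is not None else None
        node.right = mapping[node.right] if node.right is not None else None
        new_nodes[node.node_id] = node
    tree.nodes = new_nodes
    return tree


def grow(averaged: AveragedDataset, params: TreeParams | None = None) -> SubgroupTree:
    """Fit the subgroup tree to a pair-averaged dataset: response
    delta_g, predictors the averaged covariates."""
    if averaged.g2 == 0:
        raise ValueError("averaged dataset is empty")
    kinds = {c.name: ("categorical" if c.kind == "categorical" else "numeric")
             for c in averaged.covariates}
    x = averaged.data[averaged.covariate_names]
    y = averaged.data["delta_g"].to_numpy(dtype=float)
    return grow_tree(x, y, kinds, params, averaged.covariate_names)


def predict_node(tree: SubgroupTree, covariates: pd.DataFrame) -> np.ndarray:
    """Route rows down the tree; returns the terminal node id per row.

    The boundary convention is inclusive-left: ``x <= c`` routes left.
    """
    for var in tree.split_variables:
        if var not in covariates.columns:
            raise ValueError(f"covariate {var!r} required for routing is missing")
    n = len(covariates)
    out = np.full(n, -1, dtype=np.int64)
    stack = [(1, np.arange(n))]
    while stack:
        nid, idx = stack.pop()
        node = tree.nodes[nid]
        if node.is_terminal:
            out[idx] = nid
            continue
        col = covariates[node.var].iloc[idx]
        if node.kind == "numeric":
            left = col.to_numpy(dtype=float) <= node.threshold
        else:
            left = np.isin(col.astype(str).to_numpy(), node.levels)
        stack.append((node.left, idx[left]))
        stack.append((node.right, idx[~left]))
    return out
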