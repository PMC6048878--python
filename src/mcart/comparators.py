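"""Comparison strategies for HTE subgroup discovery.

These are the methods mCART is benchmarked against: per-participant
treatment-effect estimation (logistic regression with treatment
interactions and backward-AIC selection; random-forest prediction
differences; optionally an external gradient/causal forest) followed by
partitioning of the estimated effects into subgroups with a single
conditional inference tree.

Because these estimators build subgroups from modeled effects rather
than from covariate-matched pairs, nothing constrains treated and
control participants inside a discovered subgroup to look alike — the
covariate-imbalance failure mode the matched approach is designed to
avoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import matching
from .pipeline import effect_report
from .scenarios import TrialDataset
from .tree import SubgroupTree, TreeParams, grow_tree

__all__ = [
    "EffectEstimates",
    "lr_backward_aic",
    "partition_effects",
    "forest_effects",
    "register_forest_adapter",
]


@dataclass
class EffectEstimates:
    """Per-participant estimated treatment effects, in [-1, 1].

    ``status`` is "ok" or "skipped"; a skipped comparator (e.g. an
    unavailable external forest backend) carries no values but an
    explanatory message, so its absence is never silent.
    """

    values: np.ndarray | None
    method: str
    status: str = "ok"
    message: str = ""

    def __post_init__(self) -> None:
        if self.status == "ok":
            v = np.asarray(self.values, dtype=float)
            if np.any(np.abs(v) > 1 + 1e-9):
                raise ValueError("effect estimates must lie in [-1, 1]")
            self.values = v


# ---------------------------------------------------------------------------
# Logistic regression with backward AIC
# ---------------------------------------------------------------------------


def _design(enc: matching.EncodedCovariates, z: np.ndarray, terms: list[str],
            var_cols: dict[str, list[int]]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(z))]
    names = ["const"]
    for term in terms:
        if term == "Z":
            cols.append(z.astype(float))
            names.append("Z")
        elif term.startswith("Z:"):
            var = term[2:]
            for j in var_cols[var]:
                cols.append(z * enc.matrix[:, j])
                names.append(f"Z:{enc.columns[j]}")
        else:
            for j in var_cols[term]:
                cols.append(enc.matrix[:, j])
                names.append(enc.columns[j])
    return np.column_stack(cols), names


def _fit_logit(x: np.ndarray, y: np.ndarray):
    try:
        res = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation / non-convergence
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge")
    return res


def lr_backward_aic(trial: TrialDataset, return_model: bool = False):
    """Backward-AIC logistic model of the outcome with treatment
    interactions, then per-participant effects p1 - p0.

    The initial model holds all covariate main effects, the treatment
    indicator, and every treatment-by-covariate interaction.  At each
    step the single term whose removal most decreases the AIC is
    dropped; hierarchy is respected (a main effect is only removable
    after its interaction, the treatment term only after all
    interactions).  Elimination stops when no removal decreases AIC.
    """
    enc = matching.encode(trial)
    var_cols: dict[str, list[int]] = {}
    for j, col in enumerate(enc.columns):
        var_cols.setdefault(enc.source[col], []).append(j)
    z = trial.data["Z"].to_numpy(dtype=float)
    y = trial.data["Y"].to_numpy(dtype=float)

    variables = list(var_cols)
    terms = variables + ["Z"] + [f"Z:{v}" for v in variables]
    x, _ = _design(enc, z, terms, var_cols)
    res = _fit_logit(x, y)
    current_aic = res.aic
    aic_path = [current_aic]

    while True:
        has_inter = any(t.startswith("Z:") for t in terms)
        removable = []
        for t in terms:
            if t.startswith("Z:"):
                removable.append(t)
            elif t == "Z":
                if not has_inter:
                    removable.append(t)
            elif f"Z:{t}" not in terms:
                removable.append(t)
        best_term, best_aic = None, current_aic
        for t in removable:
            trial_terms = [u for u in terms if u != t]
            if trial_terms:
                x_try, _ = _design(enc, z, trial_terms, var_cols)
            else:
                x_try = np.ones((len(y), 1))
            aic = _fit_logit(x_try, y).aic
            if aic < best_aic - 1e-9:
                best_term, best_aic = t, aic
        if best_term is None:
            break
        terms = [u for u in terms if u != best_term]
        current_aic = best_aic
        aic_path.append(current_aic)

    x_final, names = _design(enc, z, terms, var_cols)
    res = _fit_logit(x_final, y)
    x1, _ = _design(enc, np.ones_like(z), terms, var_cols)
    x0, _ = _design(enc, np.zeros_like(z), terms, var_cols)
    effects = res.predict(x1) - res.predict(x0)
    est = EffectEstimates(effects, "lr")
    if return_model:
        return est, {"terms": terms, "names": names, "aic_path": aic_path,
                     "result": res}
    return est


# ---------------------------------------------------------------------------
# Partitioning estimated effects into subgroups
# ---------------------------------------------------------------------------


def partition_effects(
    effects: EffectEstimates,
    trial: TrialDataset,
    params: TreeParams | None = None,
) -> tuple[SubgroupTree, pd.DataFrame]:
    """Split the per-participant effect estimates into subgroups with a
    single conditional inference tree over the covariates, and report
    per-node risk differences, balance, and (when truth is attached)
    bias — the same report schema the matched pipeline produces."""
    if effects.status != "ok":
        raise ValueError(f"comparator {effects.method!r} was skipped: {effects.message}")
    if len(effects.values) != trial.n:
        raise ValueError("effects are not aligned with the trial rows")
    kinds = {c.name: ("categorical" if c.kind == "categorical" else "numeric")
             for c in trial.covariates}
    tree = grow_tree(trial.covariate_frame, effects.values, kinds,
                     params or TreeParams(), trial.covariate_names)
    return tree, effect_report(tree, trial)


# ---------------------------------------------------------------------------
# Forest-based effect estimators (adapters)
# ---------------------------------------------------------------------------

_FOREST_ADAPTERS: dict[str, Callable[[TrialDataset, int], np.ndarray]] = {}


def register_forest_adapter(name: str,
                            fn: Callable[[TrialDataset, int], np.ndarray]) -> None:
    """Register an external effect estimator, e.g. a gradient-forest
    backend; ``fn(trial, seed) -> effects`` in [-1, 1] per participant."""
    _FOREST_ADAPTERS[name] = fn


def _rf_effects(trial: TrialDataset, seed: int) -> np.ndarray:
    from sklearn.ensemble import RandomForestClassifier

    enc = matching.encode(trial)
    z = trial.data["Z"].to_numpy(dtype=float)
    y = trial.data["Y"].to_numpy()
    x = np.column_stack([enc.matrix, z])
    if len(np.unique(y)) < 2:
        return np.zeros(trial.n)
    clf = RandomForestClassifier(n_estimators=500, max_features="sqrt",
                                 random_state=seed)
    clf.fit(x, y)
    x1 = np.column_stack([enc.matrix, np.ones(trial.n)])
    x0 = np.column_stack([enc.matrix, np.zeros(trial.n)])
    return clf.predict(x1).astype(float) - clf.predict(x0).astype(float)


_FOREST_ADAPTERS["rf"] = _rf_effects


def forest_effects(trial: TrialDataset, method: str = "rf",
                   seed: int = 0) -> EffectEstimates:
    """Forest-based per-participant effects.

    ``rf``: a 500-tree majority-vote classification forest on
    (covariates, Z); the effect is the difference of predicted classes
    with Z forced to 1 and to 0, in {-1, 0, 1}.  ``gradient_rf`` is an
    adapter slot for an external honest/gradient forest implementation;
    with no backend registered the comparator is reported as skipped.
    """
    if method not in ("rf", "gradient_rf"):
        raise ValueError(f"unknown forest method {method!r}")
    fn = _FOREST_ADAPTERS.get(method)
    if fn is None:
        return EffectEstimates(None, method, status="skipped",
                               message=f"no {method!r} backend registered")
    return EffectEstimates(fn(trial, seed), method)
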