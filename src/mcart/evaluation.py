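"""Covariate-balance and accuracy metrics for discovered subgroups.

Balance between arms is summarized by absolute standardized differences
(ASDs): the absolute difference of group means (or proportions) scaled
by the pooled standard deviation.  A subgroup is deemed acceptably
balanced when all of its covariate ASDs fall below 0.2, the conventional
small-effect-size cutoff.  Accuracy against simulated ground truth is
measured by bias: the subgroup's estimated risk difference minus the
mean of the true individual effects (delta) of its members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .scenarios import TrialDataset

__all__ = [
    "asd_continuous",
    "asd_proportion",
    "covariate_asds",
    "balance_table",
    "baseline_table",
    "risk_difference_ci",
    "required_sample_size",
    "subgroup_bias",
    "summary_table",
    "BALANCE_CUTOFF",
]

BALANCE_CUTOFF = 0.2


def asd_continuous(treated_values, control_values) -> float:
    """|mean_t - mean_c| / sqrt((var_t + var_c) / 2), sample variances.

    Degenerate case: equal constant groups give 0; unequal constants
    give +inf (flagged to the caller by the value itself).
    """
    t = np.asarray(treated_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise ValueError("need at least two values per group")
    pooled = math.sqrt((t.var(ddof=1) + c.var(ddof=1)) / 2.0)
    diff = abs(t.mean() - c.mean())
    if pooled == 0:
        return 0.0 if diff == 0 else math.inf
    return diff / pooled


def asd_proportion(p_t: float, p_c: float) -> float:
    """|p_t - p_c| / sqrt((p_t(1-p_t) + p_c(1-p_c)) / 2)."""
    if not (0 <= p_t <= 1 and 0 <= p_c <= 1):
        raise ValueError("proportions must be in [0, 1]")
    pooled = math.sqrt((p_t * (1 - p_t) + p_c * (1 - p_c)) / 2.0)
    diff = abs(p_t - p_c)
    if pooled == 0:
        return 0.0 if diff == 0 else math.inf
    return diff / pooled


def covariate_asds(trial: TrialDataset, treated_mask, control_mask=None) -> pd.DataFrame:
    """Per-covariate (and per-level, for categoricals) ASD between arms.

    Returns a frame with columns (covariate, level, asd); a multi-level
    categorical contributes one row per level, and its variable-level
    summary for the balance verdict is the maximum over levels.
    """
    treated_mask = np.asarray(treated_mask, dtype=bool)
    control_mask = (~treated_mask if control_mask is None
                    else np.asarray(control_mask, dtype=bool))
    rows = []
    for cov in trial.covariates:
        col = trial.data[cov.name]
        if cov.kind == "continuous":
            rows.append((cov.name, "", asd_continuous(col[treated_mask], col[control_mask])))
        elif cov.kind == "binary":
            rows.append((cov.name, "",
                         asd_proportion(float(col[treated_mask].mean()),
                                        float(col[control_mask].mean()))))
        else:
            xs = col.astype(str)
            for lv in sorted(xs.unique()):
                rows.append((cov.name, lv,
                             asd_proportion(float((xs[treated_mask] == lv).mean()),
                                            float((xs[control_mask] == lv).mean()))))
    return pd.DataFrame(rows, columns=["covariate", "level", "asd"])


def balance_table(trial: TrialDataset, node_ids: np.ndarray,
                  cutoff: float = BALANCE_CUTOFF) -> pd.DataFrame:
    """Per-subgroup balance: max ASD over covariates and the verdict.

    ``node_ids`` assigns every trial participant to a subgroup (terminal
    node).  A node with an empty arm gets max_asd = NaN and verdict
    False (flagged, not dropped).
    """
    z = trial.data["Z"].to_numpy()
    out = []
    for nid in sorted(pd.unique(node_ids)):
        in_node = node_ids == nid
        t_mask = in_node & (z == 1)
        c_mask = in_node & (z == 0)
        if t_mask.sum() < 2 or c_mask.sum() < 2:
            out.append((nid, int(in_node.sum()), math.nan, False))
            continue
        asds = covariate_asds(trial, t_mask, c_mask)
        mx = float(asds["asd"].max())
        out.append((nid, int(in_node.sum()), mx, bool(mx < cutoff)))
    return pd.DataFrame(out, columns=["node_id", "n", "max_asd", "balanced"])


def baseline_table(trial: TrialDataset) -> pd.DataFrame:
    """Whole-trial characteristics-at-randomization table: per-arm
    summaries (mean +/- SD for continuous, count (%) for levels) and the
    between-arm ASD."""
    z = trial.data["Z"].to_numpy()
    t_mask, c_mask = z == 1, z == 0
    asds = covariate_asds(trial, t_mask, c_mask)
    rows = []
    for cov in trial.covariates:
        col = trial.data[cov.name]
        if cov.kind == "continuous":
            s_t = f"{col[t_mask].mean():.1f} (±{col[t_mask].std(ddof=1):.1f})"
            s_c = f"{col[c_mask].mean():.1f} (±{col[c_mask].std(ddof=1):.1f})"
            a = asds.query("covariate == @cov.name")["asd"].iloc[0]
            rows.append((cov.name, "", s_c, s_t, round(float(a), 2)))
        else:
            xs = col.astype(str) if cov.kind == "categorical" else col.map({0: "No", 1: "Yes"})
            for lv in sorted(xs.unique()):
                n_t, n_c = int((xs[t_mask] == lv).sum()), int((xs[c_mask] == lv).sum())
                s_t = f"{n_t} ({100 * n_t / t_mask.sum():.1f}%)"
                s_c = f"{n_c} ({100 * n_c / c_mask.sum():.1f}%)"
                sel = asds.query("covariate == @cov.name")
                a = (sel[sel["level"] == lv]["asd"].iloc[0] if cov.kind == "categorical"
                     else sel["asd"].iloc[0])
                rows.append((cov.name, lv, s_c, s_t, round(float(a), 2)))
    return pd.DataFrame(rows, columns=["covariate", "level", "control", "treated", "asd"])


# ---------------------------------------------------------------------------
# Risk differences, bias, design
# ---------------------------------------------------------------------------


def risk_difference_ci(events_t: int, n_t: int, events_c: int, n_c: int,
                       level: float = 0.95, cc: bool = True):
    """Risk difference with a normal-approximation confidence interval.

    With ``cc=True`` (default) the half-width carries the Yates
    continuity correction (1/n_t + 1/n_c)/2, matching R's ``prop.test``;
    ``cc=False`` gives the plain Wald interval.
    """
    if n_t <= 0 or n_c <= 0:
        raise ValueError("group sizes must be positive")
    if events_t > n_t or events_c > n_c:
        raise ValueError("event counts cannot exceed group sizes")
    p_t, p_c = events_t / n_t, events_c / n_c
    rd = p_t - p_c
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(p_t * (1 - p_t) / n_t + p_c * (1 - p_c) / n_c)
    if cc:
        half += (1.0 / n_t + 1.0 / n_c) / 2.0
    return rd, rd - half, rd + half


def required_sample_size(p0: float, p1: float, alpha: float = 0.05,
                         power: float = 0.80) -> int:
    """Per-group n for a two-sided two-proportion comparison.

    Pooled-variance normal approximation, no continuity correction:
    n = (z_{a/2} sqrt(2 pbar qbar) + z_b sqrt(p0 q0 + p1 q1))^2 / (p0-p1)^2,
    rounded up.
    """
    if not (0 < p0 < 1 and 0 < p1 < 1):
        raise ValueError("proportions must be in (0, 1)")
    if p0 == p1:
        raise ValueError("effect size is zero")
    za, zb = norm.ppf(1 - alpha / 2.0), norm.ppf(power)
    pbar = (p0 + p1) / 2.0
    num = za * math.sqrt(2 * pbar * (1 - pbar)) + zb * math.sqrt(p0 * (1 - p0) + p1 * (1 - p1))
    return math.ceil((num / (p0 - p1)) ** 2)


def subgroup_bias(report: pd.DataFrame, truth: pd.DataFrame,
                  node_ids: np.ndarray) -> pd.Series:
    """bias(node) = estimated RD - mean true delta of node members."""
    delta = truth["delta"].to_numpy(dtype=float)
    true_ate = {nid: float(delta[node_ids == nid].mean())
                for nid in pd.unique(node_ids)}
    return report.apply(
        lambda r: r["rd"] - true_ate[r["node_id"]] if not math.isnan(r["rd"]) else math.nan,
        axis=1)


def summary_table(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Tidy (method, node, max_asd, |bias|) rows — the balance-vs-bias
    scatter data.  ``reports`` maps method name -> subgroup report with
    columns node_id, max_asd, bias."""
    rows = []
    for method, rep in reports.items():
        for _, r in rep.iterrows():
            rows.append((method, r["node_id"], r["max_asd"], abs(r["bias"])))
    return pd.DataFrame(rows, columns=["method", "node_id", "max_asd", "abs_bias"])
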