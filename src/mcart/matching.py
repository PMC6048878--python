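"""Treated-control pair matching on rank-based Mahalanobis distance.

The matching stage turns a randomized trial into a set of disjoint
treated-control pairs that are close on the chosen prognostic
covariates, then discards any pair that disagrees on a categorical
covariate, and finally collapses each surviving pair into a single
pseudo-observation: the pair's treatment-effect sign
``delta_g = Y_treated - Y_control`` together with the pair-averaged
covariate vector.  The averaged dataset is what the subgroup tree is
grown on.

Distances follow Rosenbaum's rank-based Mahalanobis construction: each
encoded covariate column is replaced by its within-sample ranks
(average ranks for ties), and the Mahalanobis metric is taken with
respect to the covariance of the ranked columns.  Ranking makes the
metric invariant to monotone transforms of continuous covariates and
robust to outliers.  Pairing is the optimal bipartite assignment
minimizing the total matched distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .scenarios import Covariate, TrialDataset

__all__ = [
    "EncodedCovariates",
    "DistanceMatrix",
    "MatchedPair",
    "MatchedPairSet",
    "AveragedDataset",
    "encode",
    "rank_mahalanobis",
    "pair_match",
    "greedy_pair_match",
    "filter_exact_categorical",
    "build_averaged",
]


@dataclass
class EncodedCovariates:
    """Numeric design matrix for the distance: continuous as-is, binary
    0/1, categorical as L-1 indicators (lexicographically first level is
    the dropped reference)."""

    matrix: np.ndarray  # N x M
    columns: list[str]
    source: dict[str, str]  # encoded column -> source variable

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DistanceMatrix:
    """Distances oriented smaller arm (rows) x larger arm (columns).

    ``row_index``/``col_index`` map back to positions in the trial;
    ``rows_are_treated`` records the orientation.
    """

    values: np.ndarray
    row_index: np.ndarray
    col_index: np.ndarray
    rows_are_treated: bool


@dataclass(frozen=True)
class MatchedPair:
    treated: int  # positional index into the trial
    control: int
    distance: float


@dataclass
class MatchedPairSet:
    """Disjoint treated-control pairs; G before and G2 after filtering."""

    pairs: list[MatchedPair]
    g: int  # pair count before the exact-categorical filter
    discarded: list[tuple[MatchedPair, str]] = field(default_factory=list)

    @property
    def g2(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i, p.treated, p.control, p.distance) for i, p in enumerate(self.pairs)],
            columns=["pair_id", "treated_id", "control_id", "distance"],
        )

    def discarded_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.treated, p.control, p.distance, reason) for p, reason in self.discarded],
            columns=["treated_id", "control_id", "distance", "reason"],
        )


@dataclass
class AveragedDataset:
    """One row per retained pair: delta_g plus averaged covariates.

    Continuous covariates are the pair mean; binary and categorical
    covariates are the shared value (equal within each pair once the
    exact filter has run).
    """

    data: pd.DataFrame  # columns: covariates + delta_g
    covariates: tuple[Covariate, ...]
    pair_ids: list[tuple[int, int]]  # (treated, control) positional ids

    @property
    def g2(self) -> int:
        return len(self.data)

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]


# ---------------------------------------------------------------------------


def encode(trial: TrialDataset, prognostic_vars: list[str] | None = None) -> EncodedCovariates:
    """Encode the prognostic covariates into a numeric matrix.

    Missing values are an input error (the method has no missing-data
    handling by contract), as is an unknown variable name.
    """
    if prognostic_vars is None:
        prognostic_vars = trial.covariate_names
    known = set(trial.covariate_names)
    for v in prognostic_vars:
        if v not in known:
            raise ValueError(f"unknown prognostic variable {v!r}")
        if trial.data[v].isna().any():
            raise ValueError(f"missing values in covariate {v!r}")

    blocks, names, source = [], [], {}
    for v in prognostic_vars:
        kind = trial.kind_of(v)
        col = trial.data[v]
        if kind in ("continuous", "binary"):
            blocks.append(col.to_numpy(dtype=float)[:, None])
            names.append(v)
            source[v] = v
        else:
            levels = sorted(map(str, col.astype(str).unique()))
            for lv in levels[1:]:  # reference = lexicographically first
                blocks.append((col.astype(str) == lv).to_numpy(dtype=float)[:, None])
                cname = f"{v}[{lv}]"
                names.append(cname)
                source[cname] = v
    return EncodedCovariates(np.hstack(blocks), names, source)


def rank_mahalanobis(enc: EncodedCovariates, treated_mask: np.ndarray) -> DistanceMatrix:
    """Rank-based Mahalanobis distances between the two arms.

    Every encoded column (indicators included) is ranked over all N
    participants with average ranks for ties; S is the sample covariance
    of the ranked columns, inverted by Moore-Penrose pseudo-inverse so
    collinear indicator blocks in small trials do not break the metric.
    Zero-variance columns are dropped with a warning.
    """
    treated_mask = np.asarray(treated_mask, dtype=bool)
    n_t = int(treated_mask.sum())
    n_c = int((~treated_mask).sum())
    if n_t == 0 or n_c == 0:
        raise ValueError("both arms must be non-empty")

    ranks = np.column_stack([rankdata(col) for col in enc.matrix.T])
    keep = ranks.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(enc.columns, keep) if not k]
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
        ranks = ranks[:, keep]
    if ranks.shape[1] == 0:
        raise ValueError("no informative covariate columns remain")

    s = np.cov(ranks, rowvar=False)
    s = np.atleast_2d(s)
    vi = pinvh(s)

    t_idx = np.flatnonzero(treated_mask)
    c_idx = np.flatnonzero(~treated_mask)
    if n_t <= n_c:
        row_index, col_index, rows_are_treated = t_idx, c_idx, True
    else:
        row_index, col_index, rows_are_treated = c_idx, t_idx, False
    d = cdist(ranks[row_index], ranks[col_index], metric="mahalanobis", VI=vi)
    # guard tiny negative round-off inside the sqrt
    d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(d, row_index, col_index, rows_are_treated)


def pair_match(d: DistanceMatrix) -> MatchedPairSet:
    """Optimal pair matching: min(C, T) disjoint pairs minimizing the
    total matched distance (linear-sum assignment)."""
    if d.values.size == 0:
        raise ValueError("empty distance matrix")
    rows, cols = linear_sum_assignment(d.values)
    return _pairs_from_assignment(d, rows, cols)


def greedy_pair_match(d: DistanceMatrix) -> MatchedPairSet:
    """Greedy nearest-neighbor alternative (sensitivity analysis only):
    repeatedly take the globally smallest remaining distance."""
    if d.values.size == 0:
        raise ValueError("empty distance matrix")
    v = d.values.copy()
    rows, cols = [], []
    for _ in range(min(v.shape)):
        i, j = np.unravel_index(np.argmin(v), v.shape)
        rows.append(i)
        cols.append(j)
        v[i, :] = np.inf
        v[:, j] = np.inf
    order = np.argsort(rows)
    return _pairs_from_assignment(d, np.asarray(rows)[order], np.asarray(cols)[order])


def _pairs_from_assignment(d: DistanceMatrix, rows, cols) -> MatchedPairSet:
    pairs = []
    for i, j in zip(rows, cols):
        a, b = int(d.row_index[i]), int(d.col_index[j])
        t, c = (a, b) if d.rows_are_treated else (b, a)
        pairs.append(MatchedPair(t, c, float(d.values[i, j])))
    pairs.sort(key=lambda p: (p.treated, p.control))
    return MatchedPairSet(pairs, g=len(pairs))


def filter_exact_categorical(
    pairs: MatchedPairSet, trial: TrialDataset, categorical_vars: list[str]
) -> MatchedPairSet:
    """Discard any pair whose members disagree on a listed categorical
    (or binary) covariate; the first mismatching variable is recorded as
    the discard reason."""
    known = set(trial.covariate_names)
    for v in categorical_vars:
        if v not in known:
            raise ValueError(f"unknown categorical variable {v!r}")
    cols = {v: trial.data[v].to_numpy() for v in categorical_vars}
    kept, discarded = [], list(pairs.discarded)
    for p in pairs.pairs:
        reason = None
        for v in categorical_vars:
            if cols[v][p.treated] != cols[v][p.control]:
                reason = v
                break
        if reason is None:
            kept.append(p)
        else:
            discarded.append((p, reason))
    return MatchedPairSet(kept, g=pairs.g, discarded=discarded)


def build_averaged(pairs: MatchedPairSet, trial: TrialDataset,
                   covariates: tuple[Covariate, ...] | None = None) -> AveragedDataset:
    """Collapse pairs: delta_g = Y_t - Y_c, covariates pair-averaged.

    Non-continuous covariates must be equal within every pair (run the
    exact filter first); averaging unequal categorical values is refused
    rather than guessed at.  ``covariates`` restricts the averaged frame
    to a subset (default: all trial covariates).
    """
    if pairs.g2 == 0:
        raise ValueError("no pairs survive exact filter")
    if covariates is None:
        covariates = trial.covariates
    t_idx = [p.treated for p in pairs.pairs]
    c_idx = [p.control for p in pairs.pairs]
    y = trial.data["Y"].to_numpy()
    out: dict[str, np.ndarray | pd.Series] = {}
    for cov in covariates:
        col = trial.data[cov.name]
        if cov.kind == "continuous":
            vals = col.to_numpy(dtype=float)
            out[cov.name] = (vals[t_idx] + vals[c_idx]) / 2.0
        else:
            vt, vc = col.iloc[t_idx].to_numpy(), col.iloc[c_idx].to_numpy()
            if (vt != vc).any():
                bad = int(np.flatnonzero(vt != vc)[0])
                raise ValueError(
                    f"pair {bad} disagrees on {cov.name!r}; run "
                    "filter_exact_categorical before averaging")
            out[cov.name] = col.iloc[t_idx].reset_index(drop=True)
    df = pd.DataFrame(out)
    df["delta_g"] = y[t_idx] - y[c_idx]
    return AveragedDataset(df, tuple(covariates), list(zip(t_idx, c_idx)))
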