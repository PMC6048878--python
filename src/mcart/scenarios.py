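"""Simulated two-arm randomized trials with known treatment-effect heterogeneity.

Five study designs are bundled, spanning two clinical settings:

* an N = 200 phase II oncology trial (scenarios ``1A``, ``1B``), and
* an N = 6000 phase III cardiovascular-disease (CVD) trial (scenarios
  ``2A``, ``2B``, ``2C``).

Each participant carries a pair of binary potential outcomes ``(Y1, Y0)``
(the adverse event under treatment and under control) whose difference
``delta = Y1 - Y0`` takes values in {-1, 0, 1}: -1 benefit, 0 no effect,
1 harm.  ``delta`` is drawn from a multinomial whose probabilities depend
on the covariate-defined subgroup the participant falls in; scenarios 1A
and 2A are null designs (one multinomial for everyone, no heterogeneity),
while 1B splits on age and 2B/2C split on aspirin use crossed with
kidney function (eGFR above/below 72 ml/min/1.73 m^2).

The simulator attaches the full potential-outcome table, so downstream
evaluation can compute true subgroup effects and the bias of any
estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Covariate",
    "Condition",
    "SubgroupRule",
    "ScenarioSpec",
    "TrialDataset",
    "SCENARIO_IDS",
    "make_scenario",
    "simulate_trial",
    "expected_subgroup_ate",
]

SCENARIO_IDS = ("1A", "1B", "2A", "2B", "2C")


@dataclass(frozen=True)
class Covariate:
    """One baseline variable and its sampling distribution.

    kind:
        ``continuous`` — normal with ``params = (mean, sd)``;
        ``binary``     — Bernoulli with ``params = (p,)``, encoded 0/1;
        ``categorical``— multinomial over ``levels`` with ``params`` the
        level probabilities (same order).
    """

    name: str
    kind: str
    params: tuple[float, ...]
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if self.levels is None or len(self.levels) != len(self.params):
                raise ValueError(f"{self.name}: levels/probabilities mismatch")
            if abs(sum(self.params) - 1.0) > 1e-12:
                raise ValueError(f"{self.name}: level probabilities must sum to 1")


# A condition is (variable, operator, value); operators are the ones the
# subgroup definitions need.
_OPS = {
    "<=": lambda s, v: s <= v,
    ">": lambda s, v: s > v,
    "==": lambda s, v: s == v,
    "!=": lambda s, v: s != v,
}

Condition = tuple[str, str, float | str]


@dataclass(frozen=True)
class SubgroupRule:
    """A named region of covariate space with its delta multinomial.

    ``probs`` is (P[delta=-1], P[delta=0], P[delta=1]).  An empty
    ``conditions`` list matches every participant (the null designs).
    """

    name: str
    conditions: tuple[Condition, ...]
    probs: tuple[float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError(f"subgroup {self.name!r}: multinomial must sum to 1")
        for _, op, _ in self.conditions:
            if op not in _OPS:
                raise ValueError(f"unknown operator {op!r}")

    def mask(self, covariates: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(covariates), dtype=bool)
        for var, op, val in self.conditions:
            m &= _OPS[op](covariates[var], val).to_numpy()
        return m

    @property
    def expected_delta(self) -> float:
        return self.probs[2] - self.probs[0]


@dataclass(frozen=True)
class ScenarioSpec:
    """Full generative specification of one simulated trial design."""

    scenario_id: str
    n_total: int
    covariates: tuple[Covariate, ...]
    delta_model: tuple[SubgroupRule, ...]
    zero_delta_outcome: int  # value of Y1 = Y0 when delta = 0
    has_hte: bool  # whether the design contains true HTE subgroups

    def __post_init__(self) -> None:
        if self.n_total % 2 != 0:
            raise ValueError("n_total must be even (1:1 allocation)")
        if self.zero_delta_outcome not in (0, 1):
            raise ValueError("zero_delta_outcome must be 0 or 1")

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]

    @property
    def true_subgroup_rule(self) -> tuple[SubgroupRule, ...]:
        """The ground-truth subgroups; empty for the no-HTE designs."""
        return self.delta_model if self.has_hte else ()


@dataclass
class TrialDataset:
    """One simulated (or observed) two-arm trial.

    ``data`` holds the covariates plus ``Z`` (1 = treated) and ``Y``
    (1 = event).  ``truth``, present for simulated trials, holds the
    hidden columns ``Y1, Y0, delta, true_subgroup``.
    """

    data: pd.DataFrame
    covariates: tuple[Covariate, ...]
    truth: pd.DataFrame | None = None
    scenario_id: str | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]

    @property
    def covariate_frame(self) -> pd.DataFrame:
        return self.data[self.covariate_names]

    def kind_of(self, name: str) -> str:
        for c in self.covariates:
            if c.name == name:
                return c.kind
        raise KeyError(name)


# ---------------------------------------------------------------------------
# The five bundled designs
# ---------------------------------------------------------------------------

_ONCOLOGY = (
    Covariate("age", "continuous", (65.0, 5.0)),
    Covariate("stage4", "binary", (0.98,)),
    Covariate("site", "categorical", (0.5, 0.17, 0.33),
              ("visceral", "bone_only", "other")),
    Covariate("prev_treatment", "categorical", (0.5, 0.2, 0.2, 0.1),
              ("none", "chemo_only", "hormonal_only", "chemo_hormonal")),
    Covariate("ecog", "binary", (0.55,)),
    Covariate("disease_free_gt12", "binary", (0.35,)),
)

_CVD = (
    Covariate("age", "continuous", (68.0, 10.0)),
    Covariate("black_race", "binary", (0.3,)),
    Covariate("sbp", "continuous", (140.0, 15.0)),
    Covariate("dbp", "continuous", (78.0, 12.0)),
    Covariate("creatinine", "continuous", (1.07, 0.34)),
    Covariate("egfr", "continuous", (72.0, 20.0)),
    Covariate("statin", "binary", (0.43,)),
    Covariate("aspirin", "binary", (0.51,)),
    Covariate("framingham", "continuous", (25.0, 12.0)),
    Covariate("smoking", "categorical", (0.44, 0.42, 0.14),
              ("never", "former", "current")),
)

_ASPIRIN_EGFR_CELLS = (
    ("aspirin & eGFR<=72", (("aspirin", "==", 1), ("egfr", "<=", 72.0))),
    ("aspirin & eGFR>72", (("aspirin", "==", 1), ("egfr", ">", 72.0))),
    ("no aspirin & eGFR<=72", (("aspirin", "==", 0), ("egfr", "<=", 72.0))),
    ("no aspirin & eGFR>72", (("aspirin", "==", 0), ("egfr", ">", 72.0))),
)


def make_scenario(scenario_id: str) -> ScenarioSpec:
    """Return the generative specification for one of the five designs."""
    sid = str(scenario_id).upper()
    if sid == "1A":
        model = (SubgroupRule("all", (), (0.5, 0.2, 0.3)),)
        return ScenarioSpec("1A", 200, _ONCOLOGY, model, 1, has_hte=False)
    if sid == "1B":
        model = (
            SubgroupRule("age<=65", (("age", "<=", 65.0),), (0.6, 0.2, 0.2)),
            SubgroupRule("age>65", (("age", ">", 65.0),), (0.4, 0.2, 0.4)),
        )
        return ScenarioSpec("1B", 200, _ONCOLOGY, model, 1, has_hte=True)
    if sid == "2A":
        model = (SubgroupRule("all", (), (0.068, 0.88, 0.052)),)
        return ScenarioSpec("2A", 6000, _CVD, model, 0, has_hte=False)
    if sid == "2B":
        probs = ((0.06, 0.88, 0.06), (0.012, 0.88, 0.108),
                 (0.116, 0.88, 0.004), (0.084, 0.88, 0.036))
        model = tuple(SubgroupRule(name, cond, p)
                      for (name, cond), p in zip(_ASPIRIN_EGFR_CELLS, probs))
        return ScenarioSpec("2B", 6000, _CVD, model, 0, has_hte=True)
    if sid == "2C":
        probs = ((0.036, 0.88, 0.084), (0.004, 0.88, 0.116),
                 (0.116, 0.88, 0.004), (0.084, 0.88, 0.036))
        model = tuple(SubgroupRule(name, cond, p)
                      for (name, cond), p in zip(_ASPIRIN_EGFR_CELLS, probs))
        return ScenarioSpec("2C", 6000, _CVD, model, 0, has_hte=True)
    raise ValueError(f"unknown scenario {scenario_id!r}; expected one of {SCENARIO_IDS}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _draw_covariates(spec: ScenarioSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the baseline table column-by-column in schema order.

    The fixed draw order (each column fully drawn before the next, then
    delta, then the arm permutation) makes a seed reproducible across
    runs; the generator is numpy's PCG64 ``default_rng``.
    """
    n = spec.n_total
    cols: dict[str, np.ndarray | pd.Series] = {}
    for cov in spec.covariates:
        if cov.kind == "continuous":
            mean, sd = cov.params
            cols[cov.name] = rng.normal(mean, sd, size=n)
        elif cov.kind == "binary":
            cols[cov.name] = (rng.random(n) < cov.params[0]).astype(np.int64)
        else:
            idx = rng.choice(len(cov.params), size=n, p=np.asarray(cov.params))
            cols[cov.name] = pd.Categorical.from_codes(idx, categories=list(cov.levels))
    return pd.DataFrame(cols)


def simulate_trial(spec: ScenarioSpec, seed: int) -> TrialDataset:
    """Simulate one randomized trial under ``spec``; deterministic in ``seed``.

    Covariates are drawn first, then each participant's ``delta`` from
    the multinomial of the subgroup they fall in, then exactly n/2
    participants are assigned to treatment by a random permutation
    (complete randomization).  The observed outcome is
    ``Y = Z*Y1 + (1-Z)*Y0``.
    """
    rng = np.random.default_rng(seed)
    cov = _draw_covariates(spec, rng)
    n = spec.n_total

    # delta: a single uniform draw per participant, inverted through the
    # multinomial CDF of whichever subgroup the participant belongs to.
    u = rng.random(n)
    delta = np.full(n, 99, dtype=np.int64)
    label = np.empty(n, dtype=object)
    assigned = np.zeros(n, dtype=bool)
    for rule in spec.delta_model:
        m = rule.mask(cov) & ~assigned
        p_m1, p_0, _ = rule.probs
        d = np.where(u[m] < p_m1, -1, np.where(u[m] < p_m1 + p_0, 0, 1))
        delta[m] = d
        label[m] = rule.name
        assigned |= m
    if not assigned.all():
        raise ValueError(
            f"delta model of scenario {spec.scenario_id} does not cover "
            f"{int((~assigned).sum())} participants")

    y1 = np.where(delta == 1, 1, np.where(delta == -1, 0, spec.zero_delta_outcome))
    y0 = np.where(delta == 1, 0, np.where(delta == -1, 1, spec.zero_delta_outcome))

    z = np.zeros(n, dtype=np.int64)
    z[rng.permutation(n)[: n // 2]] = 1
    y = z * y1 + (1 - z) * y0

    data = cov.copy()
    data["Z"] = z
    data["Y"] = y
    truth = pd.DataFrame(
        {"Y1": y1, "Y0": y0, "delta": delta, "true_subgroup": label}
    )
    return TrialDataset(data=data, covariates=spec.covariates, truth=truth,
                        scenario_id=spec.scenario_id)


def expected_subgroup_ate(spec: ScenarioSpec) -> dict[str, float]:
    """Analytic average treatment effect per subgroup, plus the overall mean.

    Within a subgroup E[delta] = P[delta=1] - P[delta=-1].  The
    ``overall`` entry is the equal-weight mean across subgroups, which
    matches the designs: the subgroup-defining covariates split the
    population into (approximately) equal cells.
    """
    out = {rule.name: rule.expected_delta for rule in spec.delta_model}
    out["overall"] = math.fsum(out.values()) / len(spec.delta_model)
    return out


# ---------------------------------------------------------------------------
# CSV round-trip used by the CLI
# ---------------------------------------------------------------------------


def write_trial_csv(trial: TrialDataset, path, truth_path=None) -> None:
    trial.data.to_csv(path, index=False)
    if truth_path is not None:
        if trial.truth is None:
            raise ValueError("trial has no attached truth table")
        trial.truth.to_csv(truth_path, index=False)


def read_trial_csv(path, covariates: Sequence[Covariate] | str = "infer",
                   treatment: str = "Z", outcome: str = "Y") -> TrialDataset:
    """Load a trial from CSV; covariate kinds are inferred unless given.

    Inference: float columns are continuous, integer columns with values
    in {0,1} are binary, anything else is categorical.
    """
    df = pd.read_csv(path)
    for col in (treatment, outcome):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    df = df.rename(columns={treatment: "Z", outcome: "Y"})
    names = [c for c in df.columns if c not in ("Z", "Y")]
    if covariates == "infer":
        covs = []
        for name in names:
            s = df[name]
            if pd.api.types.is_float_dtype(s):
                covs.append(Covariate(name, "continuous", (float(s.mean()), float(s.std()))))
            elif pd.api.types.is_integer_dtype(s) and set(s.unique()) <= {0, 1}:
                covs.append(Covariate(name, "binary", (float(s.mean()),)))
            else:
                levels = tuple(sorted(map(str, s.astype(str).unique())))
                p = tuple(float((s.astype(str) == lv).mean()) for lv in levels)
                covs.append(Covariate(name, "categorical", p, levels))
                df[name] = pd.Categorical(s.astype(str), categories=list(levels))
        covariates = tuple(covs)
    return TrialDataset(data=df, covariates=tuple(covariates))
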