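"""Seeded simulation of reference populations.

Real health datasets of the kind audited here (birth registries, hospital
discharge files, adverse-event reports) are individual-level tables dominated
by categorical variables: a handful of "core" variables tied to a predefined
binary outcome, plus a large pool of "adjunct" variables whose cardinality
ranges from binary flags to long-tailed code lists (diagnoses, medications).
This module generates synthetic stand-ins with exactly that structure —
a binary outcome driven by a logistic model on a subset of core variables,
Zipf-tailed high-cardinality categoricals, MCAR missingness — so the rest of
the pipeline can be exercised and tested end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "VariableSpec",
    "OutcomeSpec",
    "PopulationSpec",
    "Population",
    "generate_population",
    "default_population_suite",
    "save_population",
    "load_population",
]


@dataclass(frozen=True)
class VariableSpec:
    """One simulated variable.

    Parameters
    ----------
    name : str
        Column name; unique within a population.
    kind : {"categorical", "numeric"}
    cardinality : int
        Number of levels (categorical) or a bin-resolution hint (numeric).
    distribution : sequence of float or dict, optional
        Category weights (must sum to 1) for categoricals, or parameters of a
        normal mixture ``{"means": [...], "sds": [...], "weights": [...]}``
        for numerics.  ``None`` means uniform weights / standard normal,
        unless ``tail_shape`` is set.
    tail_shape : float, optional
        Exponent of a truncated Zipf law for long-tailed categoricals
        (weight of level k proportional to ``k ** -tail_shape``).
    """

    name: str
    kind: str = "categorical"
    cardinality: int = 2
    distribution: object = None
    tail_shape: float | None = None

    def validate(self) -> None:
        if self.kind not in ("categorical", "numeric"):
            raise ValidationError(f"variable {self.name!r}: kind must be "
                                  f"'categorical' or 'numeric', got {self.kind!r}")
        if self.cardinality < 2:
            raise ValidationError(f"variable {self.name!r}: cardinality must be >= 2")
        if self.kind == "categorical" and isinstance(self.distribution, (list, tuple, np.ndarray)):
            w = np.asarray(self.distribution, dtype=float)
            if len(w) != self.cardinality:
                raise ValidationError(
                    f"variable {self.name!r}: distribution has {len(w)} weights "
                    f"for cardinality {self.cardinality}")
            if not math.isclose(float(w.sum()), 1.0, abs_tol=1e-8):
                raise ValidationError(
                    f"variable {self.name!r}: distribution weights sum to "
                    f"{w.sum():.6f}, not 1")

    def weights(self) -> np.ndarray:
        """Category weights (categorical variables only)."""
        if isinstance(self.distribution, (list, tuple, np.ndarray)):
            return np.asarray(self.distribution, dtype=float)
        if self.tail_shape is not None:
            ranks = np.arange(1, self.cardinality + 1, dtype=float)
            w = ranks ** -float(self.tail_shape)
            return w / w.sum()
        return np.full(self.cardinality, 1.0 / self.cardinality)


@dataclass(frozen=True)
class OutcomeSpec:
    """Binary outcome drawn from a logistic model on signal core variables."""

    outcome_name: str = "outcome"
    signal_vars: tuple[str, ...] = ()
    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    prevalence_target: float | None = None

    def validate(self, core_names: Sequence[str]) -> None:
        missing = set(self.signal_vars) - set(core_names)
        if missing:
            raise ValidationError(
                f"outcome.signal_vars not in core_vars: {sorted(missing)}")
        extra = set(self.coefficients) - set(self.signal_vars)
        if extra:
            raise ValidationError(
                f"outcome.coefficients for non-signal variables: {sorted(extra)}")
        if self.prevalence_target is not None and not 0 < self.prevalence_target < 1:
            raise ValidationError("outcome.prevalence_target must be in (0, 1)")


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    n_records: int
    core_vars: tuple[VariableSpec, ...]
    adjunct_pool: tuple[VariableSpec, ...] = ()
    outcome: OutcomeSpec = field(default_factory=OutcomeSpec)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 1:
            raise ValidationError("n_records must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        names = [v.name for v in self.core_vars] + [v.name for v in self.adjunct_pool]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate variable names: {sorted(dupes)}")
        if self.outcome.outcome_name in names:
            raise ValidationError(
                f"outcome name {self.outcome.outcome_name!r} collides with a variable")
        for v in (*self.core_vars, *self.adjunct_pool):
            v.validate()
        self.outcome.validate([v.name for v in self.core_vars])

    @property
    def core_names(self) -> list[str]:
        return [v.name for v in self.core_vars]

    @property
    def adjunct_names(self) -> list[str]:
        return [v.name for v in self.adjunct_pool]

    @property
    def pool_size(self) -> int:
        return len(self.adjunct_pool)


@dataclass
class Population:
    """A fully simulated reference population (all records, all variables)."""

    records: pd.DataFrame
    spec: PopulationSpec

    @property
    def name(self) -> str:
        return self.spec.name

    def __len__(self) -> int:
        return len(self.records)


def _category_labels(cardinality: int) -> np.ndarray:
    return np.array([f"L{i}" for i in range(cardinality)], dtype=object)


def _draw_variable(var: VariableSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if var.kind == "categorical":
        codes = rng.choice(var.cardinality, size=n, p=var.weights())
        return _category_labels(var.cardinality)[codes]
    params = var.distribution if isinstance(var.distribution, dict) else {}
    means = np.asarray(params.get("means", [0.0]), dtype=float)
    sds = np.asarray(params.get("sds", [1.0] * len(means)), dtype=float)
    w = np.asarray(params.get("weights", [1.0 / len(means)] * len(means)), dtype=float)
    comp = rng.choice(len(means), size=n, p=w / w.sum())
    x = rng.normal(means[comp], sds[comp])
    decimals = params.get("round")
    if decimals is not None:
        x = np.round(x, int(decimals))
    return x


def _signal_matrix(df: pd.DataFrame, spec: PopulationSpec) -> np.ndarray:
    """Numeric encoding of signal variables: level index for categoricals,
    raw value for numerics (the scale the logistic coefficients refer to)."""
    cols = []
    kinds = {v.name: v.kind for v in spec.core_vars}
    for name in spec.outcome.signal_vars:
        if kinds[name] == "categorical":
            cols.append(df[name].str.slice(1).astype(int).to_numpy(dtype=float))
        else:
            cols.append(df[name].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def generate_population(spec: PopulationSpec) -> Population:
    """Simulate a reference population from ``spec``.

    Deterministic given ``spec.seed``.  The outcome is Bernoulli with
    ``logit P(y=1) = intercept + sum_j beta_j * x_j`` over the signal
    variables; when ``prevalence_target`` is set the intercept is shifted
    (by bisection) so the expected prevalence matches the target.
    Missing values are injected completely at random per variable at
    ``missing_rate``, never in the outcome or the record id.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records

    data: dict[str, np.ndarray] = {"record_id": np.arange(n, dtype=np.int64)}
    for var in (*spec.core_vars, *spec.adjunct_pool):
        data[var.name] = _draw_variable(var, n, rng)
    df = pd.DataFrame(data)

    # outcome before missingness: the generating model sees complete data
    x = _signal_matrix(df, spec)
    beta = np.array([spec.outcome.coefficients.get(v, 0.0)
                     for v in spec.outcome.signal_vars])
    eta = spec.outcome.intercept + x @ beta
    if spec.outcome.prevalence_target is not None:
        target = spec.outcome.prevalence_target
        lo, hi = -30.0, 30.0
        for _ in range(80):
            mid = (lo + hi) / 2
            if _expit(eta - spec.outcome.intercept + mid).mean() < target:
                lo = mid
            else:
                hi = mid
        eta = eta - spec.outcome.intercept + (lo + hi) / 2
    y = (rng.random(n) < _expit(eta)).astype(np.int64)
    df[spec.outcome.outcome_name] = y

    if spec.missing_rate > 0:
        for var in (*spec.core_vars, *spec.adjunct_pool):
            mask = rng.random(n) < spec.missing_rate
            if mask.any():
                col = df[var.name].astype(object if var.kind == "categorical" else float)
                col[mask] = np.nan
                df[var.name] = col
    return Population(records=df, spec=spec)


def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-eta))


def default_population_suite(k: int, seed: int = 0) -> list[PopulationSpec]:
    """``k`` population specs spanning small to large adjunct pools.

    Pool sizes run log-spaced from ~5 (survey-like datasets) to 120+
    (discharge-like datasets with long-tailed code variables); every spec
    with a pool of 50 or more includes at least one long-tailed
    high-cardinality variable.  Deterministic given ``seed``.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(seed)
    if k == 1:
        pool_sizes = [20]
    else:
        pool_sizes = np.unique(np.round(np.geomspace(5, 120, k)).astype(int))
        # geomspace rounding can collide for large k; pad deterministically
        pool_sizes = list(pool_sizes)
        while len(pool_sizes) < k:
            pool_sizes.append(pool_sizes[-1] + 7)
    specs = []
    for i, m in enumerate(sorted(pool_sizes)):
        core = [
            VariableSpec(f"core{j}", "categorical", int(rng.integers(2, 5)))
            for j in range(4)
        ]
        core.append(VariableSpec("core_num", "numeric", 10,
                                 {"means": [0.0, 2.0], "sds": [1.0, 1.0],
                                  "weights": [0.7, 0.3]}))
        adjuncts = []
        for j in range(m):
            if m >= 50 and j < max(1, m // 20):
                adjuncts.append(VariableSpec(f"adj{j}", "categorical",
                                             int(rng.integers(100, 300)),
                                             tail_shape=1.2))
            elif j % 10 == 9:
                adjuncts.append(VariableSpec(f"adj{j}", "numeric", 10))
            else:
                adjuncts.append(VariableSpec(f"adj{j}", "categorical",
                                             int(rng.integers(2, 30))))
        outcome = OutcomeSpec(
            outcome_name="outcome",
            signal_vars=("core0", "core1"),
            coefficients={"core0": 1.0, "core1": -0.7},
            intercept=0.0,
            prevalence_target=float(rng.uniform(0.15, 0.5)),
        )
        specs.append(PopulationSpec(
            name=f"pop{i:02d}_m{m}",
            n_records=20_000,
            core_vars=tuple(core),
            adjunct_pool=tuple(adjuncts),
            outcome=outcome,
            missing_rate=0.02,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return specs


# ---------------------------------------------------------------------------
# persistence: table as Parquet/CSV + sidecar JSON schema

def save_population(pop: Population, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        pop.records.to_csv(path, index=False)
    else:
        pop.records.to_parquet(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    sidecar.write_text(json.dumps(_spec_to_json(pop.spec), indent=2))


def load_population(path: str | Path) -> Population:
    path = Path(path)
    df = pd.read_csv(path) if path.suffix == ".csv" else pd.read_parquet(path)
    # parquet object columns round-trip missing as None; normalize to NaN
    obj = df.columns[df.dtypes == object]
    df[obj] = df[obj].where(df[obj].notna(), np.nan)
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    spec = _spec_from_json(json.loads(sidecar.read_text()))
    return Population(records=df, spec=spec)


def _spec_to_json(spec: PopulationSpec) -> dict:
    return asdict(spec)


def _spec_from_json(d: dict) -> PopulationSpec:
    def var(v):
        return VariableSpec(**v)
    outcome = OutcomeSpec(**{**d["outcome"],
                             "signal_vars": tuple(d["outcome"]["signal_vars"])})
    return PopulationSpec(
        name=d["name"], n_records=d["n_records"],
        core_vars=tuple(var(v) for v in d["core_vars"]),
        adjunct_pool=tuple(var(v) for v in d["adjunct_pool"]),
        outcome=outcome, missing_rate=d["missing_rate"], seed=d["seed"],
    )
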