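"""Population variants and the shared train/holdout split.

A variant is a column subset of a reference population: the core variables
(and outcome) plus a sampled subset of the adjunct pool.  Every variant keeps
all records, and all variants of one population share the identical, fixed
train/holdout record split, so differences downstream are attributable to the
column set alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .population import Population

__all__ = [
    "VariantPlan",
    "PopulationVariant",
    "TrainHoldoutSplit",
    "count_subsets",
    "sample_variant_plans",
    "build_variant",
    "make_split",
]


@dataclass(frozen=True)
class VariantPlan:
    population_name: str
    adjunct_subset: frozenset[str]
    plan_id: str
    seed: int

    @property
    def v(self) -> int:
        """Number of adjunct variables in the variant."""
        return len(self.adjunct_subset)


@dataclass
class PopulationVariant:
    parent: Population
    plan: VariantPlan
    records: pd.DataFrame  # record_id + core + adjunct subset + outcome

    @property
    def columns(self) -> list[str]:
        """Variable columns of the variant (record_id excluded)."""
        return [c for c in self.records.columns if c != "record_id"]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class TrainHoldoutSplit:
    train_ids: frozenset[int]
    holdout_ids: frozenset[int]

    def __post_init__(self):
        if self.train_ids & self.holdout_ids:
            raise ValidationError("train and holdout ids overlap")


def count_subsets(m: int, v: int | str) -> int:
    """Number of distinct adjunct subsets: C(m, v), or 2**m for ``v='all'``.

    Exact integer arithmetic; with m=100 the full combinatorial space is
    2**100 ≈ 1.267651e30 distinct variants.
    """
    if m < 0:
        raise ValidationError("m must be >= 0")
    if v == "all":
        return 2 ** m
    if not 0 <= v <= m:
        raise ValidationError(f"v={v} outside [0, {m}]")
    return math.comb(m, v)


def _log_size_grid(m: int, n_strata: int = 8) -> list[int]:
    """Target subset sizes 0..m, log-spaced so small and large v are covered."""
    if m == 0:
        return [0]
    sizes = np.unique(np.round(np.geomspace(1, m, min(n_strata, m))).astype(int))
    return [0, *sizes.tolist()]


def sample_variant_plans(population: Population, n_variants: int,
                         weighting: str = "log_stratified",
                         seed: int = 0) -> list[VariantPlan]:
    """Sample ``n_variants`` distinct adjunct subsets for a population.

    The default weighting stratifies the target subset size v over a
    log-spaced grid from 0 to m and draws a uniform random v-subset per
    stratum, rejecting duplicates, so the resulting variants span the full
    complexity range without enumerating the combinatorial space.  The
    core-only plan (v=0) is always included.  When the pool is tiny
    (m <= 5) the subsets are enumerated exhaustively instead.
    """
    if n_variants < 1:
        raise ValidationError("n_variants must be >= 1")
    pool = sorted(population.spec.adjunct_names)
    m = len(pool)
    attainable = 2 ** m
    if n_variants > attainable:
        raise ValidationError(
            f"n_variants={n_variants} exceeds the attainable maximum "
            f"2**{m} = {attainable}")
    rng = np.random.default_rng(seed)
    subsets: list[frozenset[str]] = []

    if m <= 5:
        for v in range(m + 1):
            for combo in combinations(pool, v):
                subsets.append(frozenset(combo))
        subsets = subsets[:n_variants]
    else:
        if weighting != "log_stratified":
            raise ValidationError(f"unknown weighting scheme {weighting!r}")
        seen = {frozenset()}
        subsets.append(frozenset())
        grid = _log_size_grid(m)
        gi = 0
        attempts = 0
        while len(subsets) < n_variants:
            v = grid[gi % len(grid)]
            gi += 1
            if v == 0:
                continue
            cand = frozenset(rng.choice(pool, size=v, replace=False).tolist())
            attempts += 1
            if cand not in seen:
                seen.add(cand)
                subsets.append(cand)
            elif attempts == 50 * n_variants:
                # the log grid saturated (e.g. n_variants close to 2**m):
                # widen to every subset size
                grid = list(range(m + 1))
            elif attempts > 200 * n_variants:
                if m <= 16:  # enumerate the remainder exactly
                    for v in range(m + 1):
                        for combo in combinations(pool, v):
                            fs = frozenset(combo)
                            if fs not in seen:
                                seen.add(fs)
                                subsets.append(fs)
                            if len(subsets) == n_variants:
                                break
                        if len(subsets) == n_variants:
                            break
                else:
                    raise ValidationError(
                        "could not sample enough distinct subsets; "
                        "reduce n_variants")
    return [
        VariantPlan(population_name=population.name, adjunct_subset=s,
                    plan_id=f"{population.name}-v{len(s):03d}-{i:05d}",
                    seed=seed)
        for i, s in enumerate(subsets)
    ]


def build_variant(population: Population, plan: VariantPlan) -> PopulationVariant:
    """Restrict the population to core + plan.adjunct_subset + outcome columns."""
    unknown = plan.adjunct_subset - set(population.spec.adjunct_names)
    if unknown:
        raise ValidationError(f"unknown adjunct variables: {sorted(unknown)}")
    cols = (["record_id"] + population.spec.core_names
            + sorted(plan.adjunct_subset)
            + [population.spec.outcome.outcome_name])
    return PopulationVariant(parent=population, plan=plan,
                             records=population.records[cols])


def make_split(population: Population, n_train: int, n_holdout: int,
               seed: int = 0) -> TrainHoldoutSplit:
    """Disjoint train/holdout record-id sets of exact sizes, shared by all
    variants of the population.  Deterministic given ``seed``."""
    n = len(population)
    if n_train + n_holdout > n:
        raise ValidationError(
            f"requested {n_train}+{n_holdout} records from a population of {n}")
    rng = np.random.default_rng(seed)
    ids = population.records["record_id"].to_numpy()
    perm = rng.permutation(ids)
    return TrainHoldoutSplit(
        train_ids=frozenset(int(i) for i in perm[:n_train]),
        holdout_ids=frozenset(int(i) for i in perm[n_train:n_train + n_holdout]),
    )


# ---------------------------------------------------------------------------
# serialization

def save_plans(plans: list[VariantPlan], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in plans:
            fh.write(json.dumps({
                "population": p.population_name, "plan_id": p.plan_id,
                "adjunct_subset": sorted(p.adjunct_subset), "seed": p.seed,
            }) + "\n")


def load_plans(path: str | Path) -> list[VariantPlan]:
    plans = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            plans.append(VariantPlan(d["population"],
                                     frozenset(d["adjunct_subset"]),
                                     d["plan_id"], d["seed"]))
    return plans


def save_split(split: TrainHoldoutSplit, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "train_ids": sorted(split.train_ids),
        "holdout_ids": sorted(split.holdout_ids),
    }))


def load_split(path: str | Path) -> TrainHoldoutSplit:
    d = json.loads(Path(path).read_text())
    return TrainHoldoutSplit(frozenset(d["train_ids"]), frozenset(d["holdout_ids"]))
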