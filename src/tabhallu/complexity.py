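"""Structural dataset complexity: log of the summed variable cardinalities.

Complexity C = log(sum_j c_j) where c_j is the cardinality of variable j —
a structural proxy that combines dimensionality (more variables raise the
sum) and cardinality (high-cardinality code variables raise it far more).
Cardinality is measured on the canonical record form used for hallucination
matching: distinct observed levels for categoricals, occupied discretization
bins for numerics, plus one extra level whenever missing values are present
(missing is its own matchable level).  Natural log by default; the base only
rescales the axis and leaves every monotone relationship unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audit import BinningPolicy, canonicalize
from .errors import ValidationError

__all__ = ["ComplexityResult", "variable_cardinality", "complexity"]


@dataclass(frozen=True)
class ComplexityResult:
    complexity: float
    per_variable_cardinality: dict[str, int]
    log_base: str  # "e" or a number rendered as string
    all_missing_variables: tuple[str, ...] = ()

    @property
    def total_cardinality(self) -> int:
        return int(sum(self.per_variable_cardinality.values()))


def variable_cardinality(column: pd.Series, policy: BinningPolicy | None = None,
                         name: str | None = None) -> int:
    """Number of distinct canonical levels of one column.

    Categorical: observed non-missing levels, plus one if any value is
    missing.  Numeric (when the policy bins it): occupied bins, plus one for
    missing.  An all-missing column has cardinality 1 — the missing level.
    """
    if len(column) == 0:
        raise ValidationError("column is empty")
    name = name or str(column.name)
    if policy is not None and name in policy.bin_edges:
        frame = column.to_frame(name)
        sub = BinningPolicy(columns=(name,), n_bins=policy.n_bins,
                            strategy=policy.strategy,
                            missing_token=policy.missing_token,
                            bin_edges={name: policy.bin_edges[name]})
        return int(canonicalize(frame, sub)[name].nunique())
    n_levels = int(column.nunique(dropna=True))
    return max(1, n_levels + int(column.isna().any()))


def complexity(dataset: pd.DataFrame, policy: BinningPolicy | None = None,
               base: float | None = None) -> ComplexityResult:
    """log(sum of variable cardinalities) over all matching columns.

    Monotone non-decreasing under adding a variable.  ``base=None`` means
    natural log.
    """
    cols = list(policy.columns) if policy is not None else \
        [c for c in dataset.columns if c != "record_id"]
    if not cols:
        raise ValidationError("dataset has no variables")
    cards, all_missing = {}, []
    for c in cols:
        cards[c] = variable_cardinality(dataset[c], policy, c)
        if dataset[c].isna().all():
            all_missing.append(c)
    total = sum(cards.values())
    value = math.log(total) if base is None else math.log(total, base)
    return ComplexityResult(complexity=float(value),
                            per_variable_cardinality=cards,
                            log_base="e" if base is None else repr(base),
                            all_missing_variables=tuple(all_missing))
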