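"""Hallucination identification by exact-record antijoin.

A hallucinated synthetic record is one that does not exist anywhere in the
population variant the training data were sampled from — a factuality
violation, regardless of statistical plausibility.  Operationally,
``HA = S \\ P``: the rows of the synthetic table with no exact row match in
the population variant, found by a row-wise antijoin over all variant
columns.  This is equivalent to requiring a record-level Hamming distance
greater than zero to the closest population record; a direct (quadratic)
Hamming implementation is provided as a test oracle.

Exact matching needs a canonical record form.  Numeric variables are
discretized with bin edges fixed on the population variant (equal-width by
default, left-closed/right-open with the last bin closed; out-of-range
values fall into dedicated below/above bins), and missing values map to a
sentinel token that matches itself.  The bin count is a first-class knob:
finer binning can only create more hallucinations, never fewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "MISSING_TOKEN",
    "BinningPolicy",
    "fit_binning_policy",
    "canonicalize",
    "hallucinated_records",
    "hamming_oracle",
    "hallucination_rate",
    "HallucinationReport",
]

MISSING_TOKEN = "__MISSING__"
_BELOW, _ABOVE = "bin_below", "bin_above"


@dataclass(frozen=True)
class BinningPolicy:
    """Canonicalization convention shared by synthetic and population tables.

    ``columns`` fixes the matching column set and order; ``bin_edges`` holds,
    per numeric variable, the strictly increasing edges computed on the
    population variant.
    """

    columns: tuple[str, ...]
    n_bins: int = 10
    strategy: str = "equal_width"
    missing_token: str = MISSING_TOKEN
    bin_edges: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for col, edges in self.bin_edges.items():
            e = np.asarray(edges, dtype=float)
            if e.ndim != 1 or len(e) < 2 or not np.all(np.diff(e) > 0):
                raise ValidationError(
                    f"bin_edges for {col!r} must be strictly increasing")


def fit_binning_policy(reference: pd.DataFrame,
                       columns: Sequence[str] | None = None,
                       n_bins: int = 10,
                       strategy: str = "equal_width") -> BinningPolicy:
    """Fix bin edges for every numeric column of ``reference`` (normally the
    population variant, so both tables are discretized on the same grid)."""
    if strategy not in ("equal_width", "quantile"):
        raise ValidationError(f"unknown binning strategy {strategy!r}")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if columns is None:
        columns = [c for c in reference.columns if c != "record_id"]
    edges: dict[str, np.ndarray] = {}
    for col in columns:
        s = reference[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique(dropna=True) > 2:
            x = s.dropna().to_numpy(dtype=float)
            if len(x) == 0:
                continue
            lo, hi = float(x.min()), float(x.max())
            if lo == hi:
                continue  # constant column: treat as categorical
            if strategy == "equal_width":
                e = np.linspace(lo, hi, n_bins + 1)
            else:
                e = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
                if len(e) < 2:
                    continue
            edges[col] = e
    return BinningPolicy(columns=tuple(columns), n_bins=n_bins,
                         strategy=strategy, bin_edges=edges)


def _canonicalize_numeric(x: pd.Series, edges: np.ndarray,
                          missing_token: str) -> np.ndarray:
    v = x.to_numpy(dtype=float)
    n_bins = len(edges) - 1
    # left-closed / right-open; last bin closed on the right
    idx = np.digitize(v, edges, right=False) - 1
    idx[v == edges[-1]] = n_bins - 1
    labels = np.array([_BELOW] + [f"bin{i:03d}" for i in range(n_bins)] + [_ABOVE],
                      dtype=object)
    out = labels[np.clip(idx, -1, n_bins) + 1]
    out[np.isnan(v)] = missing_token
    return out


def canonicalize(dataset: pd.DataFrame, policy: BinningPolicy) -> pd.DataFrame:
    """String-canonical form of ``dataset`` under ``policy``: numerics become
    bin labels, missing values become the sentinel, columns follow the
    policy's order.  Two records match iff their canonical rows are equal."""
    missing_cols = set(policy.columns) - set(dataset.columns)
    if missing_cols:
        raise SchemaError(f"dataset lacks matching columns: {sorted(missing_cols)}")
    out = {}
    for col in policy.columns:
        s = dataset[col]
        if col in policy.bin_edges:
            out[col] = _canonicalize_numeric(s, policy.bin_edges[col],
                                             policy.missing_token)
        else:
            vals = s.astype(object).to_numpy(copy=True)
            mask = pd.isna(vals)
            vals = np.array([str(v) for v in vals], dtype=object)
            vals[mask] = policy.missing_token
            out[col] = vals
    return pd.DataFrame(out, index=dataset.index)


def hallucinated_records(synthetic: pd.DataFrame, population_variant: pd.DataFrame,
                         policy: BinningPolicy) -> np.ndarray:
    """Positions (0-based) of synthetic rows with no exact match in the
    population variant; duplicates in the synthetic table count individually."""
    s = canonicalize(synthetic, policy).reset_index(drop=True)
    p = canonicalize(population_variant, policy).drop_duplicates()
    merged = s.merge(p, how="left", on=list(policy.columns), indicator=True)
    return np.flatnonzero((merged["_merge"] == "left_only").to_numpy())


def hamming_oracle(synthetic: pd.DataFrame, population_variant: pd.DataFrame,
                   policy: BinningPolicy,
                   max_comparisons: int = 10_000 * 10_000) -> np.ndarray:
    """Quadratic reference: synthetic rows whose minimum record-level Hamming
    distance to any population row is > 0.  Must agree exactly with
    :func:`hallucinated_records`; intended for small test instances only."""
    ns, npop = len(synthetic), len(population_variant)
    if ns * npop > max_comparisons:
        raise ValidationError(
            f"{ns}x{npop} comparisons exceed the size guard; "
            "use hallucinated_records (antijoin) instead")
    s = canonicalize(synthetic, policy)
    p = canonicalize(population_variant, policy)
    # integer-encode over the joint alphabet per column for fast comparison
    s_codes = np.empty((ns, len(policy.columns)), dtype=np.int64)
    p_codes = np.empty((npop, len(policy.columns)), dtype=np.int64)
    for j, col in enumerate(policy.columns):
        both = pd.concat([s[col], p[col]], ignore_index=True)
        codes = pd.factorize(both)[0]
        s_codes[:, j] = codes[:ns]
        p_codes[:, j] = codes[ns:]
    out = []
    chunk = max(1, 2_000_000 // max(npop, 1))
    for start in range(0, ns, chunk):
        block = s_codes[start:start + chunk]
        # min Hamming == 0 iff some population row equals the record exactly
        matched = (block[:, None, :] == p_codes[None, :, :]).all(axis=2).any(axis=1)
        out.append(np.flatnonzero(~matched) + start)
    return np.concatenate(out) if out else np.array([], dtype=np.int64)


@dataclass
class HallucinationReport:
    """Per-replicate hallucination counts and the averaged rate HR = |HA|/|S|."""

    per_replicate_count: list[int]
    per_replicate_rate: list[float]
    mean_rate: float
    n_synthetic: int

    @property
    def total_hallucinated(self) -> int:
        return int(sum(self.per_replicate_count))

    @property
    def total_trials(self) -> int:
        return self.n_synthetic * len(self.per_replicate_count)


def hallucination_rate(replicates: Iterable[pd.DataFrame],
                       population_variant: pd.DataFrame,
                       policy: BinningPolicy) -> HallucinationReport:
    """Hallucination rate per synthetic replicate and its mean across
    replicates (the trained generator's HR)."""
    counts, rates, n_syn = [], [], None
    for rep in replicates:
        if len(rep) == 0:
            raise ValidationError("empty synthetic replicate")
        if n_syn is None:
            n_syn = len(rep)
        ha = hallucinated_records(rep, population_variant, policy)
        counts.append(int(len(ha)))
        rates.append(len(ha) / len(rep))
    if n_syn is None:
        raise ValidationError("no replicates supplied")
    return HallucinationReport(per_replicate_count=counts,
                               per_replicate_rate=rates,
                               mean_rate=float(np.mean(rates)),
                               n_synthetic=n_syn)
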