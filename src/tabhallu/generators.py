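"""Tabular synthetic-data generators.

Two model families are implemented from scratch — the two whose mechanics
this pipeline studies in detail:

* **Sequential decision trees (ST).**  Variables are visited in a fixed
  order; the first is drawn from its empirical marginal, and each subsequent
  variable is modeled by a CART tree on all previously visited variables,
  with sampling done by drawing a donor value uniformly from the training
  records in the destination leaf (synthpop-style conditional synthesis).

* **Chow–Liu Bayesian network (BN).**  The maximum-mutual-information
  spanning tree over the variables, with Laplace-smoothed conditional
  probability tables and ancestral sampling from the root.

Both operate on a discretized scale: numeric variables are binned on edges
fixed from the training data and back-transformed by sampling uniformly
within the sampled bin, which aligns generation with the exact-match
convention of the hallucination audit.  Missing values are modeled as one
extra level per variable.  Other families (GANs, VAEs, flows, adversarial
random forests) participate through the plugin registry: anything that can
fit on a table and sample tables with the training schema plugs into the
pipeline identically to the built-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.metrics import mutual_info_score
from sklearn.tree import DecisionTreeClassifier

from .errors import ValidationError

__all__ = [
    "FittedGenerator",
    "ReplicateSet",
    "fit_sequential_trees",
    "fit_chow_liu_bn",
    "sample_replicates",
    "register_plugin",
    "fit_generator",
    "PluginContractError",
    "BUILTIN_FAMILIES",
]

_MISSING_CODE_KIND = "categorical"


class PluginContractError(ValidationError):
    """A plugin generator violated the fit/sample contract."""


# ---------------------------------------------------------------------------
# discretized working representation

@dataclass
class _ColumnModel:
    """Code book for one variable: levels (categorical) or bin edges (numeric),
    with the last code always reserved for 'missing'."""

    name: str
    kind: str                      # "categorical" | "binned"
    levels: np.ndarray | None = None   # observed values, object array
    edges: np.ndarray | None = None    # bin edges, len n_bins+1
    has_missing: bool = False          # missing observed in training?

    @property
    def n_codes(self) -> int:
        base = len(self.levels) if self.kind == "categorical" else len(self.edges) - 1
        return base + 1  # + missing

    @property
    def missing_code(self) -> int:
        return self.n_codes - 1

    def encode(self, s: pd.Series) -> np.ndarray:
        if self.kind == "categorical":
            lookup = {v: i for i, v in enumerate(self.levels)}
            out = np.array([lookup.get(v, -1) for v in s.to_numpy(dtype=object)],
                           dtype=np.int64)
            out[pd.isna(s).to_numpy()] = self.missing_code
            if (out < 0).any():
                raise ValidationError(
                    f"column {self.name!r}: value outside training levels")
            return out
        x = s.to_numpy(dtype=float)
        nb = len(self.edges) - 1
        idx = np.clip(np.digitize(x, self.edges, right=False) - 1, 0, nb - 1)
        idx[np.isnan(x)] = self.missing_code
        return idx.astype(np.int64)

    def decode(self, codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "categorical":
            pool = np.append(self.levels, np.nan)
            return pool[codes]
        lo = self.edges[np.clip(codes, 0, len(self.edges) - 2)]
        hi = self.edges[np.clip(codes, 0, len(self.edges) - 2) + 1]
        vals = rng.uniform(lo, hi)
        return np.where(codes == self.missing_code, np.nan, vals)


def _build_codebook(train: pd.DataFrame, n_bins: int) -> dict[str, _ColumnModel]:
    book = {}
    for col in train.columns:
        s = train[col]
        has_missing = bool(s.isna().any())
        if pd.api.types.is_numeric_dtype(s) and s.nunique(dropna=True) > 2:
            x = s.dropna().to_numpy(dtype=float)
            lo, hi = float(x.min()), float(x.max())
            if lo < hi and s.nunique(dropna=True) > n_bins:
                edges = np.linspace(lo, hi, n_bins + 1)
                book[col] = _ColumnModel(col, "binned", edges=edges,
                                         has_missing=has_missing)
                continue
        levels = pd.unique(s.dropna())
        book[col] = _ColumnModel(col, "categorical",
                                 levels=np.asarray(levels, dtype=object),
                                 has_missing=has_missing)
    return book


def _encode_frame(train: pd.DataFrame, book: dict[str, _ColumnModel]) -> np.ndarray:
    return np.column_stack([book[c].encode(train[c]) for c in train.columns])


@dataclass
class FittedGenerator:
    family: str  # "sequential_trees" | "chow_liu_bn" | "plugin:<name>"
    state: dict
    training_schema: dict[str, dict]
    seed: int

    @property
    def columns(self) -> list[str]:
        return list(self.training_schema)


@dataclass
class ReplicateSet:
    replicates: list[pd.DataFrame]
    n_per_replicate: int
    k: int
    generator: FittedGenerator

    def __post_init__(self):
        for r, rep in enumerate(self.replicates):
            if list(rep.columns) != self.generator.columns:
                raise PluginContractError(
                    f"replicate {r}: columns {list(rep.columns)} != training "
                    f"schema {self.generator.columns}")
            if len(rep) != self.n_per_replicate:
                raise PluginContractError(
                    f"replicate {r}: {len(rep)} rows, expected {self.n_per_replicate}")


def _schema(book: dict[str, _ColumnModel]) -> dict[str, dict]:
    out = {}
    for c, m in book.items():
        if m.kind == "categorical":
            out[c] = {"kind": "categorical", "levels": list(m.levels)}
        else:
            out[c] = {"kind": "binned", "edges": m.edges.tolist()}
    return out


def resolve_visit_order(columns: list[str], order_policy=None,
                        core_vars: list[str] | None = None,
                        outcome: str | None = None) -> list[str]:
    """Default order: core variables first with the outcome last among them,
    then adjuncts in schema order; ``order_policy`` may be an explicit list."""
    if isinstance(order_policy, (list, tuple)):
        if sorted(order_policy) != sorted(columns):
            raise ValidationError("order_policy must be a permutation of the columns")
        return list(order_policy)
    if core_vars:
        core = [c for c in core_vars if c in columns and c != outcome]
        if outcome in columns:
            core.append(outcome)
        rest = [c for c in columns if c not in core]
        return core + rest
    return list(columns)


# ---------------------------------------------------------------------------
# sequential decision trees

def fit_sequential_trees(train: pd.DataFrame, order_policy=None,
                         tree_params: dict | None = None, seed: int = 0,
                         n_bins: int = 10, core_vars: list[str] | None = None,
                         outcome: str | None = None) -> FittedGenerator:
    """Fit the sequential-CART generator.

    The first variable in the visit order keeps its empirical code
    distribution; every later variable gets a decision tree (default minimum
    leaf size 20, no depth cap) on the codes of all previously visited
    variables, and each leaf stores the training codes that fell into it as
    a donor pool.
    """
    if len(train) == 0 or train.shape[1] == 0:
        raise ValidationError("training table is empty")
    params = {"min_samples_leaf": 20, **(tree_params or {})}
    book = _build_codebook(train, n_bins)
    order = resolve_visit_order(list(train.columns), order_policy, core_vars, outcome)
    codes = {c: book[c].encode(train[c]) for c in train.columns}

    first = order[0]
    counts = np.bincount(codes[first], minlength=book[first].n_codes)
    models: list[dict] = [{"var": first, "marginal": counts / counts.sum()}]

    for i, var in enumerate(order[1:], start=1):
        X = np.column_stack([codes[v] for v in order[:i]]).astype(np.float64)
        y = codes[var]
        tree = DecisionTreeClassifier(random_state=seed, **params)
        tree.fit(X, y)
        leaf_ids = tree.apply(X)
        donors: dict[int, np.ndarray] = {
            int(leaf): y[leaf_ids == leaf] for leaf in np.unique(leaf_ids)}
        models.append({"var": var, "tree": tree, "donors": donors})

    return FittedGenerator(
        family="sequential_trees",
        state={"order": order, "models": models, "codebook": book},
        training_schema={c: _schema(book)[c] for c in train.columns},
        seed=seed,
    )


def _sample_sequential_trees(gen: FittedGenerator, n: int,
                             rng: np.random.Generator) -> pd.DataFrame:
    order = gen.state["order"]
    book = gen.state["codebook"]
    models = gen.state["models"]
    codes: dict[str, np.ndarray] = {}
    first = models[0]
    codes[first["var"]] = rng.choice(len(first["marginal"]), size=n,
                                     p=first["marginal"])
    for i, model in enumerate(models[1:], start=1):
        X = np.column_stack([codes[v] for v in order[:i]]).astype(np.float64)
        leaf_ids = model["tree"].apply(X)
        y = np.empty(n, dtype=np.int64)
        for leaf in np.unique(leaf_ids):
            mask = leaf_ids == leaf
            pool = model["donors"][int(leaf)]
            y[mask] = rng.choice(pool, size=int(mask.sum()))
        codes[model["var"]] = y
    data = {c: book[c].decode(codes[c], rng) for c in gen.columns}
    return _restore_dtypes(pd.DataFrame(data)[gen.columns], gen)


# ---------------------------------------------------------------------------
# Chow–Liu Bayesian network

def fit_chow_liu_bn(train: pd.DataFrame, smoothing_alpha: float = 1.0,
                    seed: int = 0, n_bins: int = 10,
                    root: str | None = None) -> FittedGenerator:
    """Learn the maximum-mutual-information spanning tree over the (discretized)
    variables and Laplace-smoothed conditional probability tables.

    A single-variable table degenerates to a smoothed marginal.  If the
    empirical mutual information graph is disconnected (exact zeros), each
    component is sampled independently from its own root.
    """
    if len(train) == 0 or train.shape[1] == 0:
        raise ValidationError("training table is empty")
    if smoothing_alpha < 0:
        raise ValidationError("smoothing_alpha must be >= 0")
    book = _build_codebook(train, n_bins)
    cols = list(train.columns)
    codes = {c: book[c].encode(train[c]) for c in cols}
    p = len(cols)

    edges: list[tuple[int, int]] = []
    if p > 1:
        mi = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                mi[i, j] = mutual_info_score(codes[cols[i]], codes[cols[j]])
        # max-MI spanning tree == min spanning tree on negated weights;
        # shift so genuinely-zero MI edges still count as graph edges
        w = -(mi + 1e-9)
        mst = minimum_spanning_tree(csr_matrix(np.triu(w, k=1))).tocoo()
        edges = [(int(a), int(b)) for a, b in zip(mst.row, mst.col)]

    root_idx = cols.index(root) if root is not None else 0
    adjacency: dict[int, list[int]] = {i: [] for i in range(p)}
    for a, b in edges:
        adjacency[a].append(b)
        adjacency[b].append(a)

    parent = {root_idx: None}
    topo = [root_idx]
    stack = [root_idx]
    while stack:
        node = stack.pop()
        for nb in adjacency[node]:
            if nb not in parent:
                parent[nb] = node
                topo.append(nb)
                stack.append(nb)
    for i in range(p):  # disconnected components: independent roots
        if i not in parent:
            parent[i] = None
            topo.append(i)
            stack = [i]
            while stack:
                node = stack.pop()
                for nb in adjacency[node]:
                    if nb not in parent:
                        parent[nb] = node
                        topo.append(nb)
                        stack.append(nb)

    a = float(smoothing_alpha)
    cpts: dict[int, np.ndarray] = {}
    for i in topo:
        model = book[cols[i]]
        li = model.n_codes
        if parent[i] is None:
            cnt = np.bincount(codes[cols[i]], minlength=li).astype(float) + a
            if not model.has_missing:  # never invent a missing level
                cnt[model.missing_code] = 0.0
            cpts[i] = cnt / cnt.sum()
        else:
            lp = book[cols[parent[i]]].n_codes
            cnt = np.zeros((lp, li))
            np.add.at(cnt, (codes[cols[parent[i]]], codes[cols[i]]), 1.0)
            cnt += a
            if not model.has_missing:
                cnt[:, model.missing_code] = 0.0
            cpts[i] = cnt / cnt.sum(axis=1, keepdims=True)

    return FittedGenerator(
        family="chow_liu_bn",
        state={"cols": cols, "topo": topo, "parent": parent, "cpts": cpts,
               "codebook": book, "alpha": a},
        training_schema=_schema(book),
        seed=seed,
    )


def _sample_chow_liu(gen: FittedGenerator, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    st = gen.state
    cols, book = st["cols"], st["codebook"]
    codes: dict[int, np.ndarray] = {}
    for i in st["topo"]:
        cpt = st["cpts"][i]
        if st["parent"][i] is None:
            codes[i] = rng.choice(len(cpt), size=n, p=cpt)
        else:
            pc = codes[st["parent"][i]]
            out = np.empty(n, dtype=np.int64)
            for level in np.unique(pc):
                mask = pc == level
                out[mask] = rng.choice(cpt.shape[1], size=int(mask.sum()),
                                       p=cpt[level])
            codes[i] = out
    data = {c: book[c].decode(codes[i], rng) for i, c in enumerate(cols)}
    return _restore_dtypes(pd.DataFrame(data)[cols], gen)


def _restore_dtypes(df: pd.DataFrame, gen: FittedGenerator) -> pd.DataFrame:
    """Donor values come back as object arrays; restore numeric dtypes where
    the training levels were numeric and no missing sentinel intervenes."""
    for col, info in gen.training_schema.items():
        if info["kind"] == "categorical":
            levels = info["levels"]
            if levels and all(isinstance(v, (int, np.integer)) for v in levels):
                if not df[col].isna().any():
                    df[col] = df[col].astype(np.int64)
            elif levels and all(isinstance(v, (float, np.floating)) for v in levels):
                df[col] = df[col].astype(float)
    return df


# ---------------------------------------------------------------------------
# replicate sampling and the plugin registry

def _replicate_rng(seed: int, r: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(r,)))


_SAMPLERS: dict[str, Callable] = {
    "sequential_trees": _sample_sequential_trees,
    "chow_liu_bn": _sample_chow_liu,
}

_PLUGINS: dict[str, dict] = {}


def register_plugin(name: str, fit_fn: Callable, sample_fn: Callable) -> str:
    """Register an external generator family.

    ``fit_fn(train, seed) -> state`` and ``sample_fn(state, n, rng) ->
    DataFrame`` with exactly the training columns and ``n`` rows; violations
    are rejected when replicates are assembled.
    """
    if not callable(fit_fn) or not callable(sample_fn):
        raise PluginContractError("fit_fn and sample_fn must be callable")
    _PLUGINS[name] = {"fit": fit_fn, "sample": sample_fn}
    return f"plugin:{name}"


def fit_generator(family: str, train: pd.DataFrame, seed: int = 0,
                  **kwargs) -> FittedGenerator:
    """Dispatch a fit by family name ('sequential_trees', 'chow_liu_bn', or
    'plugin:<name>')."""
    if family == "sequential_trees":
        return fit_sequential_trees(train, seed=seed, **kwargs)
    if family == "chow_liu_bn":
        return fit_chow_liu_bn(train, seed=seed, **kwargs)
    if family.startswith("plugin:"):
        name = family.split(":", 1)[1]
        if name not in _PLUGINS:
            raise ValidationError(f"unknown plugin {name!r}")
        state = _PLUGINS[name]["fit"](train, seed)
        book = _build_codebook(train, kwargs.get("n_bins", 10))
        return FittedGenerator(family=family,
                               state={"plugin_state": state, "name": name},
                               training_schema=_schema(book), seed=seed)
    raise ValidationError(f"unknown generator family {family!r}")


BUILTIN_FAMILIES = ("sequential_trees", "chow_liu_bn")


def sample_replicates(generator: FittedGenerator, n_per_replicate: int,
                      k: int, seed: int | None = None) -> ReplicateSet:
    """Draw ``k`` synthetic tables of ``n_per_replicate`` rows; replicate r
    uses a deterministic sub-seed derived from (seed, r)."""
    if n_per_replicate < 1 or k < 1:
        raise ValidationError("n_per_replicate and k must be >= 1")
    seed = generator.seed if seed is None else seed
    if generator.family.startswith("plugin:"):
        sampler = _PLUGINS[generator.state["name"]]["sample"]
        reps = [sampler(generator.state["plugin_state"], n_per_replicate,
                        _replicate_rng(seed, r)) for r in range(k)]
    else:
        sampler = _SAMPLERS[generator.family]
        reps = [sampler(generator, n_per_replicate, _replicate_rng(seed, r))
                for r in range(k)]
    return ReplicateSet(replicates=reps, n_per_replicate=n_per_replicate,
                        k=k, generator=generator)
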