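"""End-to-end experiment orchestration.

The study workflow has five stages: (1) simulate (or load) reference
populations, (2) build population variants and the fixed train/holdout
split, (3) fit generators on each variant's training rows and sample
replicate synthetic datasets, (4) audit hallucination rates against the
population variant, (5) measure downstream TSTR/TRTR utility — followed by
the random-intercept effect models on the assembled results table.

A single master seed fans out deterministically through a named hierarchical
sub-seed scheme (population / split / plans / generator / replicates /
learner), so any stage can be re-run in isolation and a full run is
reproducible.  Results are kept as one tidy long table with a row per
population x variant x generator — the unit of analysis of the effect
models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import audit, effects, generators, utility, variants
from .complexity import complexity as _complexity
from .errors import ValidationError
from .population import Population, PopulationSpec, default_population_suite, \
    generate_population

__all__ = [
    "ExperimentConfig",
    "DesignCounts",
    "design_counts",
    "ResultsBundle",
    "run_experiment",
    "subseed",
]

logger = logging.getLogger("tabhallu.pipeline")


def subseed(master: int, *keys) -> int:
    """Deterministic child seed (< 2**31) from the master seed and a named
    path, e.g. ``subseed(s, "generator", pop_name, plan_id, family)``."""
    ints = tuple(zlib.crc32(str(k).encode()) for k in keys)
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=ints)
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


@dataclass(frozen=True)
class DesignCounts:
    """Exact design arithmetic of a full factorial run."""

    n_populations: int
    n_variants_total: int
    n_trained_generators: int
    n_replicates_total: int
    n_classifier_fits_per_learner: int


def design_counts(n_variants_total: int, n_families: int, k: int,
                  n_populations: int = 0) -> DesignCounts:
    """Trained generators = variants x families; classifier fits per learner
    = generators x k TSTR fits + one TRTR fit per variant."""
    for name, v in [("n_variants_total", n_variants_total),
                    ("n_families", n_families), ("k", k)]:
        if v < 1:
            raise ValidationError(f"{name} must be a positive integer")
    n_gen = n_variants_total * n_families
    return DesignCounts(
        n_populations=n_populations,
        n_variants_total=n_variants_total,
        n_trained_generators=n_gen,
        n_replicates_total=n_gen * k,
        n_classifier_fits_per_learner=n_gen * k + n_variants_total,
    )


@dataclass
class ExperimentConfig:
    """Everything a run needs; defaults mirror the full study design
    (10,000-record synthetic datasets, 10 replicates per trained generator,
    both learners, 10 bins for numeric matching, P90-P10 >= 0.25 filter)."""

    populations: list[PopulationSpec] | None = None
    suite_k: int = 2                       # used when populations is None
    n_variants: int = 20
    families: tuple[str, ...] = generators.BUILTIN_FAMILIES
    n_train: int = 10_000
    n_holdout: int = 10_000
    n_per_replicate: int = 10_000
    k_replicates: int = 10
    learners: tuple[str, ...] = ("gbm", "mlp")
    n_bins: int = 10
    bin_strategy: str = "equal_width"
    filter_min_spread: float = 0.25
    gbm_grid: dict | None = None
    cv_folds: int = 5
    tree_params: dict | None = None
    smoothing_alpha: float = 1.0
    master_seed: int = 0

    def validate(self) -> None:
        for name in ("n_variants", "n_train", "n_holdout", "n_per_replicate",
                     "k_replicates", "n_bins", "cv_folds", "suite_k"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        for fam in self.families:
            if fam not in generators.BUILTIN_FAMILIES and \
                    not fam.startswith("plugin:"):
                raise ValidationError(f"unknown generator family {fam!r}")
        for lr in self.learners:
            if lr not in ("gbm", "mlp"):
                raise ValidationError(f"unknown learner {lr!r}")

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (frozenset, set, tuple)):
                return sorted(map(str, o))
            return str(o)
        blob = json.dumps(dataclasses.asdict(self), default=default,
                          sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def scaled_study_config(master_seed: int = 0,
                        learners: tuple[str, ...] = ("gbm",)
                        ) -> ExperimentConfig:
    """Desk-scale study configuration: two simulated populations whose
    adjunct pools impose a strong cardinality gradient (binary flags up to
    long-tailed code lists), 20 variants each, both built-in generators,
    3 replicates of 2,000 records per trained generator.

    Small enough to run on one CPU in minutes while exercising every stage;
    the complexity gradient is steep enough for the HR~complexity effect to
    be detectable with the mixed model.
    """
    from .population import OutcomeSpec, PopulationSpec, VariableSpec

    def pop(name: str, seed: int, cards: list[int]) -> PopulationSpec:
        core = (VariableSpec("c0", cardinality=2),
                VariableSpec("c1", cardinality=3),
                VariableSpec("c2", cardinality=4))
        adj = tuple(
            VariableSpec(f"a{j}", cardinality=c,
                         tail_shape=1.2 if c >= 30 else None)
            for j, c in enumerate(cards))
        outcome = OutcomeSpec(signal_vars=("c0", "c1"),
                              coefficients={"c0": 1.2, "c1": -0.8})
        return PopulationSpec(name, 6000, core, adj, outcome,
                              missing_rate=0.01, seed=seed)

    cards_a = [2, 3, 6, 15, 50, 120, 8, 200, 2, 30, 5, 80]
    cards_b = [2, 2, 4, 10, 40, 150, 6, 100, 3, 25, 12, 60]
    return ExperimentConfig(
        populations=[pop("popA", 1, cards_a), pop("popB", 2, cards_b)],
        n_variants=20,
        families=generators.BUILTIN_FAMILIES,
        n_train=2000, n_holdout=2000,
        n_per_replicate=2000, k_replicates=3,
        learners=learners,
        gbm_grid={"learning_rate": [0.1], "num_leaves": [31],
                  "n_estimators": [100]},
        master_seed=master_seed,
    )


@dataclass
class ResultsBundle:
    results: pd.DataFrame
    effects_hr_on_complexity: dict
    effects_tstr_on_hr: dict
    retained_populations: dict
    design: DesignCounts
    config: ExperimentConfig
    config_hash: str


def _resolve_populations(config: ExperimentConfig) -> list[Population]:
    if config.populations is not None:
        specs = config.populations
    else:
        specs = default_population_suite(config.suite_k,
                                         seed=subseed(config.master_seed, "suite"))
    pops = []
    for i, spec in enumerate(specs):
        spec = dataclasses.replace(
            spec, seed=subseed(config.master_seed, "population", spec.name))
        t0 = time.perf_counter()
        pops.append(generate_population(spec))
        logger.info("simulated population %s (%d records, pool %d) in %.1fs",
                    spec.name, spec.n_records, spec.pool_size,
                    time.perf_counter() - t0)
    return pops


def _variant_row(config, pop, plan, variant, policy, split) -> dict:
    comp = _complexity(variant.records[variant.columns], policy)
    return {
        "population": pop.name,
        "plan_id": plan.plan_id,
        "v": plan.v,
        "n_columns": len(variant.columns),
        "complexity": comp.complexity,
        "total_cardinality": comp.total_cardinality,
        "per_variable_cardinality": json.dumps(comp.per_variable_cardinality),
    }


def run_experiment(config: ExperimentConfig,
                   out_dir: str | Path | None = None) -> ResultsBundle:
    """Execute the full workflow and return the tidy results table plus the
    per-generator effect estimates.

    With ``out_dir`` set, the results table is cached under the config hash:
    a re-run with the identical config reloads it instead of recomputing
    (the run is deterministic given the master seed either way).
    """
    config.validate()
    chash = config.config_hash()
    cache = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cache = out_dir / f"results-{chash}.parquet"
        if cache.exists():
            logger.info("reusing cached results %s", cache)
            results = pd.read_parquet(cache)
            return _finalize(results, config, chash)

    pops = _resolve_populations(config)
    rows = []
    for pop in pops:
        split = variants.make_split(
            pop, config.n_train, config.n_holdout,
            seed=subseed(config.master_seed, "split", pop.name))
        plans = variants.sample_variant_plans(
            pop, config.n_variants,
            seed=subseed(config.master_seed, "plans", pop.name))
        task = utility.TaskSpec(
            outcome_name=pop.spec.outcome.outcome_name,
            feature_names=tuple(pop.spec.core_names))
        id_col = pop.records["record_id"]
        train_mask = id_col.isin(split.train_ids).to_numpy()
        holdout_mask = id_col.isin(split.holdout_ids).to_numpy()
        assert not (train_mask & holdout_mask).any()

        # TRTR depends only on the core columns, which every variant shares;
        # compute once per population per learner and reuse across variants.
        core_cols = ["record_id"] + pop.spec.core_names + \
            [pop.spec.outcome.outcome_name]
        holdout_core = pop.records.loc[holdout_mask, core_cols]
        trtr: dict[str, float] = {}
        for lr in config.learners:
            trtr[lr] = utility.evaluate_trtr(
                pop.records.loc[train_mask, core_cols], holdout_core, task,
                learner=lr, seed=subseed(config.master_seed, "trtr", pop.name, lr),
                gbm_grid=config.gbm_grid, cv_folds=config.cv_folds)
            logger.info("%s TRTR[%s] = %.4f", pop.name, lr, trtr[lr])

        for plan in plans:
            variant = variants.build_variant(pop, plan)
            var_table = variant.records[variant.columns]
            policy = audit.fit_binning_policy(
                var_table, n_bins=config.n_bins, strategy=config.bin_strategy)
            base = _variant_row(config, pop, plan, variant, policy, split)
            train_table = variant.records.loc[train_mask, variant.columns]

            for family in config.families:
                gen_seed = subseed(config.master_seed, "generator",
                                   pop.name, plan.plan_id, family)
                gen = generators.fit_generator(
                    family, train_table, seed=gen_seed,
                    **({"core_vars": pop.spec.core_names,
                        "outcome": pop.spec.outcome.outcome_name,
                        "tree_params": config.tree_params,
                        "n_bins": config.n_bins}
                       if family == "sequential_trees" else
                       {"smoothing_alpha": config.smoothing_alpha,
                        "n_bins": config.n_bins}
                       if family == "chow_liu_bn" else {}))
                reps = generators.sample_replicates(
                    gen, config.n_per_replicate, config.k_replicates,
                    seed=subseed(config.master_seed, "replicates",
                                 pop.name, plan.plan_id, family))
                report = audit.hallucination_rate(reps.replicates, var_table,
                                                  policy)
                row = dict(base)
                row.update({
                    "generator": family,
                    "hr_mean": report.mean_rate,
                    "hr_per_replicate": json.dumps(report.per_replicate_rate),
                    "hallucinated_total": report.total_hallucinated,
                    "trials_total": report.total_trials,
                    "generator_seed": gen_seed,
                })
                for lr in config.learners:
                    rep_task = utility.evaluate_tstr(
                        reps, holdout_core, task, learner=lr,
                        seed=subseed(config.master_seed, "tstr",
                                     pop.name, plan.plan_id, family, lr),
                        gbm_grid=config.gbm_grid, cv_folds=config.cv_folds)
                    row[f"tstr_{lr}_mean"] = rep_task.tstr_mean
                    row[f"tstr_{lr}_per_replicate"] = json.dumps(
                        rep_task.tstr_per_replicate)
                    row[f"trtr_{lr}"] = trtr[lr]
                rows.append(row)
            logger.info("%s %s (v=%d): HR %s", pop.name, plan.plan_id, plan.v,
                        [f"{r['hr_mean']:.3f}" for r in rows[-len(config.families):]])

    results = pd.DataFrame(rows)
    results["config_hash"] = chash
    results["master_seed"] = config.master_seed
    if cache is not None:
        results.to_parquet(cache, index=False)
    return _finalize(results, config, chash)


def _finalize(results: pd.DataFrame, config: ExperimentConfig,
              chash: str) -> ResultsBundle:
    n_pops = results["population"].nunique()
    n_variants_total = len(results[["population", "plan_id"]].drop_duplicates())
    design = design_counts(n_variants_total, len(config.families),
                           config.k_replicates, n_populations=n_pops)

    eff_hr, eff_tstr, retained = {}, {}, {}
    try:
        eff_hr = effects.fit_glmm_hr_on_complexity(results)
    except Exception as exc:  # single population, too few obs, ...
        logger.warning("HR~complexity model skipped: %s", exc)
    filtered, retained = effects.hr_spread_filter(
        results, min_spread=config.filter_min_spread)
    if not filtered.empty:
        for lr in config.learners:
            try:
                eff_tstr[lr] = effects.fit_lmm_tstr_on_hr(filtered, learner=lr)
            except Exception as exc:
                logger.warning("TSTR~HR model skipped for %s: %s", lr, exc)
    return ResultsBundle(results=results, effects_hr_on_complexity=eff_hr,
                         effects_tstr_on_hr=eff_tstr,
                         retained_populations=retained,
                         design=design, config=config, config_hash=chash)
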