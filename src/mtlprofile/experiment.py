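"""End-to-end experiment driver.

For each Monte Carlo seed: split the cohort, fit encoders on the
full-training rows, compute the fold-wise relatedness matrices (TAG
probes and/or Cramér's V) on the full-training k-folds, select task
groups, train the requested architecture variants, and score them on
the hold-out test rows.  Per-seed failures are logged and skipped so a
long suite survives a single divergence.  Aggregation produces
mean/STD/CI tables per variant and item, MPI scores against the STL
ensemble and the all-task MTL, and parameter counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .evaluation import aggregate_runs, mpi_score, overall_f1, task_f1
from .grouping import GroupingResult, enumerate_groups, fold_average, score_catalog, select_max_groups
from .networks import (
    ArchitectureConfig,
    TaskEnsemble,
    TrainingConfig,
    build_group_ensemble,
    build_mtl_all,
    build_mtl_concat,
    build_stl_ensemble,
    count_parameters,
    train,
    transfer_pretrained,
)
from .preprocessing import encode, fit_encoders
from .relatedness import association_matrix, probe_affinity
from .resampling import make_plan

logger = logging.getLogger(__name__)

#: The eight studied variants: the STL ensemble, grouped-MTL ensembles
#: conditioned by TAG / VTAG, the classic all-task MTL, and the all-task
#: MTL with concatenation heads (fresh or pre-trained-weight initialised).
VARIANTS = (
    "eSTL",
    "eTAG-MTL",
    "eVTAG-MTL",
    "MTLaT",
    "MTLaT-ccTAG",
    "MTLaT-ccTAG-PTM",
    "MTLaT-ccVTAG",
    "MTLaT-ccVTAG-PTM",
)

_NEEDS_TAG = ("eTAG-MTL", "MTLaT-ccTAG", "MTLaT-ccTAG-PTM")
_NEEDS_VTAG = ("eVTAG-MTL", "MTLaT-ccVTAG", "MTLaT-ccVTAG-PTM")
_NEEDS_MTLAT = ("MTLaT", "MTLaT-ccTAG-PTM", "MTLaT-ccVTAG-PTM")


@dataclass
class ExperimentConfig:
    n_seeds: int = 50
    k: int = 3
    test_frac: float = 0.20
    val_frac: float = 0.25
    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    train_cfg: TrainingConfig = field(default_factory=TrainingConfig)
    #: training settings for the TAG probe networks (defaults to train_cfg)
    tag_train_cfg: TrainingConfig | None = None
    variants: tuple[str, ...] = VARIANTS
    seeds: tuple[int, ...] | None = None  # explicit seed list overrides n_seeds
    out_dir: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.variants) - set(VARIANTS)
        if bad:
            raise ValueError(f"unknown variants {sorted(bad)}; choose from {VARIANTS}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")

    @property
    def seed_list(self) -> tuple[int, ...]:
        return self.seeds if self.seeds is not None else tuple(range(self.n_seeds))


def _with_seed(cfg: TrainingConfig, seed: int) -> TrainingConfig:
    return dataclasses.replace(cfg, seed=int(seed) % (2**31 - 1))


def compute_tag_grouping(table, plan, encoders, cfg: ExperimentConfig, seed: int):
    """Fold-wise affinity probes on the full-training k-folds -> grouping."""
    catalog = enumerate_groups(table.profile.M)
    probe_cfg = cfg.tag_train_cfg or cfg.train_cfg
    tables, matrices = [], []
    for f in range(plan.k):
        enc_tr = encode(table, encoders, plan.fold_train_rows(f))
        enc_val = encode(table, encoders, plan.folds[f])
        matrix, _, _ = probe_affinity(
            enc_tr.X, enc_tr.y, enc_val.X, enc_val.y, table.profile,
            cfg.arch, _with_seed(probe_cfg, seed * 101 + f), seed=seed * 101 + f,
            fold_id=f,
        )
        matrices.append(matrix)
        tables.append(score_catalog(np.nan_to_num(matrix.values), catalog))
    return select_max_groups(fold_average(tables)), matrices


def compute_vtag_grouping(table, plan, cfg: ExperimentConfig):
    """Fold-wise Cramér's V on the full-training k-folds -> grouping."""
    catalog = enumerate_groups(table.profile.M)
    tables, matrices = [], []
    for f in range(plan.k):
        targets = table.targets(plan.fold_train_rows(f))
        matrix = association_matrix(targets, fold_id=f)
        matrices.append(matrix)
        tables.append(score_catalog(matrix.values, catalog))
    return select_max_groups(fold_average(tables)), matrices


def run_seed(table: CohortTable, seed: int, cfg: ExperimentConfig) -> dict:
    """One full cycle: split, group, train every requested variant, test."""
    profile = table.profile
    plan = make_plan(table.n_rows, seed, cfg.test_frac, cfg.val_frac, cfg.k)
    encoders = fit_encoders(table, plan.full_train_rows)
    enc_tr = encode(table, encoders, plan.train_rows)
    enc_val = encode(table, encoders, plan.val_rows)
    enc_te = encode(table, encoders, plan.test_rows)
    input_dim = enc_tr.X.shape[1]

    tag_grouping = vtag_grouping = None
    if any(v in cfg.variants for v in _NEEDS_TAG):
        tag_grouping, _ = compute_tag_grouping(table, plan, encoders, cfg, seed)
    if any(v in cfg.variants for v in _NEEDS_VTAG):
        vtag_grouping, _ = compute_vtag_grouping(table, plan, cfg)

    def fit(model, offset: int):
        return train(model, enc_tr.X, enc_tr.y, enc_val.X, enc_val.y,
                     _with_seed(cfg.train_cfg, seed * 911 + offset))

    def score(predictor) -> dict:
        preds = predictor.predict(enc_te.X)
        f1 = {
            it.name: task_f1(enc_te.y[it.name], preds[it.name], it)
            for it in profile.items
        }
        return f1

    results: dict[str, dict] = {}
    mtl_all_model = None
    if any(v in cfg.variants for v in _NEEDS_MTLAT):
        mtl_all_model = fit(build_mtl_all(input_dim, profile, cfg.arch, seed=seed * 911), 0)

    for variant in cfg.variants:
        if variant == "eSTL":
            members = build_stl_ensemble(input_dim, profile, cfg.arch, seed=seed * 911 + 10)
            ens = TaskEnsemble([fit(m, 10 + i) for i, m in enumerate(members)])
            f1, params = score(ens), sum(count_parameters(m) for m in ens.members)
        elif variant in ("eTAG-MTL", "eVTAG-MTL"):
            grouping = tag_grouping if variant == "eTAG-MTL" else vtag_grouping
            members = build_group_ensemble(input_dim, profile, grouping, cfg.arch,
                                           seed=seed * 911 + 40)
            ens = TaskEnsemble([fit(m, 40 + i) for i, m in enumerate(members)])
            f1, params = score(ens), sum(count_parameters(m) for m in ens.members)
        elif variant == "MTLaT":
            f1, params = score(mtl_all_model), count_parameters(mtl_all_model)
        else:  # concatenation variants
            grouping = tag_grouping if "ccTAG" in variant else vtag_grouping
            model = build_mtl_concat(input_dim, profile, grouping, cfg.arch,
                                     seed=seed * 911 + 70)
            if variant.endswith("-PTM"):
                transfer_pretrained(mtl_all_model, model)
            f1, params = score(fit(model, 70)), count_parameters(model)
        results[variant] = {
            "f1": f1,
            "overall": overall_f1(f1.values()),
            "params": params,
        }

    return {
        "seed": seed,
        "variants": results,
        "tag_grouping": tag_grouping.groups if tag_grouping else None,
        "vtag_grouping": vtag_grouping.groups if vtag_grouping else None,
    }


def run_experiment(table: CohortTable, cfg: ExperimentConfig) -> dict:
    """Run every seed (isolating per-seed failures) and aggregate."""
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    per_seed, failed = [], []
    for seed in cfg.seed_list:
        try:
            res = run_seed(table, seed, cfg)
        except Exception:
            logger.exception("seed %d failed; continuing", seed)
            failed.append(seed)
            continue
        per_seed.append(res)
        if out_dir:
            doc = {
                "seed": res["seed"],
                "variants": res["variants"],
                "tag_grouping": [g.to_dict() for g in res["tag_grouping"]]
                if res["tag_grouping"] else None,
                "vtag_grouping": [g.to_dict() for g in res["vtag_grouping"]]
                if res["vtag_grouping"] else None,
            }
            (out_dir / f"seed_{seed:03d}.json").write_text(json.dumps(doc, indent=2))
    report = summarize(per_seed, table.profile.names, tuple(cfg.variants))
    report["failed_seeds"] = failed
    if out_dir:
        report["table"].to_csv(out_dir / "report.csv", index=False)
        (out_dir / "mpi.json").write_text(json.dumps(report["mpi"], indent=2))
    return {"per_seed": per_seed, "report": report}


def summarize(per_seed: list[dict], item_names: tuple[str, ...], variants: tuple[str, ...]) -> dict:
    """Aggregate per-seed metrics into a variants x items table plus MPI."""
    if not per_seed:
        raise ValueError("no successful seeds to summarize")
    variants = tuple(v for v in variants if v in per_seed[0]["variants"])
    rows = []
    item_means: dict[str, dict[str, float]] = {}
    overall_means: dict[str, dict] = {}
    for v in variants:
        agg_cols = {}
        for name in item_names:
            vals = [s["variants"][v]["f1"][name] for s in per_seed]
            agg_cols[name] = aggregate_runs(vals) if len(vals) > 1 else {
                "mean": vals[0], "std": float("nan"),
                "ci_low": float("nan"), "ci_high": float("nan"), "n": 1}
        ovals = [s["variants"][v]["overall"] for s in per_seed]
        oagg = agg_cols["Overall"] = aggregate_runs(ovals) if len(ovals) > 1 else {
            "mean": ovals[0], "std": float("nan"),
            "ci_low": float("nan"), "ci_high": float("nan"), "n": 1}
        item_means[v] = {n: agg_cols[n]["mean"] for n in item_names}
        overall_means[v] = oagg
        for stat in ("mean", "std", "ci_low", "ci_high"):
            rows.append({"variant": v, "statistic": stat,
                         **{n: agg_cols[n][stat] for n in (*item_names, "Overall")}})
    table = pd.DataFrame(rows)

    mpi: dict[str, dict[str, float]] = {}
    for ref in ("eSTL", "MTLaT"):
        if ref not in variants:
            continue
        ref_vec = [item_means[ref][n] for n in item_names]
        mpi[f"vs_{ref}"] = {
            v: mpi_score([item_means[v][n] for n in item_names], ref_vec)
            for v in variants
        }
    params = {
        v: float(np.mean([s["variants"][v]["params"] for s in per_seed]))
        for v in variants
    }
    return {"table": table, "mpi": mpi, "params": params,
            "overall": overall_means, "item_means": item_means}
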