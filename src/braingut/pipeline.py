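"""End-to-end orchestration: cohort → features → selection → models → null.

A single declarative configuration drives every stage. Runs are idempotent
given the seed: all randomness derives from ``PipelineConfig.seed`` and two
runs with the same configuration produce byte-identical JSON reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from braingut.cohort import CohortSpec, CovariateModel, SyntheticCohort, generate_cohort, write_cohort
from braingut.combine import MergeSpec, merge_top_fraction, permutation_test
from braingut.connectome import DEFAULT_METRICS, compute_node_metrics, flatten_metrics
from braingut.evaluate import FAMILIES, assemble_design, loo_evaluate, train_linear
from braingut.features import FeatureMatrix
from braingut.rfe import RFEConfig, select_features

logger = logging.getLogger("braingut")

__all__ = ["PipelineConfig", "run_pipeline", "build_feature_blocks"]


def _derive_seed(seed: int, stage: int) -> int:
    return (seed * 1_000_003 + stage) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run.

    Defaults describe the reduced demonstration cohort: the study's subject
    split (64 obese / 53 overweight) and 165-region parcellation with a
    200-metabolite panel, signal planted in 8 brain regions and 10
    metabolites, and an automatic ~15-point candidate-k grid.
    """

    # cohort
    n_obese: int = 64
    n_overweight: int = 53
    n_regions: int = 165
    n_metabolites: int = 200
    n_informative_brain_regions: int = 8
    n_informative_metabolites: int = 10
    brain_effect: float = 1.25
    metabolite_effect: float = 0.8
    null_covariates: bool = False
    write_cohort_files: bool = False
    edge_density: float = 0.35
    mean_fiber_count: float = 40.0
    # features
    metrics: tuple[str, ...] = DEFAULT_METRICS
    volume_convention: str = "sum"
    log_metabolites: bool = True
    # selection
    blocks: tuple[str, ...] = ("brain", "metabolite")
    candidate_k_grid: list[int] | None = None
    elimination_step: int = 1
    svm_cost: float = 1.0
    n_folds: int = 10
    # evaluation
    families: tuple[str, ...] = FAMILIES
    # combined + null
    merge_fraction: float = 0.9
    permutation_R: int = 199
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("metrics", "blocks", "families"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_obese=self.n_obese,
            n_overweight=self.n_overweight,
            n_regions=self.n_regions,
            n_metabolites=self.n_metabolites,
            informative_brain_regions=list(range(self.n_informative_brain_regions)),
            informative_metabolites=list(range(self.n_informative_metabolites)),
            brain_effect=self.brain_effect,
            metabolite_effect=self.metabolite_effect,
            covariate_model=CovariateModel.null() if self.null_covariates else CovariateModel(),
            seed=_derive_seed(self.seed, 0),
            edge_density=self.edge_density,
            mean_fiber_count=self.mean_fiber_count,
        )

    def rfe_config(self) -> RFEConfig:
        return RFEConfig(
            candidate_k_grid=self.candidate_k_grid,
            elimination_step=self.elimination_step,
            svm_cost=self.svm_cost,
            n_folds=self.n_folds,
            seed=_derive_seed(self.seed, 1),
        )


def build_feature_blocks(
    cohort: SyntheticCohort, config: PipelineConfig
) -> dict[str, FeatureMatrix]:
    """Compute the subjects × features matrix for each requested block."""
    blocks: dict[str, FeatureMatrix] = {}
    if "brain" in config.blocks:
        tables = {
            sid: compute_node_metrics(
                fib, metrics=config.metrics, volume_convention=config.volume_convention
            )
            for sid, fib in zip(cohort.subject_ids, cohort.fiber_matrices)
        }
        block = flatten_metrics(tables, metrics=config.metrics)
        bad = block.columns[block.isna().any() | (block.std(axis=0) == 0)]
        if len(bad):
            logger.warning(
                "dropping %d brain features that are undefined or constant: %s",
                len(bad), list(bad),
            )
            block = block.drop(columns=bad)
        blocks["brain"] = FeatureMatrix(block, cohort.labels, cohort.covariates)
    if "metabolite" in config.blocks:
        table = cohort.metabolite_table
        if config.log_metabolites:
            table = np.log(table.clip(lower=np.finfo(float).tiny))
        blocks["metabolite"] = FeatureMatrix(table, cohort.labels, cohort.covariates)
    return blocks


def _report_to_dict(report) -> dict:
    return {
        "family": report.family,
        "confusion": {"tp": report.tp, "fp": report.fp, "fn": report.fn, "tn": report.tn},
        "accuracy": report.accuracy,
        "precision": {str(k): v for k, v in report.precision.items()},
        "recall": {str(k): v for k, v in report.recall.items()},
        "undefined_metrics": report.undefined_metrics,
        "auc": report.auc,
        "notes": report.notes,
    }


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=True, default=_json_default) + "\n"
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every configured stage, writing all artifacts under ``outdir``.

    Returns a manifest dict (also written as ``manifest.json``) listing the
    artifacts, the configuration, its hash and the package version — enough
    state to reproduce every stochastic output exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    timings: dict[str, float] = {}

    def _stage(name: str):
        logger.info("stage %s", name)
        return time.perf_counter()

    def _done(name: str, t0: float) -> None:
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, timings[name])

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- cohort --------------------------------------------------------------
    t0 = _stage("synthetic_cohort")
    try:
        cohort = generate_cohort(config.cohort_spec())
        if config.write_cohort_files:
            write_cohort(cohort, outdir / "cohort")
            artifacts.append("cohort/")
    except Exception as exc:  # noqa: BLE001
        _fail("synthetic_cohort", exc)
    _done("synthetic_cohort", t0)

    # --- clinical table ------------------------------------------------------
    from braingut.report import make_cohort_table

    t0 = _stage("cohort_table")
    try:
        table1 = make_cohort_table(cohort)
        table1.to_csv(outdir / "cohort_table.tsv", sep="\t")
        artifacts.append("cohort_table.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail("cohort_table", exc)
    _done("cohort_table", t0)

    # --- feature blocks ------------------------------------------------------
    t0 = _stage("features")
    try:
        blocks = build_feature_blocks(cohort, config)
        for name, fm in blocks.items():
            fm.values.rename_axis("subject").to_csv(outdir / f"features_{name}.tsv", sep="\t")
            artifacts.append(f"features_{name}.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail("features", exc)
    _done("features", t0)

    # --- selection -----------------------------------------------------------
    selections = {}
    rfe_cfg = config.rfe_config()
    for name, fm in blocks.items():
        t0 = _stage(f"selection_{name}")
        try:
            result = select_features(fm, rfe_cfg)
        except Exception as exc:  # noqa: BLE001
            _fail(f"selection_{name}", exc)
        selections[name] = result
        _dump_json(
            {
                "block": name,
                "accuracy_curve": {str(k): v for k, v in result.accuracy_curve.items()},
                "optimal_k": result.optimal_k,
                "votes": result.votes.counts,
                "n_folds": result.votes.n_folds,
                "final_features": result.final_features,
            },
            outdir / f"selection_{name}.json",
        )
        artifacts.append(f"selection_{name}.json")
        _done(f"selection_{name}", t0)

    # --- per-block models and LOO evaluation ---------------------------------
    models = {}
    for name, fm in blocks.items():
        design, covs = assemble_design(fm, selections[name].final_features, name)
        models[name] = train_linear(
            design, fm.labels, family="svm", cost=config.svm_cost, covariate_names=covs
        )
        for family in config.families:
            t0 = _stage(f"evaluate_{name}_{family}")
            try:
                report = loo_evaluate(
                    design, fm.labels, family=family, cost=config.svm_cost,
                    covariate_names=covs,
                )
            except Exception as exc:  # noqa: BLE001
                _fail(f"evaluate_{name}_{family}", exc)
            _dump_json(_report_to_dict(report), outdir / f"evaluation_{name}_{family}.json")
            report.roc.to_csv(outdir / f"roc_{name}_{family}.tsv", sep="\t", index=False)
            artifacts += [f"evaluation_{name}_{family}.json", f"roc_{name}_{family}.tsv"]
            _done(f"evaluate_{name}_{family}", t0)

    # --- combined model ------------------------------------------------------
    designs = {
        name: assemble_design(fm, selections[name].final_features, name)[0]
        for name, fm in blocks.items()
    }
    if set(("brain", "metabolite")) <= set(blocks):
        t0 = _stage("combined")
        try:
            merge = merge_top_fraction(
                models["brain"], models["metabolite"], MergeSpec(fraction=config.merge_fraction)
            )
            all_values = pd.concat(
                [blocks["brain"].values, blocks["metabolite"].values], axis=1
            )
            fm_comb = FeatureMatrix(all_values, cohort.labels, cohort.covariates)
            design, covs = assemble_design(fm_comb, merge.features, "combined")
            models["combined"] = train_linear(
                design, cohort.labels, family="svm", cost=config.svm_cost, covariate_names=covs
            )
            designs["combined"] = design
            _dump_json(
                {
                    "features": merge.features,
                    "provenance": merge.provenance,
                    "kept_per_block": merge.kept_per_block,
                    "ties_at_cut": merge.ties_at_cut,
                    "fraction": config.merge_fraction,
                },
                outdir / "combined_features.json",
            )
            artifacts.append("combined_features.json")
            for family in config.families:
                report = loo_evaluate(
                    design, cohort.labels, family=family, cost=config.svm_cost,
                    covariate_names=covs,
                )
                _dump_json(_report_to_dict(report), outdir / f"evaluation_combined_{family}.json")
                report.roc.to_csv(outdir / f"roc_combined_{family}.tsv", sep="\t", index=False)
                artifacts += [f"evaluation_combined_{family}.json", f"roc_combined_{family}.tsv"]
        except Exception as exc:  # noqa: BLE001
            _fail("combined", exc)
        _done("combined", t0)

    # --- permutation null ----------------------------------------------------
    for name, design in designs.items():
        t0 = _stage(f"permutation_{name}")
        try:
            covs = [c for c in ("age", "sex", "diet") if c in design.columns]
            perm = permutation_test(
                design, cohort.labels, R=config.permutation_R,
                seed=_derive_seed(config.seed, 2), cost=config.svm_cost,
                n_folds=config.n_folds, covariate_names=covs,
            )
        except Exception as exc:  # noqa: BLE001
            _fail(f"permutation_{name}", exc)
        _dump_json(
            {
                "block": name,
                "observed_accuracy": perm.observed_accuracy,
                "mean_permuted_accuracy": float(np.mean(perm.permuted_accuracies)),
                "permuted_accuracies": perm.permuted_accuracies,
                "empirical_p": perm.empirical_p,
                "R": config.permutation_R,
            },
            outdir / f"permutation_{name}.json",
        )
        artifacts.append(f"permutation_{name}.json")
        _done(f"permutation_{name}", t0)

    # --- manifest ------------------------------------------------------------
    cfg_dict = asdict(config)
    for key in ("metrics", "blocks", "families"):
        cfg_dict[key] = list(cfg_dict[key])
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    from braingut import __version__

    # timings go to the log only, so reruns stay byte-identical
    manifest = {
        "package_version": __version__,
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "artifacts": artifacts,
    }
    _dump_json(manifest, outdir / "manifest.json")
    return manifest
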