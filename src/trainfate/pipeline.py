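"""End-to-end orchestration: read -> preprocess -> metrics -> C1/C2 ->
classification -> concordance, with one seed reproducing everything."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .classify import build_feature_matrix, crossval_classify, rf_feature_importance
from .cluster_c1 import cluster_by_best_stage
from .cluster_c2 import cluster_c2
from .concordance import descriptor_tests_by_cluster, kmeans_descriptors, overlap_count
from .core import (
    ClusterAssignment,
    preprocess_compounds,
    read_descriptor_table,
    read_peak_area_table,
    read_train_config,
)
from .removal import all_profiles, profiles_to_frame

log = logging.getLogger("trainfate")

# fixed per-stage seed offsets so one config seed reproduces the whole run
_SEED_C2 = 1
_SEED_CLASSIFY = 2
_SEED_KMEANS = 3


@dataclass
class RunConfig:
    peak_areas: str | Path
    descriptors: str | Path
    train: str | Path
    outdir: str | Path
    bd_code: str = "BD"
    epsilon: float = 1.0
    k_c2: int = 3
    folds: int = 5
    seed: int = 0
    models: tuple[str, ...] = ("SVM", "RF", "LR")
    alpha: float = 0.05
    n_init_c2: int = 50
    standardize: bool = False
    stratify: bool = False

    def validate(self) -> None:
        for name in ("peak_areas", "descriptors", "train"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} input not found: {p}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write all artifacts to ``outdir``.

    Returns the summary dictionary (also written as ``summary.json``):
    cluster sizes per method, mean CV accuracy per model x clustering,
    overlap counts against property-space K-means, and the descriptors
    with significantly different distributions across clusters.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"clusters": {}, "classification": {}, "overlap": {},
                     "descriptor_tests": {}}

    def stage(name):
        log.info("stage %s ...", name)
        return time.perf_counter()

    t = stage("read")
    train = read_train_config(config.train)
    peaks = read_peak_area_table(config.peak_areas, train, bd_code=config.bd_code)
    descriptors = read_descriptor_table(config.descriptors)
    log.info("read done in %.2fs", time.perf_counter() - t)

    t = stage("preprocess")
    pre = preprocess_compounds(peaks)
    _dump_json(pre.removal_log, outdir / "preprocess_log.json")
    log.info("preprocess kept %d compounds (%.2fs)",
             len(pre.table.compounds), time.perf_counter() - t)

    t = stage("metrics")
    profiles = all_profiles(pre.table, train)
    profiles_to_frame(profiles).to_csv(outdir / "removal_profiles.csv", index=False)
    log.info("metrics done (%.2fs)", time.perf_counter() - t)

    t = stage("cluster-c1")
    c1 = cluster_by_best_stage(profiles, train)
    c1.to_frame().to_csv(outdir / "clusters_c1.csv", index=False)
    summary["clusters"]["C1"] = {
        "k": c1.assignment.k,
        "sizes": {str(k): v for k, v in sorted(c1.assignment.sizes().items())},
        "unassignable": list(c1.unassignable),
    }
    log.info("C1: k=%d (%.2fs)", c1.assignment.k, time.perf_counter() - t)

    t = stage("cluster-c2")
    c2 = cluster_c2(profiles, k=config.k_c2, epsilon=config.epsilon,
                    seed=config.seed + _SEED_C2, n_init=config.n_init_c2)
    c2.to_frame().to_csv(outdir / "clusters_c2.csv", index=False)
    _dump_json(c2.report(), outdir / "clusters_c2_modes.json")
    summary["clusters"]["C2"] = {
        "k": c2.assignment.k,
        "sizes": {str(k): v for k, v in sorted(c2.assignment.sizes().items())},
        "cost": c2.kmodes.cost,
    }
    log.info("C2: k=%d cost=%d (%.2fs)", c2.assignment.k, c2.kmodes.cost,
             time.perf_counter() - t)

    t = stage("classify")
    for label, assignment in (("C1", c1.assignment), ("C2", c2.assignment)):
        X, y, ids, dropped = build_feature_matrix(descriptors, assignment)
        summary["classification"][label] = {"n": len(ids), "dropped": list(dropped)}
        for model in config.models:
            report = crossval_classify(
                X, y, model=model, k_folds=config.folds,
                seed=config.seed + _SEED_CLASSIFY,
                standardize=config.standardize, stratify=config.stratify,
            )
            _dump_json(report.to_dict(), outdir / f"cv_{label}_{model}.json")
            summary["classification"][label][model] = round(report.mean_accuracy, 6)
        importance = rf_feature_importance(X, y, seed=config.seed + _SEED_CLASSIFY)
        importance.to_frame().to_csv(outdir / f"importance_{label}.csv", index=False)
        summary["classification"][label]["rf_top_feature"] = importance.top_feature
    log.info("classification done (%.2fs)", time.perf_counter() - t)

    t = stage("concordance")
    for label, assignment in (("C1", c1.assignment), ("C2", c2.assignment)):
        ids = sorted(set(assignment.labels) & set(descriptors.compounds))
        sub = descriptors.data.loc[ids]
        removal = ClusterAssignment(
            method=assignment.method,
            labels={c: assignment.labels[c] for c in ids},
        )
        prop = kmeans_descriptors(sub, k=removal.k,
                                  seed=config.seed + _SEED_KMEANS)
        overlap = overlap_count(removal, prop)
        _dump_json(overlap.to_dict(), outdir / f"overlap_{label}.json")
        summary["overlap"][label] = {
            "matched_count": overlap.matched_count,
            "matched_percent": round(overlap.matched_percent, 6),
            "n": overlap.n,
        }
        tests = descriptor_tests_by_cluster(descriptors, removal,
                                            alpha=config.alpha)
        tests.to_csv(outdir / f"descriptor_tests_{label}.csv", index=False)
        summary["descriptor_tests"][label] = {
            "significant": sorted(tests.loc[tests["significant"], "feature"]),
            "alpha": config.alpha,
        }
    log.info("concordance done (%.2fs)", time.perf_counter() - t)

    _dump_json(summary, outdir / "summary.json")
    return summary
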