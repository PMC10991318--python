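"""End-to-end orchestration: load/generate -> outlier screening -> split ->
scale -> SMOTE -> RFE -> swarm-trained attention-GRU -> evaluation.

Stage order notes.  Outlier screening runs on the full table before the
train/test split (it is unsupervised and uses internally standardized
distances).  The feature scaler is then fit on the training partition only
and applied to the test partition, and SMOTE balances the training partition
only — balancing or scaling with test records would leak information into
evaluation.  Every stage's seed is derived deterministically from the single
pipeline seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import attgru, cluster, optimizer, rfe, smote
from .metrics import baselines, evaluate_scores
from .data import CVD_SCHEMA, Dataset, Scaler, Schema, load_table, stratified_split
from .synthetic import GenConfig, generate

__all__ = ["PipelineConfig", "run", "ablation"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run; defaults give the reference protocol."""

    # input: either a synthetic design or a CSV path (exactly one)
    gen: GenConfig | None = None
    input_csv: str | None = None
    schema: Schema = CVD_SCHEMA

    # stage toggles
    outlier_removal: bool = True
    use_smote: bool = True
    use_rfe: bool = True

    # stage parameters
    kmeans_k: int = 3
    min_cluster_fraction: float = 0.10
    smote_k: int = 5
    n_select: int = 5
    rfe_ranker: str = "logistic"
    hidden_units: tuple[int, int] = (8, 8)
    fitness_kind: str = "cross_entropy"
    population_size: int = 30
    iterations: int = 60
    weight_bound: float = 2.0
    test_fraction: float = 0.2
    knn_k: int = 5
    run_baselines: bool = True

    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.gen is None) == (self.input_csv is None):
            raise ValueError("provide exactly one of gen / input_csv")


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest.

    The manifest records per-stage record counts, the removed-outlier count,
    class counts before/after SMOTE, the selected features, the optimizer
    convergence history, and the final evaluation reports.
    """
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stages": {}, "timings_s": {}}
    t0 = time.perf_counter()

    # ---- input -----------------------------------------------------------
    if config.gen is not None:
        gen_cfg = dataclasses.replace(config.gen, seed=seeds[0])
        ds, gt = generate(gen_cfg)
        manifest["ground_truth_outliers"] = int(gt.outlier_indices.size)
    else:
        ds = load_table(config.input_csv, config.schema)
        gt = None
    manifest["stages"]["input"] = {"n": ds.n_records, "class_counts": ds.class_counts()}
    manifest["timings_s"]["input"] = time.perf_counter() - t0

    # ---- outlier screening (unsupervised, pre-split) ---------------------
    t0 = time.perf_counter()
    outlier_report = None
    if config.outlier_removal:
        X_clean, outlier_report = cluster.remove_outliers(
            ds.X, K=config.kmeans_k,
            min_cluster_fraction=config.min_cluster_fraction, seed=seeds[1],
        )
        keep = np.setdiff1d(np.arange(ds.n_records), outlier_report.removed_indices)
        if gt is not None:
            planted = set(gt.outlier_indices.tolist())
            found = set(outlier_report.removed_indices.tolist())
            manifest["outlier_recall"] = (
                len(planted & found) / len(planted) if planted else None
            )
        ds = ds.take(keep)
        manifest["stages"]["outlier_removal"] = {
            "n": ds.n_records,
            "removed": int(outlier_report.removed_indices.size),
            "silhouette_before": outlier_report.silhouette_before,
            "silhouette_after": outlier_report.silhouette_after,
        }
    manifest["timings_s"]["outlier_removal"] = time.perf_counter() - t0

    # ---- split and scale -------------------------------------------------
    t0 = time.perf_counter()
    split = stratified_split(ds, config.test_fraction, seed=seeds[2])
    train = ds.take(split.train_indices)
    test = ds.take(split.test_indices)
    scaler = Scaler.fit(train.X)
    train = Dataset(scaler.transform(train.X), train.y, train.schema)
    test = Dataset(scaler.transform(test.X), test.y, test.schema)
    manifest["stages"]["split"] = {
        "n_train": train.n_records, "n_test": test.n_records,
        "test_class_counts": test.class_counts(),
    }
    manifest["timings_s"]["split"] = time.perf_counter() - t0

    # ---- SMOTE (training partition only) ---------------------------------
    t0 = time.perf_counter()
    counts_before = train.class_counts()
    if config.use_smote:
        train = smote.balance(
            train, smote.SmoteConfig(k_neighbors=config.smote_k, seed=seeds[3])
        )
    manifest["stages"]["smote"] = {
        "enabled": config.use_smote,
        "class_counts_before": counts_before,
        "class_counts_after": train.class_counts(),
        "n": train.n_records,
    }
    manifest["timings_s"]["smote"] = time.perf_counter() - t0

    # ---- RFE -------------------------------------------------------------
    t0 = time.perf_counter()
    if config.use_rfe:
        rfe_result = rfe.rfe_rank(
            train.X, train.y, n_select=config.n_select,
            base_ranker=config.rfe_ranker, seed=seeds[4],
        )
        train = rfe.apply_selection(train, rfe_result)
        test = rfe.apply_selection(test, rfe_result)
        manifest["stages"]["rfe"] = {
            "selected": list(train.schema.feature_names),
            "ranking": rfe_result.ranking.tolist(),
        }
    else:
        rfe_result = None
    manifest["timings_s"]["rfe"] = time.perf_counter() - t0

    # ---- swarm-trained attention-GRU -------------------------------------
    t0 = time.perf_counter()
    net_cfg = attgru.AttGRUConfig(
        n_features_in=train.n_features, hidden_units=config.hidden_units
    )
    spec = attgru.FitnessSpec(kind=config.fitness_kind)
    Xtr, ytr = train.X, train.y

    def loss(vec: np.ndarray) -> float:
        return attgru.fitness(vec, Xtr, ytr, net_cfg, spec)

    opt_cfg = optimizer.HMSIConfig(
        dimensions=attgru.param_count(net_cfg),
        lower=-config.weight_bound, upper=config.weight_bound,
        population_size=config.population_size,
        max_iterations=config.iterations, seed=seeds[5],
    )
    best_vec, best_fit, history = optimizer.optimize(loss, opt_cfg)
    params = attgru.unflatten(best_vec, net_cfg)
    manifest["stages"]["train"] = {
        "n_parameters": attgru.param_count(net_cfg),
        "final_train_loss": best_fit,
        "fitness_kind": config.fitness_kind,
    }
    manifest["timings_s"]["train"] = time.perf_counter() - t0

    # ---- evaluation ------------------------------------------------------
    t0 = time.perf_counter()
    scores = attgru.forward_batch(test.X, params, net_cfg)
    reports = [evaluate_scores(test.y, scores, model_name="AttGRU-HMSI")]
    if config.run_baselines:
        reports += baselines(
            train, test, knn_k=config.knn_k, seed=seeds[6]
        )
    manifest["reports"] = [r.to_dict() for r in reports]
    majority = max(test.class_counts().values()) / test.n_records
    manifest["majority_class_rate"] = majority
    manifest["timings_s"]["evaluate"] = time.perf_counter() - t0

    manifest["_objects"] = {
        "params": params, "net_cfg": net_cfg, "history": history,
        "reports": reports, "outlier_report": outlier_report,
        "rfe_result": rfe_result, "scaler": scaler,
        "train": train, "test": test,
    }
    if config.outdir is not None:
        _write_artifacts(config, manifest)
    return manifest


def _write_artifacts(config: PipelineConfig, manifest: dict) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    objs = manifest["_objects"]
    public = {k: v for k, v in manifest.items() if k != "_objects"}
    (out / "manifest.json").write_text(json.dumps(public, indent=2), encoding="utf-8")
    optimizer.save_history(objs["history"], out / "convergence.csv")
    objs["scaler"].save(out / "scaler.tsv")
    if objs["outlier_report"] is not None:
        objs["outlier_report"].to_json(out / "outlier_report.json")
    with open(out / "reports.csv", "w", encoding="utf-8") as fh:
        fh.write("model,accuracy,recall,precision,f1,auc,tp,fp,tn,fn\n")
        for r in objs["reports"]:
            c = r.counts
            fh.write(
                f"{r.model_name},{r.accuracy},{r.recall},{r.precision},"
                f"{r.f1},{r.auc},{c.tp},{c.fp},{c.tn},{c.fn}\n"
            )
    main = objs["reports"][0]
    with open(out / "roc_points.csv", "w", encoding="utf-8") as fh:
        fh.write("fpr,tpr\n")
        for fpr, tpr in main.roc_points:
            fh.write(f"{fpr},{tpr}\n")
    if objs["rfe_result"] is not None:
        with open(out / "selected_features.csv", "w", encoding="utf-8") as fh:
            fh.write("Feature,Selected\n")
            full_names = (
                config.schema.feature_names if config.gen is None
                else config.gen.schema.feature_names
            )
            for name, sel in objs["rfe_result"].table(full_names):
                fh.write(f"{name},{sel}\n")


def ablation(
    base_config: PipelineConfig,
    arms: tuple[tuple[bool, bool], ...] = (
        (False, False), (False, True), (True, False), (True, True),
    ),
) -> list[dict]:
    """Controlled comparison over (SMOTE on/off, RFE on/off) arms.

    All arms share the pipeline seed (hence identical input draw, outlier
    screening, and test indices) and differ only in the toggled stages.
    Returns one summary dict per arm with the main model's metrics.
    """
    results = []
    for use_smote, use_rfe in arms:
        cfg = dataclasses.replace(
            base_config, use_smote=use_smote, use_rfe=use_rfe, outdir=None,
        )
        manifest = run(cfg)
        main = manifest["reports"][0]
        results.append({
            "smote": use_smote,
            "rfe": use_rfe,
            "n_features": len(manifest["_objects"]["test"].schema.feature_names),
            "test_indices_n": manifest["stages"]["split"]["n_test"],
            **{k: main[k] for k in ("accuracy", "recall", "precision", "f1", "auc")},
        })
    return results
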