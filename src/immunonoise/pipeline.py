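"""End-to-end orchestration of the anomaly-detection workflow.

Stage order: group statistics -> correlation PCA on the aggregated
EOP+LOP discovery sample -> sample-entropy screen of the residual
parameters (repeated on the validation cohort when present, which is used
for nothing else) -> two-step clustering importance + corroboration ->
aggregate LOF over the corroborated anomaly parameters -> k-NN
classification of EOP vs LOP with stratified cross-validation.

Every stage writes its report to the output directory; a run manifest
records the normalized configuration, seed, package versions, stage
timings and output files. With a fixed configuration the stage outputs
are byte-for-byte reproducible (timings live only in the manifest).
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, group_stats, synthetic
from .cohort import CohortTable, read_cohort, subset_by_group, write_cohort
from .entropy import entropy_screen
from .lof_knn import aggregate_lof, knn_classify_cv, scores_frame, select_k
from .pca import pca, scree_frame, split_subspaces, standardize
from .twostep import anomaly_corroboration, predictor_importance, two_step_cluster


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


_KNOWN_KEYS = {
    "input", "generator", "structure", "eps", "decimals", "entropy_threshold",
    "importance_cutoff", "k_lof", "k_nn", "folds", "seed", "out_dir",
    "n_preclusters", "use_entropy_flags_only",
}


@dataclass
class PipelineConfig:
    input: str | None = None          # cohort file; None -> synthetic cohort
    generator: str | None = None      # generator YAML; None -> packaged default
    structure: str = "collinear"      # structural preset for synthetic input
    eps: float = 0.01                 # eigenvalue threshold ("zero" on the scree)
    decimals: int = 2                 # entropy discretization (recorded precision)
    entropy_threshold: float = 3.0    # squared-entropy anomaly flag level
    importance_cutoff: float = 0.05
    k_lof: int = 10
    k_nn: int | str = "auto"          # odd int, or CV-selected
    folds: int = 10
    seed: int = 0
    out_dir: str = "immunonoise_out"
    n_preclusters: int = 20
    use_entropy_flags_only: bool = False


def validate_config(source) -> PipelineConfig:
    """Normalize a config mapping / YAML file; unknown keys are errors."""
    if isinstance(source, PipelineConfig):
        doc = asdict(source)
    elif isinstance(source, dict):
        doc = dict(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**doc)
    if cfg.eps < 0:
        raise ValueError("eps must be non-negative")
    if cfg.entropy_threshold < 0:
        raise ValueError("entropy_threshold must be non-negative")
    if not 0 <= cfg.importance_cutoff <= 1:
        raise ValueError("importance_cutoff must lie in [0, 1]")
    if cfg.k_lof < 1:
        raise ValueError("k_lof must be >= 1")
    if cfg.k_nn != "auto" and (int(cfg.k_nn) < 1 or int(cfg.k_nn) % 2 == 0):
        raise ValueError("k_nn must be 'auto' or a positive odd integer")
    if cfg.folds < 2:
        raise ValueError("folds must be >= 2")
    if cfg.n_preclusters < 2:
        raise ValueError("n_preclusters must be >= 2")
    if cfg.structure not in ("independent", "collinear"):
        raise ValueError(f"unknown structure {cfg.structure!r}")
    if cfg.input is None:
        gen = _generator_config(cfg)
        sizes = gen.group_sizes
        smallest = min(sizes.get("EOP", 1), sizes.get("LOP", 1))
        if cfg.folds > smallest:
            raise ValueError(
                f"folds={cfg.folds} exceeds the smallest discovery group "
                f"({smallest}); use folds <= {smallest}")
    return cfg


def _generator_config(cfg: PipelineConfig) -> synthetic.GeneratorConfig:
    if cfg.generator is not None:
        gen = synthetic.config_from_yaml(cfg.generator)
        return synthetic.with_seed(gen, cfg.seed)
    return synthetic.default_table2_config(seed=cfg.seed,
                                           structure=cfg.structure)


def _log(msg: str) -> None:
    print(f"[immunonoise] {msg}", file=sys.stderr)


def run_pipeline(config) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    cfg = validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "immunonoise",
        "version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "stages": [],
        "outputs": {},
    }
    with open(out / "config_normalized.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                manifest["failed_stage"] = name
                manifest["error"] = str(exc)
                with open(out / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=2, default=str)
                raise PipelineError(name, str(exc)) from exc
            dt = time.perf_counter() - t0
            manifest["stages"].append({"name": name, "seconds": round(dt, 3)})
            _log(f"{name}: done in {dt:.2f}s")
            return result
        return deco

    @stage("load_cohort")
    def cohort() -> CohortTable:
        if cfg.input is not None:
            c = read_cohort(cfg.input)
        else:
            c = synthetic.generate_cohort(_generator_config(cfg))
        write_cohort(c, out / "cohort.csv")
        manifest["outputs"]["cohort"] = "cohort.csv"
        manifest["group_sizes"] = c.group_sizes()
        return c

    discovery = subset_by_group(cohort, {"EOP", "LOP"})

    @stage("group_stats")
    def comparisons():
        comp = group_stats.compare_groups(discovery, "EOP", "LOP")
        df = group_stats.comparisons_to_frame(comp)
        df.to_csv(out / "group_stats.csv", index=False)
        manifest["outputs"]["group_stats"] = "group_stats.csv"
        manifest["n_significant"] = int(df["significant"].sum())
        return comp

    @stage("pca_subspace")
    def subspaces():
        z = standardize(discovery.values, discovery.parameter_names)
        decomp = pca(z, discovery.parameter_names)
        normal, residual = split_subspaces(decomp, eps=cfg.eps)
        scree_frame(decomp).to_csv(out / "scree.csv", index=False)
        pd.DataFrame({
            "parameter": discovery.parameter_names,
            "subspace": ["normal" if p in set(normal) else "residual"
                         for p in discovery.parameter_names],
        }).to_csv(out / "subspace.csv", index=False)
        manifest["outputs"]["scree"] = "scree.csv"
        manifest["outputs"]["subspace"] = "subspace.csv"
        manifest["n_residual"] = len(residual)
        return normal, residual

    normal, residual = subspaces

    @stage("entropy_anomaly")
    def entropy_reports():
        rep = entropy_screen(discovery, residual, decimals=cfg.decimals,
                             threshold=cfg.entropy_threshold)
        rep.to_frame().to_csv(out / "entropy_discovery.csv", index=False)
        manifest["outputs"]["entropy_discovery"] = "entropy_discovery.csv"
        if "VALIDATION" in cohort.group_labels:
            val = subset_by_group(cohort, {"VALIDATION"})
            vrep = entropy_screen(val, residual, decimals=cfg.decimals,
                                  threshold=cfg.entropy_threshold)
            vrep.to_frame().to_csv(out / "entropy_validation.csv", index=False)
            manifest["outputs"]["entropy_validation"] = "entropy_validation.csv"
        manifest["entropy_flags"] = list(rep.flags)
        return rep

    @stage("twostep_cluster")
    def importance():
        z = standardize(discovery.matrix(residual), residual)
        clus = two_step_cluster(z, n_preclusters=cfg.n_preclusters, k=2,
                                seed=cfg.seed)
        rep = predictor_importance(z, clus.labels, residual)
        pd.DataFrame({
            "patient_id": discovery.patient_ids,
            "cluster": clus.labels,
        }).to_csv(out / "cluster_assignment.csv", index=False)
        rep.to_frame().to_csv(out / "cluster_importance.csv", index=False)
        manifest["outputs"]["cluster_assignment"] = "cluster_assignment.csv"
        manifest["outputs"]["cluster_importance"] = "cluster_importance.csv"
        manifest["cluster_degenerate"] = bool(clus.degenerate)
        return rep

    @stage("corroboration")
    def features():
        corroborated = anomaly_corroboration(
            entropy_reports, importance,
            importance_cutoff=cfg.importance_cutoff)
        manifest["corroborated"] = sorted(corroborated)
        if cfg.use_entropy_flags_only or not corroborated:
            feats = list(entropy_reports.flags)
        else:
            feats = sorted(corroborated)
        if not feats:
            raise ValueError("no anomaly-candidate parameters to classify on")
        manifest["classifier_features"] = feats
        return feats

    @stage("lof_knn")
    def classification():
        lofs = aggregate_lof(discovery, features, k_lof=cfg.k_lof)
        scores_frame(discovery, lofs).to_csv(out / "lof_scores.csv",
                                             index=False)
        manifest["outputs"]["lof_scores"] = "lof_scores.csv"
        k_nn = (select_k(lofs.scores, discovery.group_labels,
                         folds=cfg.folds, seed=cfg.seed)
                if cfg.k_nn == "auto" else int(cfg.k_nn))
        rep = knn_classify_cv(lofs.scores, discovery.group_labels, k_nn=k_nn,
                              folds=cfg.folds, seed=cfg.seed)
        with open(out / "classification.json", "w") as fh:
            json.dump({"k_lof": cfg.k_lof, **rep.to_dict()}, fh, indent=2)
        manifest["outputs"]["classification"] = "classification.json"
        manifest["classification"] = rep.to_dict()
        return rep

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
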