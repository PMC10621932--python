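"""End-to-end orchestration: load -> preprocess -> phase 1 -> phase 2 -> evaluate.

A validated :class:`RunConfig` (YAML-friendly, unknown keys rejected)
drives the five-step run; every stage writes plain-text artifacts
(CSV/TSV/JSON) into the output directory so each phase can be inspected
or resumed independently.  A single root seed derives per-stage seeds
from a stable hash of the stage name, so toggling one stage never
perturbs the randomness of another.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import data_io
from .data_io import ExpressionDataset, SplitPlan
from .evaluation import EvaluationReport, evaluate_classifiers, reduction_percentage
from .phase1 import GAConfig, ig_filter, ga_select
from .phase2 import PSOConfig, phase2
from .synthetic import SyntheticSpec, generate

log = logging.getLogger("hmlfsm")

STAGES = ("preprocess", "phase1", "phase2", "evaluate")


# --------------------------------------------------------------------------
# configuration schema


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IOBlock(_Strict):
    path: Optional[str] = None
    orientation: str = "samples-in-rows"
    label_column: Optional[str] = None
    labels_path: Optional[str] = None
    positive_label: Optional[str] = None
    impute: Optional[str] = None
    synthetic: Optional[dict] = None  # SyntheticSpec fields instead of a file


class PreprocessBlock(_Strict):
    dedup: bool = True
    dedup_by_profile: bool = False
    normalize: bool = True
    shuffle: bool = True


class GABlock(_Strict):
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: Optional[float] = None
    elitism: int = 1
    tournament_size: int = 3
    fitness_size_weight: float = 0.0
    patience: int = 20


class Phase1Block(_Strict):
    ig_threshold: float = 0.0
    discretization: str = "mdl"
    classifier: str = "1nn"
    ga: GABlock = GABlock()


class PSOBlock(_Strict):
    swarm_size: int = 30
    iterations: int = 100
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    v_max: float = 4.0
    patience: int = 20
    pool_size: int = 100


class Phase2Block(_Strict):
    enabled: bool = True
    mrmr_k: Optional[int] = None
    scheme: str = "MID"
    classifier: str = "1nn"
    pso: PSOBlock = PSOBlock()


class SplitBlock(_Strict):
    kind: str = "holdout"
    train_fraction: float = 0.7
    k: int = 10
    stratified: bool = True


class EvalBlock(_Strict):
    classifiers: list[str] = ["svm", "nb", "dt", "rf", "knn", "mlp"]
    split: SplitBlock = SplitBlock()


class RunConfig(_Strict):
    io: IOBlock = IOBlock()
    preprocess: PreprocessBlock = PreprocessBlock()
    phase1: Phase1Block = Phase1Block()
    phase2: Phase2Block = Phase2Block()
    evaluation: EvalBlock = EvalBlock()
    seed: int = 0
    out_dir: str = "hmlfsm_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (root_seed * 2654435761)) % (2**31)


# --------------------------------------------------------------------------
# run report


@dataclass
class RunReport:
    input_summary: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    reductions: dict = field(default_factory=dict)
    phase1_genes: list = field(default_factory=list)
    phase2_genes: list = field(default_factory=list)
    phase1_metrics: dict = field(default_factory=dict)
    phase2_metrics: dict = field(default_factory=dict)
    elapsed: dict = field(default_factory=dict)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


# --------------------------------------------------------------------------
# helpers


def _load_input(cfg: RunConfig) -> ExpressionDataset:
    io = cfg.io
    if io.synthetic is not None:
        spec_kwargs = dict(io.synthetic)
        spec_kwargs.setdefault("seed", stage_seed(cfg.seed, "simulate"))
        ds, _ = generate(SyntheticSpec(**spec_kwargs))
        return ds
    if io.path is None:
        raise ValueError("config io block needs either a path or a synthetic spec")
    return data_io.load_expression_table(
        io.path,
        orientation=io.orientation,
        label_column=io.label_column,
        labels_path=io.labels_path,
        positive_label=io.positive_label,
        impute=io.impute,
    )


def _split_plan(block: SplitBlock, seed: int) -> SplitPlan:
    return SplitPlan(
        kind=block.kind,
        train_fraction=block.train_fraction,
        k=block.k,
        seed=seed,
        stratified=block.stratified,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _metrics_summary(report: EvaluationReport) -> dict:
    return {
        name: {k: round(v, 4) for k, v in m.items() if k != "confusion"}
        for name, m in report.rows.items()
    }


def _write_dataset(ds: ExpressionDataset, out: Path) -> None:
    frame = pd.DataFrame(ds.matrix, columns=ds.gene_ids.astype(str))
    frame.insert(0, "label", np.where(ds.labels == 1, "tumour", "normal"))
    frame.to_csv(out, index_label="sample")


def read_dataset_csv(path) -> ExpressionDataset:
    """Read back a dataset written by the pipeline (label column included)."""
    return data_io.load_expression_table(path, label_column="label")


# --------------------------------------------------------------------------
# full run


def run_full(config: RunConfig) -> RunReport:
    """Execute the whole two-phase pipeline and write all artifacts.

    Stage order: load -> dedup -> z-score -> shuffle -> IG filter -> GA ->
    evaluate (phase-1 report) -> mRMR + PSO -> evaluate (phase-2 report).
    Identical config + seed give identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2))
    report = RunReport(seed=config.seed, config=config.model_dump())
    stage = "load"
    try:
        t0 = time.perf_counter()
        ds = _load_input(config)
        classes, counts = np.unique(ds.labels, return_counts=True)
        report.input_summary = {
            "samples": ds.n_samples,
            "genes": ds.n_genes,
            "class_counts": {int(c): int(k) for c, k in zip(classes, counts)},
        }
        n_input = ds.n_genes

        stage = "preprocess"
        removed = 0
        if config.preprocess.dedup:
            ds, removed = data_io.remove_duplicate_genes(
                ds, by_profile=config.preprocess.dedup_by_profile
            )
        if config.preprocess.normalize:
            ds = data_io.zscore_normalize(ds)
        if config.preprocess.shuffle:
            ds = data_io.shuffle_samples(ds, seed=stage_seed(config.seed, "shuffle"))
        log.info("preprocess: %d duplicates removed, %d genes remain", removed, ds.n_genes)
        _write_dataset(ds, out / "preprocessed.csv")
        report.stage_counts["input"] = n_input
        report.stage_counts["preprocessed"] = ds.n_genes
        report.elapsed["preprocess"] = round(time.perf_counter() - t0, 3)

        stage = "phase1"
        t0 = time.perf_counter()
        p1_seed = stage_seed(config.seed, "phase1")
        filtered, scores = ig_filter(
            ds, threshold=config.phase1.ig_threshold, method=config.phase1.discretization
        )
        ga_cfg = GAConfig(**config.phase1.ga.model_dump(), seed=p1_seed)
        wrapper_plan = SplitPlan(kind="kfold", k=5, seed=p1_seed, stratified=True)
        ga_res = ga_select(
            filtered, config=ga_cfg, classifier=config.phase1.classifier, protocol=wrapper_plan
        )
        if not ga_res.best_mask.any():
            ga_res.best_mask[int(np.argmax(scores.gains[scores.gains > config.phase1.ig_threshold]))] = True
        ds_p1 = filtered.subset_genes(np.flatnonzero(ga_res.best_mask))
        pd.DataFrame(
            {"gene_id": scores.gene_ids.astype(str), "gain": scores.gains, "n_bins": scores.n_bins}
        ).to_csv(out / "ig_scores.tsv", sep="\t", index=False)
        data_io.write_gene_list(ds_p1.gene_ids, out / "phase1_genes.txt")
        (out / "ga_result.json").write_text(
            json.dumps(
                {
                    "best_fitness": ga_res.best_fitness,
                    "fitness_history": ga_res.fitness_history,
                    "evaluations": ga_res.evaluations,
                    "n_selected": int(ga_res.best_mask.sum()),
                },
                indent=2,
            )
        )
        _write_dataset(ds_p1, out / "phase1_dataset.csv")
        report.stage_counts["ig_filter"] = filtered.n_genes
        report.stage_counts["phase1"] = ds_p1.n_genes
        report.phase1_genes = [str(g) for g in ds_p1.gene_ids]
        report.elapsed["phase1"] = round(time.perf_counter() - t0, 3)
        log.info("phase1: %d genes after IG, %d after GA", filtered.n_genes, ds_p1.n_genes)

        stage = "evaluate_phase1"
        t0 = time.perf_counter()
        eval_seed = stage_seed(config.seed, "evaluate")
        plan = _split_plan(config.evaluation.split, eval_seed)
        rep1 = evaluate_classifiers(
            ds_p1,
            np.arange(ds_p1.n_genes),
            classifiers=config.evaluation.classifiers,
            plan=plan,
            seed=eval_seed,
        )
        (out / "phase1_eval.tsv").write_text(rep1.to_tsv())
        (out / "phase1_eval.json").write_text(rep1.to_json())
        report.phase1_metrics = _metrics_summary(rep1)
        report.elapsed["evaluate_phase1"] = round(time.perf_counter() - t0, 3)

        if config.phase2.enabled:
            stage = "phase2"
            t0 = time.perf_counter()
            p2_seed = stage_seed(config.seed, "phase2")
            pso_cfg = PSOConfig(**config.phase2.pso.model_dump(), seed=p2_seed)
            pso_plan = SplitPlan(kind="kfold", k=5, seed=p2_seed, stratified=True)
            subset, mrmr_scores, _state = phase2(
                ds_p1,
                mrmr_k=config.phase2.mrmr_k,
                pso_config=pso_cfg,
                classifier=config.phase2.classifier,
                protocol=pso_plan,
                scheme=config.phase2.scheme,
                return_details=True,
            )
            ds_p2 = ds_p1.subset_genes(subset.indices)
            order = mrmr_scores.selection_order
            pd.DataFrame(
                {
                    "rank": np.arange(1, len(order) + 1),
                    "gene_id": mrmr_scores.gene_ids[order].astype(str),
                    "relevance": mrmr_scores.relevance[order],
                    "greedy_score": mrmr_scores.greedy_scores,
                }
            ).to_csv(out / "mrmr.tsv", sep="\t", index=False)
            data_io.write_gene_list(ds_p2.gene_ids, out / "phase2_genes.txt")
            _write_dataset(ds_p2, out / "phase2_dataset.csv")
            report.stage_counts["phase2"] = ds_p2.n_genes
            report.phase2_genes = [str(g) for g in ds_p2.gene_ids]
            report.elapsed["phase2"] = round(time.perf_counter() - t0, 3)
            log.info("phase2: %d genes selected", ds_p2.n_genes)

            stage = "evaluate_phase2"
            t0 = time.perf_counter()
            rep2 = evaluate_classifiers(
                ds_p2,
                np.arange(ds_p2.n_genes),
                classifiers=config.evaluation.classifiers,
                plan=plan,
                seed=eval_seed,
            )
            (out / "phase2_eval.tsv").write_text(rep2.to_tsv())
            (out / "phase2_eval.json").write_text(rep2.to_json())
            report.phase2_metrics = _metrics_summary(rep2)
            report.elapsed["evaluate_phase2"] = round(time.perf_counter() - t0, 3)

        counts = report.stage_counts
        report.reductions = {
            "phase1_vs_input": reduction_percentage(counts["input"], counts["phase1"]),
        }
        if "phase2" in counts:
            report.reductions["phase2_vs_input"] = reduction_percentage(
                counts["input"], counts["phase2"]
            )
        (out / "run_report.json").write_text(report.to_json())
        return report
    except Exception as exc:
        # partial artifacts stay on disk for inspection
        (out / "FAILED.json").write_text(
            json.dumps({"stage": stage, "error": str(exc)}, indent=2)
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


# --------------------------------------------------------------------------
# resumable stage execution

_STAGE_INPUTS = {
    "phase1": ["preprocessed.csv"],
    "phase2": ["phase1_dataset.csv", "phase1_genes.txt"],
    "evaluate": ["phase2_dataset.csv", "phase2_genes.txt"],
}

_STAGE_BEFORE = {"phase1": "preprocess", "phase2": "phase1", "evaluate": "phase2"}


def run_stage(stage: str, config: RunConfig, workdir=None):
    """Run (or skip) one stage against artifacts already on disk.

    Prerequisite artifacts must exist and match the hashes recorded in
    ``manifest.json``; a completed stage with unchanged inputs is skipped.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages: {', '.join(STAGES)}")
    out = Path(workdir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}

    inputs = _STAGE_INPUTS.get(stage, [])
    for name in inputs:
        path = out / name
        if not path.exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {name}; run stage "
                f"{_STAGE_BEFORE[stage]!r} first"
            )
        recorded = manifest.get("hashes", {}).get(name)
        if recorded is not None and recorded != _sha256(path):
            raise ValueError(f"hash mismatch for {name}: artifact was modified")

    input_hashes = {name: _sha256(out / name) for name in inputs}
    entry = manifest.get("stages", {}).get(stage)
    if entry is not None and entry.get("inputs") == input_hashes:
        outputs_ok = all(
            (out / n).exists() and _sha256(out / n) == h
            for n, h in entry.get("outputs", {}).items()
        )
        if outputs_ok:
            log.info("stage %s skipped (up to date)", stage)
            return entry

    produced = _execute_stage(stage, config, out)
    manifest.setdefault("hashes", {}).update(input_hashes)
    output_hashes = {n: _sha256(out / n) for n in produced}
    manifest["hashes"].update(output_hashes)
    manifest.setdefault("stages", {})[stage] = {
        "inputs": input_hashes,
        "outputs": output_hashes,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest["stages"][stage]


def _execute_stage(stage: str, config: RunConfig, out: Path) -> list[str]:
    if stage == "preprocess":
        ds = _load_input(config)
        if config.preprocess.dedup:
            ds, _ = data_io.remove_duplicate_genes(ds, by_profile=config.preprocess.dedup_by_profile)
        if config.preprocess.normalize:
            ds = data_io.zscore_normalize(ds)
        if config.preprocess.shuffle:
            ds = data_io.shuffle_samples(ds, seed=stage_seed(config.seed, "shuffle"))
        _write_dataset(ds, out / "preprocessed.csv")
        return ["preprocessed.csv"]
    if stage == "phase1":
        ds = read_dataset_csv(out / "preprocessed.csv")
        p1_seed = stage_seed(config.seed, "phase1")
        filtered, scores = ig_filter(
            ds, threshold=config.phase1.ig_threshold, method=config.phase1.discretization
        )
        ga_cfg = GAConfig(**config.phase1.ga.model_dump(), seed=p1_seed)
        plan = SplitPlan(kind="kfold", k=5, seed=p1_seed, stratified=True)
        res = ga_select(filtered, config=ga_cfg, classifier=config.phase1.classifier, protocol=plan)
        ds_p1 = filtered.subset_genes(np.flatnonzero(res.best_mask))
        data_io.write_gene_list(ds_p1.gene_ids, out / "phase1_genes.txt")
        _write_dataset(ds_p1, out / "phase1_dataset.csv")
        return ["phase1_genes.txt", "phase1_dataset.csv"]
    if stage == "phase2":
        ds_p1 = read_dataset_csv(out / "phase1_dataset.csv")
        p2_seed = stage_seed(config.seed, "phase2")
        pso_cfg = PSOConfig(**config.phase2.pso.model_dump(), seed=p2_seed)
        plan = SplitPlan(kind="kfold", k=5, seed=p2_seed, stratified=True)
        subset = phase2(
            ds_p1,
            mrmr_k=config.phase2.mrmr_k,
            pso_config=pso_cfg,
            classifier=config.phase2.classifier,
            protocol=plan,
            scheme=config.phase2.scheme,
        )
        ds_p2 = ds_p1.subset_genes(subset.indices)
        data_io.write_gene_list(ds_p2.gene_ids, out / "phase2_genes.txt")
        _write_dataset(ds_p2, out / "phase2_dataset.csv")
        return ["phase2_genes.txt", "phase2_dataset.csv"]
    # evaluate
    ds_p2 = read_dataset_csv(out / "phase2_dataset.csv")
    eval_seed = stage_seed(config.seed, "evaluate")
    plan = _split_plan(config.evaluation.split, eval_seed)
    rep = evaluate_classifiers(
        ds_p2,
        np.arange(ds_p2.n_genes),
        classifiers=config.evaluation.classifiers,
        plan=plan,
        seed=eval_seed,
    )
    (out / "final_eval.tsv").write_text(rep.to_tsv())
    (out / "final_eval.json").write_text(rep.to_json())
    return ["final_eval.tsv", "final_eval.json"]
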