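"""End-to-end orchestration: generate/load → extract → detect → evaluate.

A run is described by a single :class:`RunConfig`; every artifact it
writes is stamped with the config hash and seed so predictions are
traceable to the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import evidence as ev
from .backends import HashingEmbedder, MockGenerationBackend
from .corpus import Corpus, read_corpus, write_predictions
from .detection import DetectionConfig, DetectionResult, detect_peae
from .evaluation import (
    EvalConfig,
    MetricEstimate,
    SurveillanceReport,
    bootstrap_metrics,
    surveillance,
)
from .synthetic import GeneratorConfig, generate_corpus

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    corpus_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    backend: str = "mock"
    n_boot: int = 1000
    ci_level: float = 0.95
    granularity: str = "year"
    seed: int = 0
    out_dir: Optional[str] = None


class RunResult(BaseModel):
    config_hash: str
    predictions: list[DetectionResult]
    metrics: Optional[dict[str, MetricEstimate]] = None
    surveillance: Optional[SurveillanceReport] = None
    reduction: Optional[dict] = None

    model_config = {"arbitrary_types_allowed": True}


def config_hash(config: RunConfig) -> str:
    """Fingerprint of every result-determining field (out_dir excluded)."""
    payload = json.dumps(
        config.model_dump(mode="json", exclude={"out_dir"}), sort_keys=True
    )
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]


def _make_backend(name: str):
    if name == "mock":
        return MockGenerationBackend()
    raise ValueError(
        f"unknown generation backend {name!r}; plug external backends in "
        "through run_pipeline(backend_obj=...)"
    )


def _load_corpus(config: RunConfig) -> Corpus:
    if config.corpus_path is not None:
        path = Path(config.corpus_path)
        if not path.exists():
            raise FileNotFoundError(f"corpus path does not exist: {path}")
        return read_corpus(path)
    gen = config.generator or GeneratorConfig(seed=config.seed)
    corpus, _ = generate_corpus(gen)
    return corpus


def run_pipeline(config: RunConfig, backend_obj=None) -> RunResult:
    """Execute the configured flow and (optionally) write artifacts."""
    corpus = _load_corpus(config)
    backend = backend_obj if backend_obj is not None else _make_backend(config.backend)
    embedder = (
        HashingEmbedder() if config.detection.retrieval == "semantic" else None
    )
    tag = config_hash(config)
    logger.info("run %s: %d charts in", tag, len(corpus.charts))

    results: list[DetectionResult] = []
    stage_counts: dict[str, dict[str, tuple[int, int]]] = {
        "raw": {},
        "filtered": {},
    }
    det = config.detection
    for chart in corpus.charts:
        raw_chunks = []
        summary_id = (
            chart.discharge_summary.note_id if chart.discharge_summary else None
        )
        for note in chart.notes:
            if summary_id is not None and note.note_id == summary_id:
                continue
            raw_chunks.extend(
                ev.chunk_note(
                    note, det.strategy, det.max_words, det.overlap, chart.patient_id
                )
            )
        stage_counts["raw"][chart.patient_id] = (
            len(raw_chunks),
            sum(c.word_count for c in raw_chunks),
        )
        result = detect_peae(chart, det, backend, embed_backend=embedder)
        kept = ev.extract_evidence(
            chart,
            det.retrieval,
            strategy=det.strategy,
            max_words=det.max_words,
            overlap=det.overlap,
            keyword_spec=det.keyword_spec,
            examples=det.examples,
            backend=embedder,
        )
        stage_counts["filtered"][chart.patient_id] = (
            len(kept),
            sum(c.word_count for c in kept),
        )
        results.append(result)

    reduction = ev.summarize_reduction(stage_counts).to_dict(orient="index")

    metrics_out = None
    surv = None
    golds = [c.gold_label for c in corpus.charts]
    if all(g is not None for g in golds) and golds:
        preds = [r.label for r in results]
        metrics_out = bootstrap_metrics(
            preds,
            golds,
            EvalConfig(n_boot=config.n_boot, ci_level=config.ci_level, seed=config.seed),
        )
        surv = surveillance(preds, golds, corpus.charts, config.granularity)

    run = RunResult(
        config_hash=tag,
        predictions=results,
        metrics=metrics_out,
        surveillance=surv,
        reduction=reduction,
    )
    if config.out_dir:
        _write_artifacts(config, run)
    return run


def _write_artifacts(config: RunConfig, run: RunResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True),
        encoding="utf-8",
    )
    write_predictions(
        (
            {
                "patient_id": r.patient_id,
                "label": r.label,
                "backend": r.backend,
                "config_tag": run.config_hash,
            }
            for r in run.predictions
        ),
        out / "predictions.tsv",
    )
    with (out / "detections.jsonl").open("w", encoding="utf-8") as fh:
        for r in run.predictions:
            fh.write(json.dumps(r.model_dump(mode="json"), sort_keys=True) + "\n")
    if run.metrics is not None:
        (out / "metrics.json").write_text(
            json.dumps(
                {k: v.model_dump(mode="json") for k, v in run.metrics.items()},
                indent=2,
                sort_keys=True,
            ),
            encoding="utf-8",
        )
    if run.surveillance is not None:
        (out / "surveillance.json").write_text(
            run.surveillance.model_dump_json(indent=2), encoding="utf-8"
        )
    (out / "reduction.json").write_text(
        json.dumps(run.reduction, indent=2, sort_keys=True), encoding="utf-8"
    )


def compare_conditions(base: RunConfig, backend_obj=None, lenient: bool = True) -> pd.DataFrame:
    """Run the 2×2 grid {keyword, semantic} × {discharge on, off}.

    Returns one row per condition in metric-table column order; in
    lenient mode a failing condition becomes a failure row instead of
    aborting the grid.
    """
    rows = []
    for retrieval in ("keyword", "semantic"):
        for include_discharge in (True, False):
            cfg = base.model_copy(deep=True)
            cfg.detection.retrieval = retrieval
            cfg.detection.include_discharge = include_discharge
            try:
                run = run_pipeline(cfg, backend_obj=backend_obj)
            except Exception as exc:
                if not lenient:
                    raise
                rows.append(
                    {
                        "retrieval": retrieval,
                        "discharge": include_discharge,
                        "error": str(exc),
                    }
                )
                continue
            row = {"retrieval": retrieval, "discharge": include_discharge, "error": ""}
            if run.metrics:
                for name in ("ppv", "sensitivity", "specificity", "npv", "f1"):
                    est = run.metrics[name]
                    row[name] = est.boot_mean
                    row[f"{name}_ci"] = (est.ci_low, est.ci_high)
            rows.append(row)
    return pd.DataFrame(rows)
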