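"""PEAE detection: prompt assembly, response classification, orchestration.

The detection prompt aggregates everything known about one stay — the
temporal facts, the dated evidence chunks, and (optionally) the six
extracted discharge sections — into a single binary question: did this
patient develop a pulmonary embolism after admission, as a
hospital-acquired adverse event?  The generated answer is classified by
a first-sentence heuristic: label 1 iff the first sentence contains the
word "yes" (case-insensitive, word-boundary).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import logging
import re
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .corpus import PatientChart
from .discharge import (
    SECTION_FIELDS,
    SECTION_TITLES,
    DischargeInfo,
    GenerationBackend,
    extract_discharge_info,
)
from .evidence import (
    Chunk,
    EmbeddingBackend,
    ExampleSentenceSet,
    KeywordSpec,
    SemanticFilterConfig,
    extract_evidence,
)
from .prompts import PromptDialect, get_dialect, load_prompts

logger = logging.getLogger(__name__)


class EvidenceBundle(BaseModel):
    """Per-patient material assembled for detection."""

    patient_id: str
    evidence_chunks: list[Chunk] = Field(default_factory=list)
    discharge_info: Optional[DischargeInfo] = None
    admission_date: dt.date
    discharge_date: dt.date

    @model_validator(mode="after")
    def _ordered(self) -> "EvidenceBundle":
        if self.admission_date > self.discharge_date:
            raise ValueError("admission_date must not exceed discharge_date")
        self.evidence_chunks = sorted(self.evidence_chunks, key=lambda c: c.timestamp)
        return self


class DetectionResult(BaseModel):
    patient_id: str
    label: int
    raw_response: str
    justification: str
    prompt_hash: str
    backend: str = ""
    dialect: str = "plain"
    flags: list[str] = Field(default_factory=list)


class DetectionConfig(BaseModel):
    """Pipeline knobs for a single detection pass."""

    retrieval: str = "keyword"  # keyword | semantic
    include_discharge: bool = True
    dialect: str = "plain"
    strategy: str = "paragraph"
    max_words: int = 128
    overlap: int = 0
    top_percent: float = 5.0
    aggregation: str = "max"
    max_chars: Optional[int] = None
    lenient: bool = True
    keyword_spec: KeywordSpec = Field(default_factory=KeywordSpec)
    examples: ExampleSentenceSet = Field(default_factory=ExampleSentenceSet)


def build_detection_prompt(
    bundle: EvidenceBundle,
    dialect: PromptDialect,
    include_discharge: bool = True,
    max_chars: Optional[int] = None,
) -> str:
    """Render the detection prompt for one patient.

    Sections appear in a fixed order: task instruction, temporal facts,
    dated evidence chunks (oldest first), discharge sections (when
    requested and extraction did not fail), output instruction.  Dialect
    wrapping is applied last and never alters the payload.  When a
    ``max_chars`` budget is exceeded, the oldest evidence chunks are
    dropped first (truncations are logged).
    """
    tpl = load_prompts()["detection"]

    def evidence_lines(chunks: list[Chunk]) -> list[str]:
        if not chunks:
            return [tpl["empty_evidence"]]
        return [
            f"- [{c.timestamp.date().isoformat()}] {' '.join(c.text.split())}"
            for c in chunks
        ]

    def render(chunks: list[Chunk]) -> str:
        parts = [
            tpl["instruction"].rstrip(),
            "",
            f"ADMISSION DATE: {bundle.admission_date.isoformat()}",
            f"DISCHARGE DATE: {bundle.discharge_date.isoformat()}",
            "",
            tpl["evidence_header"],
            *evidence_lines(chunks),
        ]
        info = bundle.discharge_info
        if include_discharge and info is not None and info.status != "failed":
            parts += ["", tpl["discharge_header"]]
            parts += [
                f"{SECTION_TITLES[f]}: {getattr(info, f)}" for f in SECTION_FIELDS
            ]
        parts += ["", tpl["output_instruction"].rstrip()]
        return "\n".join(parts)

    chunks = list(bundle.evidence_chunks)
    payload = render(chunks)
    dropped = 0
    while max_chars is not None and len(payload) > max_chars and len(chunks) > 1:
        chunks.pop(0)  # oldest first
        dropped += 1
        payload = render(chunks)
    if dropped:
        logger.info(
            "truncated %d oldest evidence chunks for %s to fit %d chars",
            dropped,
            bundle.patient_id,
            max_chars,
        )
    return dialect.wrap(payload)


_SENTENCE_END = re.compile(r"[.!?\n]")
_YES = re.compile(r"(?<!\w)yes(?!\w)", re.IGNORECASE)


def classify_response(raw: str) -> tuple[int, str]:
    """First-sentence yes/no heuristic.

    The first sentence runs up to the first of ``. ! ?`` or newline; the
    label is 1 iff it contains the word "yes" at a word boundary,
    case-insensitively ("yesterday" never fires).  The justification is
    the trimmed remainder.  Empty input classifies as 0.
    """
    if not raw:
        return 0, ""
    m = _SENTENCE_END.search(raw)
    first = raw[: m.start()] if m else raw
    rest = raw[m.end():].strip() if m else ""
    return (1 if _YES.search(first) else 0), rest


def detect_peae(
    chart: PatientChart,
    config: DetectionConfig,
    backend: GenerationBackend,
    embed_backend: Optional[EmbeddingBackend] = None,
) -> DetectionResult:
    """Run the full per-patient flow: extract → prompt → generate → classify."""
    if not chart.notes:
        raise ValueError(f"chart {chart.patient_id} has no notes")
    dialect = get_dialect(config.dialect)
    flags: list[str] = []

    chunks = extract_evidence(
        chart,
        config.retrieval,
        strategy=config.strategy,
        max_words=config.max_words,
        overlap=config.overlap,
        keyword_spec=config.keyword_spec,
        examples=config.examples,
        backend=embed_backend,
        semantic_config=SemanticFilterConfig(
            top_percent=config.top_percent, aggregation=config.aggregation
        ),
    )
    if not chunks:
        flags.append("no_evidence")

    discharge_info = None
    if config.include_discharge and chart.discharge_summary is not None:
        discharge_info = extract_discharge_info(chart, backend, dialect)
        if discharge_info.status != "ok":
            flags.append(f"discharge_{discharge_info.status}")

    bundle = EvidenceBundle(
        patient_id=chart.patient_id,
        evidence_chunks=chunks,
        discharge_info=discharge_info,
        admission_date=chart.admission_date,
        discharge_date=chart.discharge_date,
    )
    prompt = build_detection_prompt(
        bundle, dialect, config.include_discharge, config.max_chars
    )
    try:
        raw = backend.generate(prompt)
    except Exception as exc:
        if not config.lenient:
            raise
        raw = ""
        flags.append(f"backend_failure: {exc}")
    if not raw:
        flags.append("empty_generation")
    label, justification = classify_response(raw)
    return DetectionResult(
        patient_id=chart.patient_id,
        label=label,
        raw_response=raw,
        justification=justification,
        prompt_hash=hashlib.sha256(prompt.encode("utf-8")).hexdigest()[:16],
        backend=getattr(backend, "name", "unknown"),
        dialect=dialect.name,
        flags=flags,
    )
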