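"""Chart data model and corpus I/O.

A corpus is a line-delimited UTF-8 JSON file: the first line is a header
record carrying provenance (``schema_version``, ``source``, optional
``seed``); every subsequent line is one :class:`PatientChart`.  The format
is streamable and diff-friendly, and ``read_corpus(write_corpus(c))``
reproduces ``c`` field for field.

Dates are ISO-8601; note timestamps are timezone-naive (the source EMR
timezone is assumed uniform).  A patient appears at most once: cohorts
retain a single admission per patient, so a duplicate ``patient_id`` is a
data error, fatal in strict mode.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel, Field, field_validator

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: ICD-10 shape: a letter, two digits, optional dotted subcode.
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(?:\.[A-Z0-9]{1,4})?$")


class CorpusFormatError(ValueError):
    """Raised for unreadable or structurally invalid corpus files."""


class ClinicalNote(BaseModel):
    """One timestamped free-text note of a hospital stay."""

    note_id: str
    note_type: str
    timestamp: dt.datetime
    text: str
    allow_empty: bool = False


class DiagnosisCode(BaseModel):
    """A coded discharge diagnosis with its diagnosis-type indicator."""

    code: str
    present_on_admission: bool = False

    @field_validator("code")
    @classmethod
    def _check_icd10(cls, v: str) -> str:
        if not ICD10_PATTERN.match(v):
            raise ValueError(f"not an ICD-10-shaped code: {v!r}")
        return v


class PatientChart(BaseModel):
    """One hospitalization: notes, dates and (optionally) gold annotation.

    Demographic fields are optional; they feed cohort summaries only and
    are absent in minimal corpora.
    """

    patient_id: str
    admission_date: dt.date
    discharge_date: dt.date
    notes: list[ClinicalNote] = Field(default_factory=list)
    discharge_summary: Optional[ClinicalNote] = None
    diagnosis_codes: Optional[list[DiagnosisCode]] = None
    gold_label: Optional[int] = None
    age: Optional[int] = None
    sex: Optional[str] = None
    died_in_hospital: Optional[bool] = None
    n_comorbidities: Optional[int] = None

    @field_validator("gold_label")
    @classmethod
    def _check_label(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v not in (0, 1):
            raise ValueError("gold_label must be 0 or 1")
        return v

    @property
    def length_of_stay_days(self) -> int:
        return (self.discharge_date - self.admission_date).days


class Corpus(BaseModel):
    """A collection of charts plus provenance metadata."""

    charts: list[PatientChart] = Field(default_factory=list)
    source: str = "unknown"
    seed: Optional[int] = None
    schema_version: int = SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.charts)

    def by_id(self) -> dict[str, PatientChart]:
        return {c.patient_id: c for c in self.charts}


def validate_chart(
    chart: PatientChart,
    require_discharge_summary: bool = False,
    strict_timestamps: bool = True,
) -> list[str]:
    """Return violation descriptors for ``chart`` (empty list = valid).

    Violations are data, not exceptions: this function is total over any
    :class:`PatientChart` instance.  ``strict_timestamps`` enforces that
    every note timestamp lies within ``[admission - 30d, discharge]``
    (the synthetic-corpus contract); when off, out-of-range timestamps
    are warnings, not violations.
    """
    violations: list[str] = []
    if chart.admission_date > chart.discharge_date:
        violations.append("date_order")
    if require_discharge_summary and chart.discharge_summary is None:
        violations.append("missing_discharge_summary")
    timestamps = [n.timestamp for n in chart.notes]
    if timestamps != sorted(timestamps):
        violations.append("notes_unsorted")
    lo = dt.datetime.combine(chart.admission_date - dt.timedelta(days=30), dt.time.min)
    hi = dt.datetime.combine(chart.discharge_date, dt.time.max)
    for note in chart.notes:
        if not note.text and not note.allow_empty:
            violations.append(f"empty_note_text:{note.note_id}")
        if not (lo <= note.timestamp <= hi):
            if strict_timestamps:
                violations.append(f"timestamp_out_of_range:{note.note_id}")
            else:
                logger.warning(
                    "note %s of %s outside stay window", note.note_id, chart.patient_id
                )
    return violations


def read_corpus(
    path: str | Path,
    strict: bool = False,
    errors: Optional[list[tuple[int, str]]] = None,
) -> Corpus:
    """Read a line-delimited corpus file.

    Malformed lines are collected as ``(line_number, message)`` pairs in
    ``errors`` (and logged) unless ``strict`` is set, in which case the
    first malformed line raises.  A duplicate ``patient_id`` is fatal in
    strict mode and otherwise dropped with a report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    collected: list[tuple[int, str]] = errors if errors is not None else []
    charts: list[PatientChart] = []
    seen: set[str] = set()
    header: dict = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                msg = f"line {lineno}: invalid JSON ({exc})"
                if strict:
                    raise CorpusFormatError(msg) from exc
                collected.append((lineno, msg))
                continue
            if lineno == 1 and isinstance(record, dict) and "schema_version" in record and "patient_id" not in record:
                header = record
                continue
            try:
                chart = PatientChart.model_validate(record)
            except Exception as exc:  # pydantic ValidationError
                msg = f"line {lineno}: schema violation ({exc})"
                if strict:
                    raise CorpusFormatError(msg) from exc
                collected.append((lineno, msg))
                continue
            if chart.patient_id in seen:
                msg = f"line {lineno}: duplicate patient_id {chart.patient_id!r}"
                if strict:
                    raise CorpusFormatError(msg)
                collected.append((lineno, msg))
                continue
            seen.add(chart.patient_id)
            charts.append(chart)
    for _, msg in collected:
        logger.warning("read_corpus %s: %s", path, msg)
    return Corpus(
        charts=charts,
        source=str(header.get("source", "unknown")),
        seed=header.get("seed"),
        schema_version=int(header.get("schema_version", SCHEMA_VERSION)),
    )


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write ``corpus`` as line-delimited JSON; byte-stable for a fixed corpus."""
    path = Path(path)
    header = {
        "schema_version": corpus.schema_version,
        "source": corpus.source,
        "seed": corpus.seed,
    }
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps(header, sort_keys=True, ensure_ascii=False) + "\n")
        for chart in corpus.charts:
            payload = chart.model_dump(mode="json", exclude_none=True)
            fh.write(json.dumps(payload, sort_keys=True, ensure_ascii=False) + "\n")


def write_predictions(rows: Iterable[dict], path: str | Path) -> None:
    """Write predictions as a TSV of (patient_id, label, backend, config_tag)."""
    path = Path(path)
    cols = ["patient_id", "label", "backend", "config_tag"]
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
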