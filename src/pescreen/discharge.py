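"""Discharge-summary information extraction.

A discharge summary condenses the whole stay into a handful of sections.
Rather than segmenting by headers ourselves, the generation backend is
instructed to return a JSON object with six canonical keys: reason for
hospitalization, significant findings, procedures and treatments,
medical history, discharge condition, and patient and family
instructions.  Parsing is deliberately forgiving — generated structured
output is noisy — and total: any input yields a :class:`DischargeInfo`,
never an exception.
"""

from __future__ import annotations

import json
import re
from typing import Literal, Optional, Protocol

from pydantic import BaseModel

from .corpus import PatientChart
from .prompts import PromptDialect, load_prompts

SECTION_FIELDS = [
    "reason_for_hospitalization",
    "significant_findings",
    "procedures_and_treatments",
    "medical_history",
    "discharge_condition",
    "patient_family_instructions",
]

#: Canonical display titles (used in prompts and synthetic summaries).
SECTION_TITLES = {
    "reason_for_hospitalization": "Reason for Hospitalization",
    "significant_findings": "Significant Findings",
    "procedures_and_treatments": "Procedures and Treatments",
    "medical_history": "Medical History",
    "discharge_condition": "Discharge Condition",
    "patient_family_instructions": "Patient and Family Instructions",
}

_KEY_ALIASES = {
    "reason_for_hospitalization": {
        "reason for hospitalization",
        "reason for hospitalisation",
        "reason for admission",
    },
    "significant_findings": {
        "significant findings",
        "significant findings for the current admission",
    },
    "procedures_and_treatments": {
        "procedures and treatments",
        "procedures and treatments provided",
    },
    "medical_history": {"medical history", "past medical history"},
    "discharge_condition": {"discharge condition", "condition at discharge"},
    "patient_family_instructions": {
        "patient and family instructions",
        "patient family instructions",
        "patient instructions",
    },
}


class MissingDischargeSummaryError(ValueError):
    pass


class DischargeInfo(BaseModel):
    reason_for_hospitalization: str = ""
    significant_findings: str = ""
    procedures_and_treatments: str = ""
    medical_history: str = ""
    discharge_condition: str = ""
    patient_family_instructions: str = ""
    status: Literal["ok", "partial", "failed"] = "failed"
    error: Optional[str] = None

    def sections(self) -> dict[str, str]:
        return {f: getattr(self, f) for f in SECTION_FIELDS}


class GenerationBackend(Protocol):
    """Contract: total text-to-text generation; see detection module."""

    name: str

    def generate(self, prompt: str) -> str: ...


def _normalize_key(key: str) -> str:
    key = re.sub(r"[^a-z0-9]+", " ", key.lower())
    return key.strip()


def _match_field(key: str) -> Optional[str]:
    norm = _normalize_key(key)
    for field, aliases in _KEY_ALIASES.items():
        if norm in aliases:
            return field
    for field, aliases in _KEY_ALIASES.items():
        if any(norm.startswith(a) or a.startswith(norm) for a in aliases if norm):
            return field
    return None


def build_discharge_prompt(summary_text: str, dialect: PromptDialect) -> str:
    """Prompt instructing structured extraction of the six sections."""
    if not summary_text or not summary_text.strip():
        raise ValueError("discharge summary text is empty")
    tpl = load_prompts()["discharge"]
    payload = "\n".join(
        [
            tpl["instruction"].rstrip(),
            "",
            tpl["summary_header"],
            summary_text.rstrip(),
            tpl["summary_footer"],
        ]
    )
    return dialect.wrap(payload)


def parse_discharge_response(raw: str) -> DischargeInfo:
    """Parse a generated response into a :class:`DischargeInfo`.

    The first JSON object found anywhere in ``raw`` wins (code fences
    and leading prose are tolerated by construction: we scan for a
    decodable ``{...}`` block).  Keys are matched case- and
    punctuation-insensitively; missing keys become empty strings.
    Unparseable input yields ``status="failed"``, never an exception.
    """
    info = DischargeInfo()
    if not raw:
        return info
    decoder = json.JSONDecoder()
    obj = None
    for i, ch in enumerate(raw):
        if ch != "{":
            continue
        try:
            candidate, _ = decoder.raw_decode(raw, i)
        except ValueError:
            continue
        if isinstance(candidate, dict):
            obj = candidate
            break
    if obj is None:
        return info
    found = 0
    for key, value in obj.items():
        field = _match_field(str(key))
        if field is None:
            continue
        setattr(info, field, "" if value is None else str(value))
        found += 1
    if found >= len(SECTION_FIELDS):
        info.status = "ok"
    elif found >= 1:
        info.status = "partial"
    return info


def extract_discharge_info(
    chart: PatientChart, backend: GenerationBackend, dialect: PromptDialect
) -> DischargeInfo:
    """build prompt → generate → parse, for one chart's discharge summary."""
    if chart.discharge_summary is None or not chart.discharge_summary.text.strip():
        raise MissingDischargeSummaryError(
            f"missing_discharge_summary:{chart.patient_id}"
        )
    prompt = build_discharge_prompt(chart.discharge_summary.text, dialect)
    try:
        raw = backend.generate(prompt)
    except Exception as exc:
        return DischargeInfo(status="failed", error=f"backend_failure: {exc}")
    return parse_discharge_response(raw)
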