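"""Synthetic chart-corpus generator with exact gold bookkeeping.

The generator emulates the statistical shape the detection framework
assumes: rare hospital-acquired PE (default prevalence 0.4%), stays
admitted across a 2017-2022 window, a dozen note types drawn from a
large vocabulary, six-section discharge summaries, label-consistent
ICD codes, and — on gold-negative charts — confounding mentions drawn
from the error taxonomy the framework must survive: negated PE,
historical PE, PE present on admission, pulmonary-edema terminology and
anticoagulant-prophylaxis mentions.

Text is template-based, not neural: determinism and exact span
bookkeeping outweigh linguistic realism for a test fixture.  Every
planted sentence is recorded with its character span, so downstream
stages can be audited chunk by chunk.  The convention that a PE counts
as hospital-acquired iff it is documented ≥2 days after admission is a
synthetic-world definition, echoed in the generation manifest.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .corpus import ClinicalNote, Corpus, DiagnosisCode, PatientChart
from .discharge import SECTION_FIELDS, SECTION_TITLES

CONFOUNDER_CATEGORIES = (
    "negated_pe",
    "historical_pe",
    "poa_pe",
    "pulmonary_edema",
    "prophylaxis_mention",
)

#: template id -> (category, template text).  Affirming templates carry
#: both a retrieval keyword and a phrase the rule-mock affirms; negation
#: templates carry cues in the positions the mock inspects — except
#: ``neg_ruled_out``, whose cue *follows* the mention and therefore
#: slips past prefix-scoped negation handling (a deliberate hard case).
TEMPLATES: dict[str, tuple[str, str]] = {
    "affirm_ctpa": (
        "affirming",
        "CTPA demonstrates acute pulmonary embolism in the {side} lower lobe.",
    ),
    "affirm_ct": (
        "affirming",
        "CT chest with contrast reveals new pulmonary embolus in a {side} segmental branch.",
    ),
    "affirm_vq": (
        "affirming",
        "Ventilation-perfusion scan is consistent with acute pulmonary embolism.",
    ),
    "affirm_pe": (
        "affirming",
        "Imaging confirms acute PE and therapeutic anticoagulation was initiated.",
    ),
    "neg_no_evidence": ("negated_pe", "No evidence of acute pulmonary embolism on CTPA."),
    "neg_negative_for": ("negated_pe", "CT chest negative for acute pulmonary embolism."),
    "neg_ruled_out": ("negated_pe", "Acute pulmonary embolism was ruled out by imaging."),
    "neg_not": ("negated_pe", "Not consistent with acute PE on repeat imaging."),
    "hist_pe": (
        "historical_pe",
        "History of acute pulmonary embolism in {year}, treated and resolved.",
    ),
    "edema": (
        "pulmonary_edema",
        "Chest radiograph shows pulmonary edema, improving with diuresis.",
    ),
    "prophylaxis": (
        "prophylaxis_mention",
        "Subcutaneous heparin administered for thrombosis prophylaxis.",
    ),
}

AFFIRMING_TEMPLATE_IDS = [k for k, (cat, _) in TEMPLATES.items() if cat == "affirming"]
_NEGATED_TEMPLATE_IDS = [k for k, (cat, _) in TEMPLATES.items() if cat == "negated_pe"]

# Benign filler; deliberately free of PE keywords.
_FILLER_SENTENCES = [
    "Patient resting comfortably, vital signs stable.",
    "Tolerating oral diet, ambulating in the hallway with assistance.",
    "Afebrile overnight, blood pressure {sys}/{dia}, heart rate {hr}.",
    "Pain controlled with scheduled analgesia.",
    "Wound edges clean and dry, dressing changed.",
    "Physiotherapy session completed, gait steady with walker.",
    "Electrolytes within normal limits this morning.",
    "Family meeting held to discuss goals of care.",
    "Urine output adequate over the past shift.",
    "Chest auscultation clear bilaterally, no adventitious sounds.",
    "Medication reconciliation completed by pharmacy.",
    "Blood glucose {bg} before breakfast, sliding scale applied.",
    "Social work consulted regarding home supports.",
    "Repeat bloodwork ordered for the morning.",
    "Patient reports improved energy compared with yesterday.",
]

_COMPLAINTS = [
    "community-acquired pneumonia",
    "acute cholecystitis",
    "exacerbation of heart failure",
    "hip fracture after a mechanical fall",
    "small bowel obstruction",
    "urosepsis",
    "elective knee arthroplasty",
]

_BACKGROUND_ICD = ["I10", "E11.9", "J18.9", "N17.9", "K21.9", "E78.5", "F32.9", "M17.1"]

_BASE_NOTE_TYPES = [
    "progress note",
    "nursing note",
    "consultation note",
    "physician assessment",
    "operative report",
    "emergency department note",
    "pharmacy note",
    "physiotherapy note",
    "social work note",
    "respiratory therapy note",
    "dietitian note",
    "transfer summary",
]

#: ~120-type vocabulary emulating the breadth of hospital note types.
NOTE_TYPE_POOL: list[str] = _BASE_NOTE_TYPES + [
    f"{base} ({unit})"
    for base in _BASE_NOTE_TYPES[:9]
    for unit in (
        "cardiology",
        "general surgery",
        "internal medicine",
        "orthopedics",
        "icu",
        "oncology",
        "neurology",
        "urology",
        "respirology",
        "geriatrics",
        "obstetrics",
        "psychiatry",
    )
]

IMAGING_NOTE_TYPE = "diagnostic imaging report"


class GeneratorConfig(BaseModel):
    n_patients: int = 1000
    prevalence: float = 0.004
    start_date: dt.date = dt.date(2017, 1, 1)
    end_date: dt.date = dt.date(2022, 12, 31)
    n_note_types: int = 12
    notes_per_patient_mean: float = 6.0
    confounder_rates: dict[str, float] = Field(
        default_factory=lambda: {c: 0.02 for c in CONFOUNDER_CATEGORIES}
    )
    #: chance a gold-positive chart receives an I26 code (undercoding is
    #: the norm for adverse events in administrative data)
    icd_sensitivity: float = 0.4
    #: chance a confounder-bearing negative chart is miscoded I26
    icd_miscode_rate: float = 0.2
    los_shift_for_positives: bool = True
    seed: int = 0

    @field_validator("n_patients")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("n_patients must be >= 0")
        return v

    @field_validator("prevalence", "icd_sensitivity", "icd_miscode_rate")
    @classmethod
    def _proportion(cls, v: float) -> float:
        if not 0 <= v <= 1:
            raise ValueError("proportions must lie in [0, 1]")
        return v

    @field_validator("confounder_rates")
    @classmethod
    def _rates(cls, v: dict[str, float]) -> dict[str, float]:
        for cat, rate in v.items():
            if cat not in CONFOUNDER_CATEGORIES:
                raise ValueError(f"unknown confounder category {cat!r}")
            if not 0 <= rate <= 1:
                raise ValueError("confounder rates must lie in [0, 1]")
        return v


class PlantedSpan(BaseModel):
    note_id: str
    start: int
    end: int
    timestamp: dt.datetime
    template_id: str
    category: str


class GoldAnnotation(BaseModel):
    patient_id: str
    label: int
    planted_evidence: list[PlantedSpan] = Field(default_factory=list)
    planted_confounders: list[PlantedSpan] = Field(default_factory=list)


def plant_sentence(
    template_id: str,
    slots: dict[str, object],
    note: ClinicalNote,
    position: int,
) -> tuple[ClinicalNote, PlantedSpan]:
    """Insert an instantiated template into ``note`` at ``position``.

    The sentence is inserted as its own paragraph (a blank-line
    separator is added when needed) and its exact character span in the
    updated note text is returned.
    """
    if template_id not in TEMPLATES:
        raise KeyError(f"unknown template {template_id!r}")
    if position > len(note.text) or position < 0:
        raise ValueError(
            f"position {position} outside note text of length {len(note.text)}"
        )
    category, template = TEMPLATES[template_id]
    sentence = template.format(**slots)
    before = note.text[:position]
    sep = "" if (not before or before.endswith("\n\n")) else "\n\n"
    new_text = before + sep + sentence + note.text[position:]
    start = position + len(sep)
    updated = note.model_copy(update={"text": new_text})
    span = PlantedSpan(
        note_id=note.note_id,
        start=start,
        end=start + len(sentence),
        timestamp=note.timestamp,
        template_id=template_id,
        category=category,
    )
    return updated, span


def _filler_text(rng: np.random.Generator, n_paragraphs: int) -> str:
    paragraphs = []
    for _ in range(n_paragraphs):
        k = int(rng.integers(1, 3))
        idx = rng.integers(0, len(_FILLER_SENTENCES), size=k)
        sentences = [
            _FILLER_SENTENCES[i].format(
                sys=int(rng.integers(100, 150)),
                dia=int(rng.integers(55, 95)),
                hr=int(rng.integers(55, 110)),
                bg=round(float(rng.uniform(4.0, 12.0)), 1),
            )
            for i in idx
        ]
        paragraphs.append(" ".join(sentences))
    return "\n\n".join(paragraphs)


def _discharge_summary_text(
    rng: np.random.Generator,
    complaint: str,
    label: int,
    event_day: Optional[int],
    n_comorbidities: int,
) -> str:
    if label == 1:
        findings = (
            f"The patient developed acute pulmonary embolism on hospital day "
            f"{event_day} and was started on therapeutic anticoagulation."
        )
        condition = "Stable on anticoagulation at discharge."
        instructions = (
            "Continue anticoagulation as prescribed and attend thrombosis "
            "clinic follow-up in two weeks."
        )
    else:
        findings = "The admission course was uncomplicated from a cardiopulmonary standpoint."
        condition = "Stable and improved at discharge."
        instructions = "Resume home medications and follow up with the family physician."
    bodies = {
        "reason_for_hospitalization": f"Admitted for management of {complaint}.",
        "significant_findings": findings,
        "procedures_and_treatments": "Supportive care, intravenous fluids and targeted therapy as documented.",
        "medical_history": f"{n_comorbidities} chronic comorbid conditions on file.",
        "discharge_condition": condition,
        "patient_family_instructions": instructions,
    }
    blocks = [f"{SECTION_TITLES[f]}:\n{bodies[f]}" for f in SECTION_FIELDS]
    return "\n\n".join(blocks)


def _note_timestamp(
    rng: np.random.Generator, admission: dt.date, day: int
) -> dt.datetime:
    return dt.datetime.combine(
        admission + dt.timedelta(days=day),
        dt.time(int(rng.integers(7, 21)), int(rng.integers(0, 60))),
    )


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[Corpus, dict[str, GoldAnnotation]]:
    """Generate a gold-labeled corpus; byte-reproducible under the seed."""
    rng = np.random.default_rng(config.seed)
    vocab_extra = [t for t in NOTE_TYPE_POOL if t != IMAGING_NOTE_TYPE]
    pick = rng.choice(
        len(vocab_extra), size=max(config.n_note_types - 1, 1), replace=False
    )
    note_types = [IMAGING_NOTE_TYPE] + [vocab_extra[i] for i in sorted(pick)]
    span_days = (config.end_date - config.start_date).days + 1

    charts: list[PatientChart] = []
    annotations: dict[str, GoldAnnotation] = {}
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        label = int(rng.random() < config.prevalence)
        admission = config.start_date + dt.timedelta(days=int(rng.integers(span_days)))
        base_los = 1 + int(rng.poisson(3.7))
        if label and config.los_shift_for_positives:
            los = 4 + int(rng.poisson(6.0))
        elif label:
            los = max(base_los, 3)
        else:
            los = base_los
        discharge = admission + dt.timedelta(days=los)

        age = int(rng.integers(18, 101))
        sex = "female" if rng.random() < 0.521 else "male"
        died = bool(rng.random() < 0.071)
        n_com = int(rng.choice([0, 1, 2, 3, 4], p=[0.24, 0.232, 0.30, 0.15, 0.078]))
        complaint = _COMPLAINTS[int(rng.integers(len(_COMPLAINTS)))]

        n_notes = 1 + int(rng.poisson(max(config.notes_per_patient_mean - 1, 0)))
        raw_notes = []
        for _ in range(n_notes):
            day = int(rng.integers(0, los + 1))
            raw_notes.append(
                ClinicalNote(
                    note_id="pending",
                    note_type=note_types[int(rng.integers(len(note_types)))],
                    timestamp=_note_timestamp(rng, admission, day),
                    text=_filler_text(rng, int(rng.integers(1, 4))),
                )
            )

        plant_requests: list[tuple[ClinicalNote, str, dict]] = []
        event_day: Optional[int] = None
        if label:
            event_day = int(rng.integers(2, los + 1))
            note = ClinicalNote(
                note_id="pending",
                note_type=IMAGING_NOTE_TYPE,
                timestamp=_note_timestamp(rng, admission, event_day),
                text=_filler_text(rng, 1),
            )
            raw_notes.append(note)
            tid = AFFIRMING_TEMPLATE_IDS[int(rng.integers(len(AFFIRMING_TEMPLATE_IDS)))]
            side = "right" if rng.random() < 0.5 else "left"
            plant_requests.append((note, tid, {"side": side}))
        else:
            for cat in CONFOUNDER_CATEGORIES:
                if rng.random() >= config.confounder_rates.get(cat, 0.0):
                    continue
                if cat == "poa_pe":
                    day = int(rng.integers(0, min(2, los + 1)))
                    note = ClinicalNote(
                        note_id="pending",
                        note_type=IMAGING_NOTE_TYPE,
                        timestamp=_note_timestamp(rng, admission, day),
                        text=_filler_text(rng, 1),
                    )
                    raw_notes.append(note)
                    tid = AFFIRMING_TEMPLATE_IDS[
                        int(rng.integers(len(AFFIRMING_TEMPLATE_IDS)))
                    ]
                    side = "right" if rng.random() < 0.5 else "left"
                    plant_requests.append((note, tid, {"side": side}))
                else:
                    target = raw_notes[int(rng.integers(len(raw_notes)))]
                    if cat == "negated_pe":
                        tid = _NEGATED_TEMPLATE_IDS[
                            int(rng.integers(len(_NEGATED_TEMPLATE_IDS)))
                        ]
                        slots: dict[str, object] = {}
                    elif cat == "historical_pe":
                        tid, slots = "hist_pe", {
                            "year": int(rng.integers(2005, admission.year))
                        }
                    elif cat == "pulmonary_edema":
                        tid, slots = "edema", {}
                    else:
                        tid, slots = "prophylaxis", {}
                    plant_requests.append((target, tid, slots))

        raw_notes.sort(key=lambda n: n.timestamp)
        final_notes: list[ClinicalNote] = []
        spans_by_obj: dict[int, list[PlantedSpan]] = {}
        requests_by_obj: dict[int, list[tuple[str, dict]]] = {}
        for note, tid, slots in plant_requests:
            requests_by_obj.setdefault(id(note), []).append((tid, slots))
        for j, note in enumerate(raw_notes):
            named = note.model_copy(update={"note_id": f"{pid}-N{j:03d}"})
            spans: list[PlantedSpan] = []
            for tid, slots in requests_by_obj.get(id(note), []):
                named, span = plant_sentence(tid, slots, named, len(named.text))
                spans.append(span)
            final_notes.append(named)
            if spans:
                spans_by_obj[j] = spans

        summary = ClinicalNote(
            note_id=f"{pid}-DS",
            note_type="discharge summary",
            timestamp=dt.datetime.combine(discharge, dt.time(12, 0)),
            text=_discharge_summary_text(rng, complaint, label, event_day, n_com),
        )

        planted_evidence: list[PlantedSpan] = []
        planted_confounders: list[PlantedSpan] = []
        for spans in spans_by_obj.values():
            for span in spans:
                if span.category == "affirming" and label == 1:
                    planted_evidence.append(span)
                else:
                    cat = "poa_pe" if span.category == "affirming" else span.category
                    planted_confounders.append(
                        span.model_copy(update={"category": cat})
                    )

        codes: list[DiagnosisCode] = [
            DiagnosisCode(
                code=_BACKGROUND_ICD[int(rng.integers(len(_BACKGROUND_ICD)))],
                present_on_admission=bool(rng.random() < 0.7),
            )
            for _ in range(int(rng.integers(0, 4)))
        ]
        if label and rng.random() < config.icd_sensitivity:
            codes.append(DiagnosisCode(code="I26.9", present_on_admission=False))
        elif not label and planted_confounders:
            if any(s.category == "poa_pe" for s in planted_confounders):
                codes.append(DiagnosisCode(code="I26.9", present_on_admission=True))
            elif rng.random() < config.icd_miscode_rate:
                codes.append(DiagnosisCode(code="I26.9", present_on_admission=False))

        charts.append(
            PatientChart(
                patient_id=pid,
                admission_date=admission,
                discharge_date=discharge,
                notes=final_notes,
                discharge_summary=summary,
                diagnosis_codes=codes,
                gold_label=label,
                age=age,
                sex=sex,
                died_in_hospital=died,
                n_comorbidities=n_com,
            )
        )
        annotations[pid] = GoldAnnotation(
            patient_id=pid,
            label=label,
            planted_evidence=planted_evidence,
            planted_confounders=planted_confounders,
        )

    corpus = Corpus(charts=charts, source="synthetic", seed=config.seed)
    return corpus, annotations


def corpus_report(
    corpus: Corpus, annotations: dict[str, GoldAnnotation]
) -> dict:
    """Realized generation statistics (prevalence, confounders, admissions)."""
    ids = {c.patient_id for c in corpus.charts}
    if ids != set(annotations):
        raise ValueError("corpus and annotations cover different patients")
    n = len(corpus.charts)
    labels = [annotations[c.patient_id].label for c in corpus.charts]
    confounder_counts = {c: 0 for c in CONFOUNDER_CATEGORIES}
    for ann in annotations.values():
        for span in ann.planted_confounders:
            confounder_counts[span.category] += 1
    per_year: dict[str, int] = {}
    for c in corpus.charts:
        key = str(c.admission_date.year)
        per_year[key] = per_year.get(key, 0) + 1
    return {
        "n_patients": n,
        "realized_prevalence": (sum(labels) / n) if n else 0.0,
        "n_positive": int(sum(labels)),
        "confounder_counts": confounder_counts,
        "admissions_per_year": dict(sorted(per_year.items())),
        "seed": corpus.seed,
    }
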