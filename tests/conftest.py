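import datetime as dt

import pytest

from pescreen.corpus import ClinicalNote, Corpus, PatientChart
from pescreen.synthetic import CONFOUNDER_CATEGORIES, GeneratorConfig, generate_corpus

ZERO_CONFOUNDERS = {c: 0.0 for c in CONFOUNDER_CATEGORIES}


def make_note(text, note_id="n1", day=0, note_type="progress note"):
    return ClinicalNote(
        note_id=note_id,
        note_type=note_type,
        timestamp=dt.datetime(2019, 3, 1 + day, 9, 0),
        text=text,
    )


def make_chart(patient_id="P1", notes=(), gold_label=None, with_summary=True, los=7):
    summary = None
    if with_summary:
        summary = ClinicalNote(
            note_id=f"{patient_id}-DS",
            note_type="discharge summary",
            timestamp=dt.datetime(2019, 3, 1 + los, 12, 0),
            text="Reason for Hospitalization:\nAdmitted for care.",
        )
    return PatientChart(
        patient_id=patient_id,
        admission_date=dt.date(2019, 3, 1),
        discharge_date=dt.date(2019, 3, 1 + los),
        notes=list(notes),
        discharge_summary=summary,
        gold_label=gold_label,
    )


def clean_generator_config(n_patients, seed=0, prevalence=0.05, **kwargs):
    """Confounder-free generator configuration for recovery tests."""
    return GeneratorConfig(
        n_patients=n_patients,
        prevalence=prevalence,
        confounder_rates=dict(ZERO_CONFOUNDERS),
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_clean_corpus():
    """200 charts, 5% prevalence, no confounders; gold recovery expected."""
    return generate_corpus(clean_generator_config(200, seed=11))


@pytest.fixture(scope="session")
def small_confounded_corpus():
    """200 charts with confounders at the default 2% per category."""
    return generate_corpus(GeneratorConfig(n_patients=200, prevalence=0.05, seed=11))
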