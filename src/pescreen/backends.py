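"""Reference backends fulfilling the embedding and generation contracts.

:class:`HashingEmbedder` is a deterministic lexical embedder (hashed
word/bigram counts, L2-normalized): texts sharing vocabulary embed
nearby, which is exactly the property the semantic filter and triplet
evaluation exercise.  Swap in a sentence-transformer behind the same
``embed`` contract for real deployments.

:class:`MockGenerationBackend` is a deterministic rule engine over the
prompt payload.  For detection prompts it answers "Yes." iff some dated
evidence line contains a PE-affirming phrase that is not preceded
in-sentence by a negation cue and whose date is at least
``min_days_after_admission`` days after the stated admission date (the
synthetic-world convention for "hospital-acquired").  For discharge
prompts it parses the summary's section headers and echoes the sections
as a JSON block.  Real chat-completion backends plug in behind the same
one-method ``generate`` contract.
"""

from __future__ import annotations

import datetime as dt
import json
import re
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field
from sklearn.feature_extraction.text import HashingVectorizer

from .discharge import SECTION_FIELDS, SECTION_TITLES
from .prompts import load_prompts, unwrap_any


class HashingEmbedder:
    """Deterministic hashed bag-of-words embedding backend."""

    def __init__(self, n_features: int = 512, ngram_range: tuple[int, int] = (1, 2)):
        self.n_features = n_features
        self._vec = HashingVectorizer(
            n_features=n_features,
            ngram_range=ngram_range,
            norm="l2",
            alternate_sign=True,
            lowercase=True,
            stop_words="english",
        )
        self.name = f"hashing-{n_features}"

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        if len(texts) == 0:
            return np.zeros((0, self.n_features))
        return np.asarray(self._vec.transform(list(texts)).todense(), dtype=float)


#: Phrases the rule engine treats as affirming an acute/new PE.  The
#: synthetic generator's affirming templates are built over these.
DEFAULT_AFFIRM_PATTERNS = [
    r"acute pulmonary embol(?:ism|us)",
    r"new pulmonary embol(?:ism|us)",
    r"segmental pulmonary embol(?:ism|us)",
    r"acute PE(?!\w)",
]

DEFAULT_NEGATION_CUES = [
    "no",
    "not",
    "without",
    "negative for",
    "no evidence of",
    "ruled out",
    "history of",
    "denies",
]


class MockRuleConfig(BaseModel):
    affirm_patterns: list[str] = Field(
        default_factory=lambda: list(DEFAULT_AFFIRM_PATTERNS)
    )
    negation_cues: list[str] = Field(
        default_factory=lambda: list(DEFAULT_NEGATION_CUES)
    )
    #: Days after admission from which a PE counts as hospital-acquired.
    #: A synthetic-world convention, not a clinical claim.
    min_days_after_admission: int = 2


_EVIDENCE_LINE = re.compile(r"^- \[(\d{4}-\d{2}-\d{2})\] (.*)$", re.MULTILINE)
_ADMISSION = re.compile(r"^ADMISSION DATE: (\d{4}-\d{2}-\d{2})$", re.MULTILINE)
_SENT_SPLIT = re.compile(r"[.!?\n]")


class MockGenerationBackend:
    """Deterministic rule-based stand-in honoring the generation contract."""

    def __init__(self, config: MockRuleConfig | None = None):
        self.config = config or MockRuleConfig()
        self.name = "rule-mock"
        self.version = "1"
        self._affirm = re.compile(
            "|".join(f"(?:{p})" for p in self.config.affirm_patterns), re.IGNORECASE
        )
        cues = "|".join(
            re.escape(c) for c in sorted(self.config.negation_cues, key=len, reverse=True)
        )
        self._cue = re.compile(rf"(?<!\w)(?:{cues})(?!\w)", re.IGNORECASE)

    # -- discharge prompts -------------------------------------------------
    def _handle_discharge(self, payload: str) -> str:
        tpl = load_prompts()["discharge"]
        header, footer = tpl["summary_header"], tpl["summary_footer"]
        start = payload.index(header) + len(header)
        end = payload.find(footer, start)
        summary = payload[start : end if end >= 0 else len(payload)].strip()
        titles = {SECTION_TITLES[f]: f for f in SECTION_FIELDS}
        pattern = re.compile(
            rf"^({'|'.join(re.escape(t) for t in titles)}):\s*$", re.MULTILINE
        )
        sections: dict[str, str] = {}
        matches = list(pattern.finditer(summary))
        for i, m in enumerate(matches):
            body_end = matches[i + 1].start() if i + 1 < len(matches) else len(summary)
            sections[titles[m.group(1)]] = summary[m.end() : body_end].strip()
        out = {
            SECTION_TITLES[f].lower(): sections.get(f, "") for f in SECTION_FIELDS
        }
        return json.dumps(out, ensure_ascii=False)

    # -- detection prompts -------------------------------------------------
    def _handle_detection(self, payload: str) -> str:
        m = _ADMISSION.search(payload)
        if m is None:
            return "No. The prompt does not state an admission date."
        admission = dt.date.fromisoformat(m.group(1))
        for line in _EVIDENCE_LINE.finditer(payload):
            when = dt.date.fromisoformat(line.group(1))
            days = (when - admission).days
            for sentence in _SENT_SPLIT.split(line.group(2)):
                hit = self._affirm.search(sentence)
                if hit is None:
                    continue
                if self._cue.search(sentence[: hit.start()]):
                    continue  # negated / historical context before the mention
                if days >= self.config.min_days_after_admission:
                    return (
                        f"Yes. Pulmonary embolism documented on {when.isoformat()}, "
                        f"{days} days after admission, consistent with a "
                        "hospital-acquired adverse event."
                    )
        return (
            "No. No affirmed hospital-acquired pulmonary embolism was found "
            "in the evidence."
        )

    def generate(self, prompt: str) -> str:
        if not prompt:
            raise ValueError("empty prompt")
        payload = unwrap_any(prompt)
        if load_prompts()["discharge"]["summary_header"] in payload:
            return self._handle_discharge(payload)
        return self._handle_detection(payload)
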