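"""Evidence extraction: chunking plus keyword / semantic-similarity filtering.

Narrative charts are far too long for direct LLM consumption, so each
note is split into chunks and the chunks are filtered down to the few
that plausibly discuss pulmonary embolism.  Two filters are provided:

* keyword filtering — retain chunks containing at least one PE-relevant
  term (word-boundary matching so that "hoPEful" never fires);
* semantic filtering — embed chunks and a small set of exemplar
  PE-affirming sentences, score each chunk by its best cosine similarity
  to any exemplar, and keep the top ``n`` percent.

The module also builds anchor/positive/negative triplets for adapting
and evaluating embedding backends, and summarizes the chunk-count
reduction achieved by each filtering stage.
"""

from __future__ import annotations

import datetime as dt
import math
import re
from typing import Optional, Protocol, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .corpus import ClinicalNote, Corpus, PatientChart


class Chunk(BaseModel):
    """A contiguous segment of one note, with provenance.

    ``span`` is a 0-based half-open character interval into the owning
    note's text; ``text`` always equals that substring.
    """

    patient_id: str = ""
    note_id: str
    chunk_index: int
    start: int
    end: int
    text: str
    word_count: int
    timestamp: dt.datetime

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class KeywordSpec(BaseModel):
    """PE-relevant keyword configuration.

    ``exact_terms`` match case-sensitively (short acronyms like "PE"
    whose lowercase form collides with ordinary prose); phrases in
    ``insensitive_terms`` match case-insensitively.  Both honor word
    boundaries when ``word_boundary`` is on.  The defaults are the
    printed starting point, not a closed list — extend them for local
    documentation habits.
    """

    exact_terms: list[str] = Field(default_factory=lambda: ["PE"])
    insensitive_terms: list[str] = Field(
        default_factory=lambda: [
            "blood clot",
            "thrombosis",
            "pulmonary embolism",
            "pulmonary embolus",
            "ctpe",
            "pe",
        ]
    )
    word_boundary: bool = True

    @field_validator("exact_terms", "insensitive_terms")
    @classmethod
    def _no_empty_terms(cls, v: list[str]) -> list[str]:
        if any(not t.strip() for t in v):
            raise ValueError("keyword terms must be non-empty")
        return v

    def _pattern(self, terms: Sequence[str], flags: int) -> Optional[re.Pattern]:
        if not terms:
            return None
        alts = "|".join(re.escape(t) for t in sorted(terms, key=len, reverse=True))
        if self.word_boundary:
            return re.compile(rf"(?<!\w)(?:{alts})(?!\w)", flags)
        return re.compile(f"(?:{alts})", flags)

    def matches(self, text: str) -> bool:
        exact = self._pattern(self.exact_terms, 0)
        insens = self._pattern(self.insensitive_terms, re.IGNORECASE)
        if exact and exact.search(text):
            return True
        return bool(insens and insens.search(text))


#: Ten exemplar sentences mimicking PE-affirming content across note
#: genres (imaging reports, nursing notes, assessments, discharge
#: summaries).  Authored defaults — treat as configuration.
DEFAULT_EXAMPLE_SENTENCES = [
    "CT pulmonary angiogram demonstrates acute pulmonary embolism in the right lower lobe artery.",
    "Patient developed sudden shortness of breath; CTPA confirmed a new pulmonary embolus.",
    "Nursing note: pleuritic chest pain and oxygen saturation 86 percent, physician notified of possible PE.",
    "Assessment: acute pulmonary embolism, therapeutic heparin infusion started.",
    "Discharge diagnosis includes hospital-acquired pulmonary embolism treated with anticoagulation.",
    "Ventilation-perfusion scan shows high probability of pulmonary embolism.",
    "CT chest consistent with acute PE with thrombus in segmental branches.",
    "New tachycardia and hypoxia concerning for pulmonary embolism; CTPE ordered.",
    "Imaging report: filling defect in the left pulmonary artery compatible with acute embolus.",
    "Plan: continue enoxaparin at treatment dose for newly diagnosed pulmonary embolism.",
]


class ExampleSentenceSet(BaseModel):
    sentences: list[str] = Field(default_factory=lambda: list(DEFAULT_EXAMPLE_SENTENCES))

    @field_validator("sentences")
    @classmethod
    def _non_empty(cls, v: list[str]) -> list[str]:
        if not v or any(not s.strip() for s in v):
            raise ValueError("exemplar set must contain non-empty sentences")
        return v


class SemanticFilterConfig(BaseModel):
    """``top_percent`` is the adjustable retention threshold n ∈ (0, 100]."""

    top_percent: float = 5.0
    aggregation: str = "max"  # or "mean"

    @field_validator("top_percent")
    @classmethod
    def _in_range(cls, v: float) -> float:
        if not 0 < v <= 100:
            raise ValueError("top_percent must be in (0, 100]")
        return v

    @field_validator("aggregation")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in ("max", "mean"):
            raise ValueError("aggregation must be 'max' or 'mean'")
        return v


class EmbeddingBackend(Protocol):
    """Contract: one fixed-length finite vector per input text."""

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...


class Triplet(BaseModel):
    """Anchor/positive/negative texts for embedding adaptation."""

    anchor: str
    positive: str
    negative: str
    negative_source: str  # "non_pe_chart" | "negated_anchor"

    @model_validator(mode="after")
    def _distinct(self) -> "Triplet":
        if len({self.anchor, self.positive, self.negative}) != 3:
            raise ValueError("triplet texts must be pairwise distinct")
        return self


# ---------------------------------------------------------------------------
# chunking

_WORD_RE = re.compile(r"\S+")
_PARA_SEP_RE = re.compile(r"\n[ \t]*\n+")
_SENT_SEP_RE = re.compile(r"(?<=[.!?])\s+|\n+")


def _word_window_spans(
    text: str, start: int, end: int, max_words: int, overlap: int
) -> list[tuple[int, int]]:
    words = [m for m in _WORD_RE.finditer(text, start, end)]
    if not words:
        return []
    step = max_words - overlap
    spans = []
    i = 0
    while i < len(words):
        j = min(i + max_words, len(words))
        s = words[i].start()
        if overlap == 0 and j < len(words):
            e = words[j].start()  # keep separators: spans tile the word region
        else:
            e = words[j - 1].end()
        spans.append((s, e))
        if j == len(words):
            break
        i += step
    return spans


def _segment_spans(text: str, sep: re.Pattern) -> list[tuple[int, int]]:
    spans = []
    pos = 0
    for m in sep.finditer(text):
        if m.start() > pos:
            spans.append((pos, m.start()))
        pos = m.end()
    if pos < len(text):
        spans.append((pos, len(text)))
    # trim surrounding whitespace inside each segment
    out = []
    for s, e in spans:
        seg = text[s:e]
        ls = len(seg) - len(seg.lstrip())
        rs = len(seg) - len(seg.rstrip())
        if s + ls < e - rs:
            out.append((s + ls, e - rs))
    return out


def chunk_note(
    note: ClinicalNote,
    strategy: str = "paragraph",
    max_words: int = 128,
    overlap: int = 0,
    patient_id: str = "",
) -> list[Chunk]:
    """Split one note into chunks of at most ``max_words`` words.

    ``paragraph`` splits on blank lines and ``sentence`` on sentence
    terminators; any oversize segment falls back to a word window.
    ``word_window`` tiles the whole note; with ``overlap == 0`` its spans
    are contiguous so their concatenation reconstructs the note body.
    An empty note yields an empty list.
    """
    if max_words < 1:
        raise ValueError("max_words must be >= 1")
    if overlap >= max_words or overlap < 0:
        raise ValueError("overlap must satisfy 0 <= overlap < max_words")
    if strategy not in ("paragraph", "sentence", "word_window"):
        raise ValueError(f"unknown chunking strategy {strategy!r}")
    text = note.text
    if not text.strip():
        return []

    spans: list[tuple[int, int]] = []
    if strategy == "word_window":
        spans = _word_window_spans(text, 0, len(text), max_words, overlap)
    else:
        sep = _PARA_SEP_RE if strategy == "paragraph" else _SENT_SEP_RE
        for s, e in _segment_spans(text, sep):
            n_words = sum(1 for _ in _WORD_RE.finditer(text, s, e))
            if n_words <= max_words:
                spans.append((s, e))
            else:  # unbreakable oversize segment: word-window fallback
                spans.extend(_word_window_spans(text, s, e, max_words, overlap))

    chunks = []
    for idx, (s, e) in enumerate(spans):
        seg = text[s:e]
        chunks.append(
            Chunk(
                patient_id=patient_id,
                note_id=note.note_id,
                chunk_index=idx,
                start=s,
                end=e,
                text=seg,
                word_count=len(_WORD_RE.findall(seg)),
                timestamp=note.timestamp,
            )
        )
    return chunks


# ---------------------------------------------------------------------------
# filters


def keyword_filter(chunks: Sequence[Chunk], spec: Optional[KeywordSpec] = None) -> list[Chunk]:
    """Retain exactly the chunks containing at least one keyword, in order."""
    spec = spec or KeywordSpec()
    return [c for c in chunks if spec.matches(c.text)]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u||v|); raises on dimension mismatch or a zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def score_chunks(
    chunks: Sequence[Chunk],
    examples: ExampleSentenceSet,
    backend: EmbeddingBackend,
    aggregation: str = "max",
) -> np.ndarray:
    """Similarity score per chunk against the exemplar set.

    A chunk whose embedding is the zero vector (e.g. an all-stopword
    hashing embedding) scores -1, the similarity floor.
    """
    if not chunks:
        return np.zeros(0)
    try:
        chunk_vecs = np.asarray(backend.embed([c.text for c in chunks]), dtype=float)
        ex_vecs = np.asarray(backend.embed(list(examples.sentences)), dtype=float)
    except Exception as exc:
        raise RuntimeError(
            f"embedding backend failed on {len(chunks)} chunks "
            f"(first: {chunks[0].note_id}/{chunks[0].chunk_index})"
        ) from exc
    if not (np.isfinite(chunk_vecs).all() and np.isfinite(ex_vecs).all()):
        raise RuntimeError("embedding backend produced non-finite vectors")
    cn = np.linalg.norm(chunk_vecs, axis=1, keepdims=True)
    en = np.linalg.norm(ex_vecs, axis=1, keepdims=True)
    if (en == 0).any():
        raise RuntimeError("an exemplar sentence embedded to the zero vector")
    zero_chunks = (cn[:, 0] == 0)
    cn[zero_chunks] = 1.0
    sims = (chunk_vecs / cn) @ (ex_vecs / en).T
    agg = sims.max(axis=1) if aggregation == "max" else sims.mean(axis=1)
    agg[zero_chunks] = -1.0
    return agg


def semantic_filter(
    chunks: Sequence[Chunk],
    examples: ExampleSentenceSet,
    backend: EmbeddingBackend,
    config: Optional[SemanticFilterConfig] = None,
) -> list[Chunk]:
    """Keep the ceil(top_percent% × N) best-scoring chunks, document order.

    Ties are broken in favor of the earlier document position.
    """
    config = config or SemanticFilterConfig()
    if not chunks:
        return []
    scores = score_chunks(chunks, examples, backend, config.aggregation)
    k = math.ceil(config.top_percent / 100.0 * len(chunks))
    order = sorted(range(len(chunks)), key=lambda i: (-scores[i], i))
    keep = sorted(order[:k])
    return [chunks[i] for i in keep]


def extract_evidence(
    chart: PatientChart,
    method: str = "keyword",
    *,
    strategy: str = "paragraph",
    max_words: int = 128,
    overlap: int = 0,
    keyword_spec: Optional[KeywordSpec] = None,
    examples: Optional[ExampleSentenceSet] = None,
    backend: Optional[EmbeddingBackend] = None,
    semantic_config: Optional[SemanticFilterConfig] = None,
) -> list[Chunk]:
    """Chunk every in-stay note of ``chart`` and apply the selected filter.

    The discharge summary is handled by its own extraction module and is
    never chunked here.  An empty result is legal (flagged downstream).
    """
    if method not in ("keyword", "semantic"):
        raise ValueError(f"unknown retrieval method {method!r}")
    summary_id = chart.discharge_summary.note_id if chart.discharge_summary else None
    chunks: list[Chunk] = []
    for note in chart.notes:
        if summary_id is not None and note.note_id == summary_id:
            continue
        chunks.extend(
            chunk_note(note, strategy, max_words, overlap, patient_id=chart.patient_id)
        )
    if method == "keyword":
        return keyword_filter(chunks, keyword_spec)
    if backend is None:
        raise ValueError("semantic retrieval requires an embedding backend")
    return semantic_filter(
        chunks, examples or ExampleSentenceSet(), backend, semantic_config
    )


# ---------------------------------------------------------------------------
# triplets

NEGATION_PREFIX = "No evidence of the following was found: "


def negate_chunk(text: str) -> str:
    """Deterministic template negation of a chunk text."""
    if not text:
        raise ValueError("cannot negate empty text")
    return NEGATION_PREFIX + text


def _chart_chunks(chart: PatientChart, strategy: str, max_words: int) -> list[Chunk]:
    summary_id = chart.discharge_summary.note_id if chart.discharge_summary else None
    out: list[Chunk] = []
    for note in chart.notes:
        if summary_id is not None and note.note_id == summary_id:
            continue
        out.extend(chunk_note(note, strategy, max_words, 0, patient_id=chart.patient_id))
    return out


def build_triplets(
    corpus: Corpus,
    spec: Optional[KeywordSpec] = None,
    negated_fraction: float = 0.5,
    seed: int = 0,
    strategy: str = "paragraph",
    max_words: int = 128,
) -> list[Triplet]:
    """Build one triplet per anchor chunk.

    Anchors are keyword-bearing chunks of gold-positive charts.  The
    positive is a different keyword chunk, same chart preferred;
    negatives are either a template-negated copy of the anchor (with
    probability ``negated_fraction``) or a keyword-free chunk from a
    gold-negative chart containing no keywords at all.
    """
    if not 0 <= negated_fraction <= 1:
        raise ValueError("negated_fraction must be in [0, 1]")
    spec = spec or KeywordSpec()
    rng = np.random.default_rng(seed)

    anchors: list[tuple[str, Chunk]] = []  # (chart id, chunk)
    per_chart_kw: dict[str, list[Chunk]] = {}
    negatives_pool: list[Chunk] = []
    for chart in corpus.charts:
        chunks = _chart_chunks(chart, strategy, max_words)
        kw = keyword_filter(chunks, spec)
        if chart.gold_label == 1 and kw:
            per_chart_kw[chart.patient_id] = kw
            anchors.extend((chart.patient_id, c) for c in kw)
        elif chart.gold_label == 0 and not kw:
            negatives_pool.extend(chunks)

    all_positive_kw = [c for lst in per_chart_kw.values() for c in lst]
    triplets: list[Triplet] = []
    for chart_id, anchor in anchors:
        same = [c for c in per_chart_kw[chart_id] if c.text != anchor.text]
        pool = same or [c for c in all_positive_kw if c.text != anchor.text]
        if not pool:
            continue  # no distinct positive exists for this anchor
        positive = pool[int(rng.integers(len(pool)))]
        if rng.random() < negated_fraction:
            triplets.append(
                Triplet(
                    anchor=anchor.text,
                    positive=positive.text,
                    negative=negate_chunk(anchor.text),
                    negative_source="negated_anchor",
                )
            )
        else:
            candidates = [
                c for c in negatives_pool if c.text not in (anchor.text, positive.text)
            ]
            if not candidates:
                raise ValueError("no eligible negative chunks in corpus")
            negative = candidates[int(rng.integers(len(candidates)))]
            triplets.append(
                Triplet(
                    anchor=anchor.text,
                    positive=positive.text,
                    negative=negative.text,
                    negative_source="non_pe_chart",
                )
            )
    return triplets


def triplet_accuracy(triplets: Sequence[Triplet], backend: EmbeddingBackend) -> float:
    """Fraction of triplets with cos(anchor, positive) > cos(anchor, negative).

    Ties count as failures.
    """
    if not triplets:
        raise ValueError("triplet_accuracy needs a non-empty triplet list")
    a = np.asarray(backend.embed([t.anchor for t in triplets]), dtype=float)
    p = np.asarray(backend.embed([t.positive for t in triplets]), dtype=float)
    n = np.asarray(backend.embed([t.negative for t in triplets]), dtype=float)

    def _rowwise_cos(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        nx = np.linalg.norm(x, axis=1)
        ny = np.linalg.norm(y, axis=1)
        denom = np.where((nx == 0) | (ny == 0), 1.0, nx * ny)
        sims = (x * y).sum(axis=1) / denom
        sims[(nx == 0) | (ny == 0)] = 0.0
        return sims

    return float(np.mean(_rowwise_cos(a, p) > _rowwise_cos(a, n)))


# ---------------------------------------------------------------------------
# reduction summary


def summarize_reduction(
    stage_chunks: dict[str, dict[str, tuple[int, int]]],
) -> "pd.DataFrame":
    """Summarize per-stage chunk reduction.

    ``stage_chunks`` maps stage name -> {patient_id: (n_chunks, n_words)}.
    Returns one row per stage with the total chunk count and the median
    and IQR (linear-interpolation quartiles) of per-patient chunk and
    word counts.  All stages must cover the same patient set.
    """
    import pandas as pd

    stages = list(stage_chunks)
    if not stages:
        raise ValueError("no stages given")
    base = set(stage_chunks[stages[0]])
    for s in stages[1:]:
        if set(stage_chunks[s]) != base:
            raise ValueError(f"stage {s!r} covers a different patient set")
    rows = []
    for s in stages:
        counts = np.array([v[0] for v in stage_chunks[s].values()], dtype=float)
        words = np.array([v[1] for v in stage_chunks[s].values()], dtype=float)
        q = lambda a, p: float(np.percentile(a, p, method="linear"))
        rows.append(
            {
                "stage": s,
                "total_chunks": int(counts.sum()),
                "chunks_median": q(counts, 50),
                "chunks_q1": q(counts, 25),
                "chunks_q3": q(counts, 75),
                "words_median": q(words, 50),
                "words_q1": q(words, 25),
                "words_q3": q(words, 75),
            }
        )
    return pd.DataFrame(rows).set_index("stage")
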