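import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pescreen.corpus import Corpus
from pescreen.evidence import (
    Chunk,
    ExampleSentenceSet,
    KeywordSpec,
    SemanticFilterConfig,
    build_triplets,
    chunk_note,
    cosine_similarity,
    keyword_filter,
    negate_chunk,
    semantic_filter,
    summarize_reduction,
    triplet_accuracy,
)

from conftest import make_chart, make_note


def chunks_from_texts(texts):
    return [
        Chunk(
            note_id="n1",
            chunk_index=i,
            start=0,
            end=len(t),
            text=t,
            word_count=max(len(t.split()), 1),
            timestamp=make_note("x").timestamp,
        )
        for i, t in enumerate(texts)
    ]


# ---------------------------------------------------------------------------
# chunking


def test_chunk_empty_note_is_empty():
    assert chunk_note(make_note("")) == []
    assert chunk_note(make_note("   \n\n  ")) == []


def test_word_window_250_words_splits_100_100_50():
    note = make_note(" ".join(f"w{i}" for i in range(250)))
    chunks = chunk_note(note, strategy="word_window", max_words=100, overlap=0)
    assert [c.word_count for c in chunks] == [100, 100, 50]
    # contiguous spans covering the word region
    assert chunks[0].start == 0
    for a, b in zip(chunks, chunks[1:]):
        assert a.end == b.start
    assert "".join(c.text for c in chunks) == note.text


def test_paragraph_strategy_returns_paragraph_texts():
    note = make_note("first paragraph here.\n\nsecond paragraph there.")
    chunks = chunk_note(note, strategy="paragraph", max_words=128)
    assert [c.text for c in chunks] == [
        "first paragraph here.",
        "second paragraph there.",
    ]


def test_oversize_paragraph_falls_back_to_word_window():
    note = make_note(" ".join(f"w{i}" for i in range(40)) + "\n\nshort tail.")
    chunks = chunk_note(note, strategy="paragraph", max_words=16)
    assert all(c.word_count <= 16 for c in chunks)
    assert chunks[-1].text == "short tail."


def test_sentence_strategy_splits_on_terminators():
    note = make_note("One sentence. Another one! A third?")
    texts = [c.text for c in chunk_note(note, strategy="sentence")]
    assert texts == ["One sentence.", "Another one!", "A third?"]


def test_overlap_produces_overlapping_windows():
    note = make_note(" ".join(f"w{i}" for i in range(10)))
    chunks = chunk_note(note, strategy="word_window", max_words=4, overlap=2)
    assert chunks[0].text.split()[-2:] == chunks[1].text.split()[:2]


def test_chunk_parameter_validation():
    with pytest.raises(ValueError):
        chunk_note(make_note("x"), max_words=0)
    with pytest.raises(ValueError):
        chunk_note(make_note("x"), max_words=4, overlap=4)
    with pytest.raises(ValueError):
        chunk_note(make_note("x"), strategy="tokens")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    text=st.text(
        alphabet=st.sampled_from(list("abc PE.\n")), min_size=0, max_size=200
    ),
    strategy=st.sampled_from(["paragraph", "sentence", "word_window"]),
)
def test_chunk_spans_address_note_text(text, strategy):
    """Every chunk's span reproduces its text; order and bounds hold."""
    note = make_note(text)
    chunks = chunk_note(note, strategy=strategy, max_words=8)
    prev_start = -1
    for c in chunks:
        assert note.text[c.start : c.end] == c.text
        assert c.word_count >= 1
        assert c.start > prev_start
        prev_start = c.start


# ---------------------------------------------------------------------------
# keyword filter


@pytest.mark.parametrize(
    "text,kept",
    [
        ("CT chest showed acute PE in the right lower lobe", True),
        ("the patient remains hoPEful about discharge", False),
        ("pulmonary edema improving on diuresis", False),
        ("known pulmonary embolism, on anticoagulation", True),
        ("ctpe requested for tomorrow morning", True),
        ("a small blood clot was noted", True),
        ("deep vein thrombosis prophylaxis continued", True),
    ],
)
def test_keyword_filter_cases(text, kept):
    out = keyword_filter(chunks_from_texts([text]))
    assert (len(out) == 1) is kept


def test_keyword_filter_preserves_order_and_identity():
    chunks = chunks_from_texts(["acute PE", "nothing here", "blood clot seen"])
    out = keyword_filter(chunks)
    assert out == [chunks[0], chunks[2]]
    assert keyword_filter([]) == []


def test_keyword_spec_rejects_empty_terms():
    with pytest.raises(ValueError):
        KeywordSpec(insensitive_terms=["ok", "  "])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    texts=st.lists(
        st.text(alphabet=st.sampled_from(list("abe PEclot\n")), max_size=40),
        max_size=12,
    )
)
def test_keyword_filter_idempotent_and_matches_regex_oracle(texts):
    chunks = chunks_from_texts(texts)
    once = keyword_filter(chunks)
    assert keyword_filter(once) == once
    # independent word-boundary regex oracle over the default spec
    spec = KeywordSpec()
    terms = "|".join(re.escape(t) for t in spec.insensitive_terms)
    oracle = [
        c
        for c in chunks
        if re.search(r"(?<!\w)PE(?!\w)", c.text)
        or re.search(rf"(?<!\w)(?:{terms})(?!\w)", c.text, re.IGNORECASE)
    ]
    assert once == oracle


# ---------------------------------------------------------------------------
# cosine + semantic filter


def test_cosine_identity_orthogonal_and_hand_value():
    assert cosine_similarity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)
    assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)
    assert cosine_similarity([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)


def test_cosine_errors():
    with pytest.raises(ValueError):
        cosine_similarity([0.0, 0.0], [1.0, 0.0])
    with pytest.raises(ValueError):
        cosine_similarity([1.0], [1.0, 0.0])


class SeededRandomEmbedder:
    """Deterministic per-text random embedding (independent of the package)."""

    def __init__(self, dim=16):
        self.dim = dim

    def _one(self, text):
        seed = abs(hash(text)) % (2**31)
        return np.random.default_rng(seed).normal(size=self.dim)

    def embed(self, texts):
        return np.array([self._one(t) for t in texts])


def test_semantic_filter_top_100_is_identity():
    chunks = chunks_from_texts([f"text {i}" for i in range(7)])
    out = semantic_filter(
        chunks,
        ExampleSentenceSet(),
        SeededRandomEmbedder(),
        SemanticFilterConfig(top_percent=100),
    )
    assert out == chunks


def test_semantic_filter_retains_exact_exemplar_match():
    examples = ExampleSentenceSet(sentences=["acute pulmonary embolism seen"])
    chunks = chunks_from_texts(
        ["completely unrelated text"] * 9 + ["acute pulmonary embolism seen"]
    )
    out = semantic_filter(
        chunks, examples, SeededRandomEmbedder(), SemanticFilterConfig(top_percent=10)
    )
    assert len(out) == 1 and out[0].text == "acute pulmonary embolism seen"


def test_semantic_filter_size_is_ceiling():
    chunks = chunks_from_texts([f"t {i}" for i in range(10)])
    out = semantic_filter(
        chunks,
        ExampleSentenceSet(),
        SeededRandomEmbedder(),
        SemanticFilterConfig(top_percent=25),
    )
    assert len(out) == 3  # ceil(2.5)


def brute_force_semantic(chunks, examples, backend, top_percent, aggregation="max"):
    """Score-all-then-sort oracle, written independently of the package."""
    ex = np.asarray(backend.embed(examples.sentences), dtype=float)
    scores = []
    for c in chunks:
        v = np.asarray(backend.embed([c.text]), dtype=float)[0]
        sims = [
            float(np.dot(v, e) / (np.linalg.norm(v) * np.linalg.norm(e)))
            for e in ex
        ]
        scores.append(max(sims) if aggregation == "max" else sum(sims) / len(sims))
    k = math.ceil(top_percent / 100 * len(chunks))
    ranked = sorted(range(len(chunks)), key=lambda i: (-scores[i], i))[:k]
    return [chunks[i] for i in sorted(ranked)]


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("top_percent", [5, 25, 60])
def test_semantic_filter_matches_brute_force_oracle(seed, top_percent):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 200))
    texts = [f"chunk {i} {'pe ' * int(rng.integers(0, 3))}" for i in range(n)]
    chunks = chunks_from_texts(texts)
    backend = SeededRandomEmbedder()
    examples = ExampleSentenceSet()
    got = semantic_filter(
        chunks, examples, backend, SemanticFilterConfig(top_percent=top_percent)
    )
    expected = brute_force_semantic(chunks, examples, backend, top_percent)
    assert got == expected


def test_semantic_filter_empty_input():
    assert semantic_filter([], ExampleSentenceSet(), SeededRandomEmbedder()) == []


# ---------------------------------------------------------------------------
# negation and triplets


def test_negate_chunk_template():
    assert (
        negate_chunk("acute PE identified on CTPA")
        == "No evidence of the following was found: acute PE identified on CTPA"
    )
    with pytest.raises(ValueError):
        negate_chunk("")
    twice = negate_chunk(negate_chunk("x"))
    assert twice.count("No evidence of the following was found: ") == 2


def _triplet_corpus():
    pos = make_chart(
        "POS",
        notes=[
            make_note("acute PE confirmed on imaging today.", "n1"),
            make_note("pulmonary embolism treated with heparin drip.", "n2", day=1),
        ],
        gold_label=1,
        with_summary=False,
    )
    neg = make_chart(
        "NEG",
        notes=[make_note("routine wound care performed.", "n3")],
        gold_label=0,
        with_summary=False,
    )
    return Corpus(charts=[pos, neg])


def test_build_triplets_enumeration():
    corpus = _triplet_corpus()
    triplets = build_triplets(corpus, negated_fraction=0.0, seed=1)
    assert len(triplets) == 2
    assert all(t.negative_source == "non_pe_chart" for t in triplets)
    assert all(t.negative == "routine wound care performed." for t in triplets)


def test_build_triplets_forced_negation_branch():
    triplets = build_triplets(_triplet_corpus(), negated_fraction=1.0, seed=1)
    assert all(t.negative == negate_chunk(t.anchor) for t in triplets)
    assert all(t.negative_source == "negated_anchor" for t in triplets)


def test_build_triplets_without_keyword_chunks_is_empty():
    corpus = Corpus(
        charts=[
            make_chart("A", notes=[make_note("nothing here")], gold_label=1, with_summary=False),
            make_chart("B", notes=[make_note("benign text")], gold_label=0, with_summary=False),
        ]
    )
    assert build_triplets(corpus) == []


class TableBackend:
    """Embeds texts via an explicit lookup table."""

    def __init__(self, table):
        self.table = table

    def embed(self, texts):
        return np.array([self.table[t] for t in texts])


def test_triplet_accuracy_perfect_and_tie():
    from pescreen.evidence import Triplet

    t = Triplet(anchor="a", positive="p", negative="n", negative_source="non_pe_chart")
    same = TableBackend({"a": [1, 0], "p": [1, 0], "n": [0, 1]})
    assert triplet_accuracy([t], same) == 1.0
    tie = TableBackend({"a": [1, 0], "p": [1, 0], "n": [1, 0]})
    assert triplet_accuracy([t], tie) == 0.0  # ties count as failures
    with pytest.raises(ValueError):
        triplet_accuracy([], same)


def test_triplet_accuracy_three_of_four():
    from pescreen.evidence import Triplet

    table = {
        "a1": [1, 0], "p1": [0.9, 0.1], "n1": [0, 1],   # satisfied
        "a2": [1, 0], "p2": [0.8, 0.2], "n2": [0, 1],   # satisfied
        "a3": [1, 0], "p3": [0.7, 0.3], "n3": [0, 1],   # satisfied
        "a4": [1, 0], "p4": [0, 1], "n4": [0.99, 0.01],  # violated
    }
    triplets = [
        Triplet(
            anchor=f"a{i}",
            positive=f"p{i}",
            negative=f"n{i}",
            negative_source="non_pe_chart",
        )
        for i in range(1, 5)
    ]
    assert triplet_accuracy(triplets, TableBackend(table)) == 0.75


# ---------------------------------------------------------------------------
# reduction summary


def test_summarize_reduction_medians_and_iqr():
    stage = {
        "raw": {"p1": (1, 10), "p2": (2, 20), "p3": (3, 30)},
    }
    table = summarize_reduction(stage)
    assert table.loc["raw", "chunks_median"] == 2
    assert table.loc["raw", "total_chunks"] == 6

    four = {"s": {f"p{i}": (i, 10 * i) for i in (1, 2, 3, 4)}}
    t4 = summarize_reduction(four)
    assert t4.loc["s", "chunks_median"] == 2.5
    assert t4.loc["s", "chunks_q1"] == 1.75  # linear-interpolation quartiles
    assert t4.loc["s", "chunks_q3"] == 3.25


def test_summarize_reduction_single_patient_iqr_zero():
    t = summarize_reduction({"s": {"p1": (5, 50)}})
    assert t.loc["s", "chunks_median"] == 5
    assert t.loc["s", "chunks_q1"] == t.loc["s", "chunks_q3"] == 5


def test_summarize_reduction_rejects_mismatched_patients():
    with pytest.raises(ValueError):
        summarize_reduction({"a": {"p1": (1, 1)}, "b": {"p2": (1, 1)}})
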