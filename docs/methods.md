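# Methods

This note records the modeling and design choices behind `pescreen`:
what each stage assumes, which knobs matter, what the synthetic corpus
does and does not emulate, and where the design was genuinely open.

## Problem framing

The target label is *pulmonary embolism as a hospital-acquired adverse
event* (PEAE): a PE that developed after admission and is linked to the
hospital stay.  Everything else — no PE, PE present on admission,
historical PE, community-acquired PE — is negative.  The task is
framed as high-sensitivity screening over a whole admission cohort:
false negatives are expensive (missed safety events), false positives
are tolerable because flagged charts go to human review.  At realistic
prevalence (~0.4%) even excellent specificity yields a low PPV; the
evaluation layer is built to make that arithmetic visible rather than
hide it.

## Evidence extraction

**Chunking.** Default strategy is paragraph splitting on blank lines
with a word-window fallback at `max_words=128`, `overlap=0`; sentence
and pure word-window strategies are available.  Chunks carry exact
character spans into their source note, so every downstream decision is
auditable.  With `overlap=0` the word-window spans tile the note text;
paragraph/sentence spans exclude the blank-line separators.

**Keyword filter.** The default term list is the obvious PE vocabulary
("PE" case-sensitive; "blood clot", "thrombosis", "pulmonary
embolism", "pulmonary embolus", "ctpe", "pe" case-insensitive), all at
word boundaries so "hoPEful" never matches.  The list is configuration,
not code: real deployments extend it with local documentation habits.
The acronym "PE" is kept case-sensitive in its own list because the
lowercase collision ("pe" inside words) is only controlled by the
word-boundary rule; the case-insensitive "pe" entry mirrors the
printed-note habit of lowercase acronyms.

**Semantic filter.** Chunks and ten exemplar PE-affirming sentences
(authored across note genres: imaging, nursing, assessment, discharge)
are embedded; each chunk is scored by its **maximum** cosine similarity
over exemplars — a chunk needs to resemble only one exemplar genre, so
max is preferred over mean (mean is available).  The top
`ceil(n% × N)` chunks are kept, ties broken toward earlier document
position, output restored to document order.  Default `top_percent=5`
produces an order-of-magnitude reduction comparable to keyword
filtering on synthetic corpora.  The bundled `HashingEmbedder`
(hashed word/bigram counts, English stopwords removed, L2-normalized)
is a deterministic lexical embedding: it makes vocabulary overlap —
exactly what the filter and the triplet evaluation exercise —
measurable without model weights.  A sentence-transformer drops in
behind the same `embed` contract for real use.

**Triplets.** For embedding adaptation/evaluation, anchors are
keyword-bearing chunks of gold-positive charts; positives are a
different keyword chunk (same chart preferred); negatives are either a
keyword-free chunk from an entirely keyword-free gold-negative chart or
a template negation of the anchor ("No evidence of the following was
found: …"), chosen with probability `negated_fraction` under a single
seeded generator.  The deterministic template replaces LLM-generated
negations: reproducibility and zero dependencies outweigh fluency for
contrastive negatives, and an LLM negator can be swapped in through the
generation contract.  Triplet accuracy counts strict
`cos(a,p) > cos(a,n)`; ties are failures.

## Discharge extraction

The six target sections are the canonical discharge-summary anatomy:
reason for hospitalization, significant findings, procedures and
treatments, medical history, discharge condition, patient and family
instructions.  Section finding is delegated to the generation backend
(instructed to emit JSON); the parser is total and tolerant — first
decodable JSON object wins (code fences and surrounding prose are
ignored), keys are matched case-/punctuation-insensitively with
aliases, missing keys become empty strings.  Status is `ok` (all six
keys present), `partial` (≥1), or `failed` (none); `partial` exists so
detection prompts can still use whatever was recovered.

## Detection

The prompt contains, in order: the task instruction (did a PE develop
*after* admission, not present on admission?), the admission and
discharge dates, the dated evidence chunks oldest-first (or an explicit
placeholder when no evidence survived filtering), the discharge
sections when requested and not failed, and the output instruction
(answer "yes"/"no" first, then justify).  Dialect wrapping — Phi-3
`<|im_start|>`/`<|im_end|>`, Mistral `[INST]`, Llama-3 and Gemma role
markers, or none — is a reversible prefix/suffix applied last, so the
payload is recoverable from any wrapped prompt.  Prompt wording lives
in `data/prompts.yaml`, not code.  An optional `max_chars` budget drops
the *oldest* evidence chunks first (recent notes are where a
hospital-acquired event is documented) and logs each truncation.

Classification is deliberately minimal: the first sentence (up to the
first of `. ! ?` or newline) is positive iff it contains the word
"yes" at a word boundary, case-insensitively.  Empty or failed
generations classify as 0 with a flag rather than raising — a
screening tool must be total over a corpus.  The two-step clinical
logic (PE present? hospital-acquired?) is encoded in one prompt and one
backend call, not two.

**Rule-mock backend.** The tested backend is a deterministic rule
engine over the prompt payload: it affirms iff some evidence line
contains a PE-affirming phrase, no negation cue ("no", "not", "ruled
out", "history of", …) appears *before* the phrase within the sentence,
and the line's date is ≥2 days after the stated admission date.  The
2-day threshold is a synthetic-world convention for "hospital-acquired",
stated in configuration, not a clinical claim.  The prefix-scoped
negation rule is an intentional, documented limitation: post-positioned
negations ("… was ruled out") slip through, giving the mock a realistic
and attributable false-positive mode.  For discharge prompts the mock
parses the summary's section headers and echoes the sections as JSON.

## Evaluation

**Metrics.** PPV, sensitivity, specificity, NPV as percentage ratios of
the 2×2 counts; F1 as the harmonic mean of PPV and sensitivity.  0/0
denominators yield 0 with a `degenerate` flag.

**Bootstrap.** Percentile bootstrap at the patient level, default
10 000 resamples, 95% interval, mean-over-resamples reported alongside
the point estimate.  Implementation detail: since every metric is a
function of the four confusion counts alone, resamples are drawn as
multinomial counts over (tp, fn, fp, tn) — distributionally identical
to resampling patient indices with replacement and far faster.
Degenerate resamples are skipped and counted; a metric whose every
resample is degenerate is flagged missing.  Stratification is not used.

**Surveillance.** Patients are binned by admission date (discharge-date
binning via flag) at year, year-quarter, or year-month granularity;
actual and predicted **incidence proportions** (positives / admissions
per period) are compared by MSE, Pearson *r*, and *R*² = *r*².
Proportions rather than raw counts are compared because period
populations vary; this normalization choice is documented, not claimed
as canonical.  Fewer than two periods, or a zero-variance series, flags
the trend metrics undefined rather than fabricating them.  A property
worth stating precisely: with a fixed per-patient false-positive rate,
aggregation provably shrinks the *variance* of the per-period error
(it scales as 1/n_period), and the test suite checks exactly that; the
per-period Pearson correlation, by contrast, is granularity-invariant
in population value when prevalence is constant over time, because both
the signal and the noise variance scale identically with period size —
yearly correlation only dominates monthly when incidence has real
temporal structure (trends or seasonality) for aggregation to preserve.

**ICD baseline.** 1 iff any diagnosis code matches a configured prefix
(default `I26`) and, by default, is not flagged present-on-admission.
The deployed code list of any real Discharge Abstract Database is not
public; the prefix set is configuration.

**Cohort summary.** Counts and percentages by event status for age
bands (<50, 50–64, 65–74, ≥75), sex, in-hospital death, comorbidity
bands (0, 1, ≥2), and length-of-stay bands (1–4, ≥5 days), each tested
with chi-square without continuity correction (Fisher's exact via flag
for 2×2); p-values below 0.001 render as "<.001".  Quartiles
everywhere use linear interpolation between closest ranks — IQR
conventions differ enough to be worth pinning.

## Synthetic corpus generator

The generator emulates: admissions uniform over 2017–2022; gold labels
Bernoulli at configurable prevalence (default 0.004, matching the
cohort shape this tooling targets; tests mostly use 0.05 to stabilize
metric estimates at desk-scale n); a 12-type note vocabulary sampled
from a ~120-type pool, always including diagnostic imaging reports;
Poisson note counts (mean 6); benign templated filler text; a
six-section discharge summary for every chart; demographics drawn to
plausible marginals; ICD codes consistent with the label (I26.9
non-POA for a configurable fraction of positives — administrative
undercoding is the norm — and confounder-driven miscodes on negatives);
and longer stays for positives.  Positive charts receive one affirming
imaging sentence dated ≥2 days post-admission plus a consistent
discharge-summary mention; negative charts receive confounder sentences
at per-category rates (default 2% each): negated PE, historical PE, PE
present on admission (affirming sentence dated day 0–1), pulmonary
edema, prophylactic anticoagulation.  One of the four negation
templates places its cue *after* the mention, which the rule-mock
misses by design — the planted, attributable false-positive mechanism.

Every planted sentence is recorded with its exact span, note, and
timestamp, so tests can verify end-to-end recovery chunk by chunk.
Generation is byte-deterministic under (config, seed).

What the generator does **not** emulate: real clinical language
(templates, not prose), inter-note redundancy and copy-forward,
documentation lag between event and note, coding-vocabulary realism
(SNOMED/LOINC), or temporal structure in incidence (prevalence is
constant over the window).  Consequently, passing tests demonstrate the
*mechanics* — retrieval, prompting, classification, scoring — under
controlled confounding, not clinical performance on real charts.

## Numerical and degenerate-input conventions

- Cosine similarity errors on zero vectors and dimension mismatch;
  inside the semantic filter a zero-vector *chunk* scores −1 (floor)
  instead of erroring, since all-stopword chunks are legitimate data.
- Percentile CIs and quartiles use numpy's linear interpolation.
- Empty notes chunk to empty lists; empty corpora read as zero charts;
  classification of empty generations is 0 with a flag.
- All randomness (generator, triplet sampling, bootstrap) flows from
  explicit integer seeds through `numpy.random.default_rng`.

## Problem sizes used in the shipped checks

End-to-end recovery runs on 5000-patient corpora (clean and
confounded); bootstrap calibration on 100 toy corpora of 150 patients
at 1000 resamples; surveillance comparisons on twenty 3000-patient
corpora spanning the six-year window.  These sizes make every check a
from-scratch computation while keeping the default suite fast.

## Known limitations

- The rule-mock backend shares template knowledge with the generator by
  construction; it validates plumbing and bookkeeping, not language
  understanding.
- The exemplar sentences and prompt wording are authored defaults, not
  fitted artifacts; swapping either changes semantic-filter behavior.
- The keyword list is a starting point; recall against local
  documentation habits must be validated per site.
- `summarize_cohort` assumes one admission per patient (the corpus
  invariant) and does not adjust tests for multiplicity.
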