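# pescreen

Screening for **pulmonary embolism as a hospital-acquired adverse event
(PEAE)** in narrative electronic medical records.

Hospital-acquired PE is rare (on the order of 0.4% of admissions),
buried in hundreds of free-text notes per stay, and hard to separate
from look-alikes: PE present on admission, historical PE, negated
mentions, pulmonary *edema*, and anticoagulants given as prophylaxis.
`pescreen` implements an LLM-based screening pipeline for this problem,
plus the evaluation machinery to judge it both per patient and as a
population-surveillance instrument:

1. **Evidence extraction** — each note is chunked (paragraphs,
   sentences, or word windows) and filtered either by PE keywords
   ("PE", "blood clot", "thrombosis", "pulmonary embolism", "ctpe", …,
   word-boundary matched) or by embedding similarity to a set of
   exemplar PE-affirming sentences, keeping the top *n*% of chunks by
   best cosine similarity.
2. **Discharge information extraction** — a generation backend is
   prompted to return six canonical sections of the discharge summary
   (reason for hospitalization, significant findings, procedures and
   treatments, medical history, discharge condition, patient and family
   instructions) as JSON, parsed tolerantly.
3. **Detection** — the dated evidence, temporal facts and discharge
   sections are assembled into a single binary prompt (wrapped in the
   target model family's chat dialect: `llama3`, `mistral`, `gemma`,
   `phi3`, or `plain`), and the generated answer is classified by a
   first-sentence heuristic: label 1 iff the first sentence contains
   the word "yes".
4. **Evaluation** — PPV, sensitivity, specificity, NPV and F1
   (percentages) with percentile bootstrap 95% CIs over patient-level
   resampling (default 10 000 resamples); incidence-trend scoring
   (MSE, Pearson *r*, *R*² = *r*²) of predicted vs actual incidence
   proportions per year, year-quarter or year-month; an ICD-10 rule
   baseline (default: any non-present-on-admission I26.x code); and
   Table-1-style cohort summaries with chi-square tests.

Because real chart corpora cannot be shared, the package ships a
first-class **synthetic EHR generator** that emulates the statistical
shape of such a cohort (rare positives, 2017–2022 admissions, many note
types, six-section discharge summaries, label-consistent ICD codes,
confounder mentions at configurable rates) with exact span-level gold
bookkeeping, and a deterministic **rule-mock generation backend** so the
whole pipeline is testable end to end without any model weights.  Real
LLMs plug in behind a one-method `generate(prompt) -> text` contract.

## Worked example

```bash
pescreen synth --n-patients 2000 --prevalence 0.05 --seed 7 --out ex.jsonl
pescreen detect ex.jsonl --retrieval keyword --discharge --out-dir ex_run
```

prints (metric means over 1000 bootstrap resamples, 95% CIs):

```
config 50ae3edc2b8e: 2000 patients scored
PPV	Sensitivity	Specificity	NPV	F1 score
94.06 (89.09-98.11)	100.00 (100.00-100.00)	99.68 (99.42-99.90)	100.00 (100.00-100.00)	96.93 (94.23-99.05)
```

Every planted hospital-acquired PE was recovered (sensitivity 100%);
the handful of false positives (PPV < 100%) all come from planted
confounder sentences — here, post-positioned negations ("… was ruled
out") that the rule backend's prefix-scoped negation handling misses,
mirroring the contextual errors real LLMs make.  Note that at a
realistic prevalence of 0.4% the same specificity would produce a far
lower PPV: high-sensitivity screening, not confirmation.

```bash
pescreen surveil ex.jsonl ex_run/predictions.tsv --granularity year
```

reports the yearly incidence trend comparison:

```
mse 2.08e-05   pearson_r 0.980   r_squared 0.960
```

i.e. the predicted yearly incidence series tracks the actual series
closely even though individual false positives remain.  The other
subcommands are `extract`, `discharge`, `evaluate`, and `compare` (the
2×2 grid of retrieval method × discharge inclusion).

## Layout

```
src/pescreen/
  corpus.py      chart data model, JSON-lines corpus I/O, validation
  evidence.py    chunking, keyword & semantic filters, triplets
  discharge.py   six-section discharge extraction and parsing
  detection.py   prompt assembly, yes/no classification, orchestration
  backends.py    hashing embedder + deterministic rule-mock generator
  evaluation.py  metrics, bootstrap CIs, surveillance, ICD baseline
  synthetic.py   gold-annotated synthetic EHR corpus generator
  pipeline.py    end-to-end runs, config hashing, condition grids
  cli.py         `pescreen` command-line interface
```

See `docs/methods.md` for the modeling choices and their rationale.
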