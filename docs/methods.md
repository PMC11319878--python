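# Methods

## Annotation schema

Entities are categorized into primary groups (the clinical subject of a
criterion) and modifier groups (its constraints); anything outside the
primary groups is `other_observation`.  Relations run primary → modifier,
except `has_outcome` which joins two primaries (a prior therapy and the
disease status it produced).  The validator constrains relations only by
category, not by specific source group: the legal source-group inventory
per relation is an open question in the source material, and guessing a
tighter constraint would reject plausible annotations.  Character offsets
are 0-based half-open (the dominant standoff convention), and mentions are
flat — overlapping spans are validation errors, since the schema has no
nested examples.  Attribute names within a group (e.g.
`prior_therapy::chemotherapy`) are a free-text subfield of the mention, not
separate groups.

## Sequence tagger

The tagger is a BiLSTM-CRF implemented directly in numpy (forward and
backward passes hand-derived), trained per sentence with Adam.

* **Inputs.** Lower-cased token embeddings (dim 32, randomly initialized
  and learned — no pretrained vectors, keeping the build offline) are
  concatenated with a character feature: character embeddings (dim 12)
  convolved over trigram windows with 16 filters and max-pooled.  Unknown
  tokens and characters map to `<unk>`.
* **Encoder.** One bidirectional LSTM layer, 32 hidden units per
  direction; a linear layer maps the 64-dim state to per-tag emissions.
* **CRF.** Linear-chain with learned transition, start and end scores.
  The loss is the negative log likelihood; gradients are the classical
  moment differences (node/edge marginals from forward–backward minus the
  gold indicator counts).  Decoding is exact Viterbi under a structural
  mask that forbids `I-x` after anything other than `B-x`/`I-x`, so the
  output is always a valid BIO string.
* **Training protocol.** Per-sentence Adam (lr 0.01, clip ±5), default 3–4
  epochs; the 80/20 train/test split is by criterion sentence,
  seed-controlled, and stratified by label presence (a held-out-only label
  is either swapped into training or reported as a `LabelCoverageError`
  naming the label).  With a fixed seed, training is bit-reproducible on
  the same machine (single-threaded numpy, deterministic RNG).
  `train_with_stopping` exposes the iterative annotate-and-retrain loop
  that stops once held-out macro F1 exceeds 0.8.
* **Relation linking** is rule-based, not learned: each modifier links to
  the nearest preceding compatible primary (falling back to the nearest
  following), and the relation name is a function of the modifier group.
  A learned relation model would need an architecture the source material
  does not specify; the deterministic rule is transparent and exactly
  recovers the template corpus's modifier relations.

## Evaluation conventions

A true positive is an exact (span, label) match — no partial credit, since
any partial-credit scheme would be an invention.  Macro precision/recall/F1
average uniformly over the labels present in gold.  The bundled 17-row
reference score table is used for arithmetic identity checks; because its
precision/recall columns are 3-decimal roundings, a harmonic mean
recomputed from them can differ from the printed F1 by up to one unit in
the third decimal, and the identity tests use exactly that tolerance
(1e-3).

## Normalization

Rule precedence is: miscellaneous rules (case-fold, strip all whitespace —
applied to every pattern key), then concept-dictionary lookup (which
carries the CUI), then the longest-matching synonym rule; comparator,
temporal and unit rules are separate lookups used where those slots occur.
Within a class the first table row wins ties.  Temporal phrases outside the
table normalize to a canonical `within N unit` form (day counts divisible
by 7 collapse to weeks; number words one–twelve are recognized) so windows
stay machine-comparable rather than failing.  Value phrases like
`≤2.5x ULN` parse into (comparator, 2.5, `xULN`).  Unresolved surfaces pass
through flagged `uncurated`; curation overrides win over rules, with a
warning when they contradict a rule-resolved surface.  The full pipeline is
idempotent, and the bundled concept dictionary is deliberately small — a
full terminology (UMLS-scale) is a licensing-restricted drop-in, not a
bundle.

## Knowledge base

EAV identity is the quadruple (entity group, attribute name, value,
condition); duplicate identities merge with unioned source trials, and a
primary mention with conflicting value links yields both records flagged.
Primaries without a value modifier are presence assertions (`yes`, or `no`
under negation); temporal/condition/exception modifiers land in the
condition field.  Representative laboratory thresholds are the mode of the
per-trial value histogram; ties break toward the stricter threshold — the
smaller multiple-of-ULN for upper bounds, the larger count/concentration
for lower bounds — and are reported.  The bundled value histograms are
synthetic defaults shaped like published trial-count distributions (mode at
the field-typical threshold, e.g. ANC ≥ 1500 cells/µL); they are inputs to
the analysis code, not outputs of it.

Bundle notes: the reference ANC row is stored on a count basis (lower
bound 1500 cells/µL, upper 8000) because clearance-style units are not
meaningful for a cell count; hemoglobin thresholds appear with several
unit spellings in the g/dL family in the wild, and the bundle stores the
numeric 9 with `mg/dL` as transcribed in the expansion table while the
physiological unit is g/dL — users matching real data should normalize the
family.  ICD-9 patterns with bracket ranges (`428.[2-4][0-3]`) are stored
as character classes and matched as such; plain ICD-10 codes match as
prefixes at a code boundary (`I21` covers `I21.x`).  Exceptions to
umbrella exclusions (second malignancy) are encoded as value `yes` plus an
attached exception list.  RxNorm codes outside the five reference entries
are synthetic stand-ins in a reserved 900000+ namespace (flagged in the
bundle's `source` column); they give the ecosystem internal consistency
and should be replaced from a current RxNorm release for real-world use.

## Patient matching

The LOINC mapping cascade applies four rules in order, each refining the
candidate set and never enlarging it: best popularity rank, serum/plasma
sample preference, gram-based over molar units, and methodless preference;
survivors after rule 4 are reported as an ambiguity, never guessed.
ULN/LLN conversion is `value / bound(sex)` after unit-compatibility
checking (identical or table-equivalent spellings); with unrecorded sex
the male/female midpoint is used with a logged warning.

Criterion evaluation is three-valued.  Quantitative labs use the most
recent result on or before the index date (optionally within the
criterion's temporal window); missing labs, vitals and untested biomarkers
are `unknown`, while coded diagnoses, medications and procedures are
closed-world (no code ⇒ absent), the usual EHR convention.  Exclusion
(or negated) predicates disqualify on presence, with exception concepts
able to rescue.  Stage criteria match any substage via the leading roman
numeral (`III` covers `IIIA/IIIB`).  The funnel applies predicates
conjunctively in order; the default unknown-handling policy is
conservative (`unknown` ⇒ not eligible), switchable to `ignore_unknown`,
because the missing-data convention behind published funnel counts is
never stated.  The index date is a per-run parameter (default 2020-01-01
in the simulators).  Temporal windows convert at 7/30/365 days per
week/month/year.

## Synthetic data

The criteria generator realizes hand-written sentence templates covering
all 10 primary groups, 9 modifier groups and 10 relation types, with slot
fillers drawn from the bundled code and synonym tables; gold mentions are
constructed with the text, token-aligned by design.  Paraphrase/typo noise
is off by default.  The cohort generator samples coded patients and
records each patient's verdict per predicate *at generation time* by
direct comparison of the latent values (its own ULN table, its own
comparison logic) — the matcher under test never touches the ground
truth.  Defaults mirror the emulated study conditions: 246-sentence
corpora (2000 for the learning check), 2775-patient cohorts,
nonsquamous-histology prevalence 0.78, a stage-III/IV marginal of 0.197,
log-normal laboratory values straddling their thresholds (e.g. ALT median
50 U/L, σ=0.75 against ULN 56), an ECOG distribution with
P(≤1)=0.42 and P(≤2)=0.53, and comorbidity/medication prevalences of
5–10%.  These reproduce the *shape* of a realistic eligibility funnel;
they do not emulate real sentence statistics, EHR missingness patterns
(beyond configurable rates), correlated laboratory panels, or
longitudinal record depth — so passing tests demonstrate pipeline
correctness, not real-world extraction or matching accuracy.

## Problem sizes and budgets

The test suite trains the tagger once on a 2000-sentence seed-fixed corpus
(about 10 s at the default dimensions) and checks funnel/oracle agreement
on 50 cohorts of 10,000 patients (about 90 s); the acceptance script uses
10 such cohorts.  These sizes were chosen as the smallest at which the
stochastic checks are meaningful — the templated corpus is low-entropy, so
the learning check clears its 0.8 macro-F1 bar with large margin.

## Known limitations

* The tagger's perfect scores on template corpora reflect template
  regularity; real criteria prose is far harder, and no claim is made
  about transfer.
* Relation extraction is deliberately rule-based; discontinuous or
  cross-sentence relations are out of scope.
* The unit system covers only the bundled equivalences plus ULN/LLN
  multiples — it is not a general unit-conversion engine.
* Patient-matching accuracy against expert chart review cannot be
  evaluated here: no reproducible gold standard exists for that
  comparison.
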