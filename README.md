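# elikb — eligibility-criteria knowledge engineering

`elikb` turns free-text clinical-trial eligibility criteria into a
machine-computable knowledge base and simulates how each criterion shapes
the pool of eligible patients in coded EHR-style data.  It is aimed at
clinical-trial informaticists and protocol designers who want to answer
questions like *"how many patients do we lose if we require ALT ≤ 1.0×ULN
instead of ≤ 2.5×ULN?"* without hand-screening charts.

The pipeline has four stages:

1. **Extraction.** Criterion sentences are annotated against a dedicated
   schema of 10 *primary* entity groups (demographic, diagnosis, biomarker,
   disease status, prior therapy, comorbidity, laboratory test, vital,
   procedure, other medication), 9 *modifier* groups (value, condition,
   evidence, lines of therapy, negation, exception, grade, dose, temporal)
   and 10 relation types (`has_value_limit`, `has_temporal_limit`, ...,
   `has_outcome`).  The tagger is a BiLSTM-CRF: character-convolution and
   token embeddings feed a bidirectional LSTM whose states score BIO tags
   under a linear-chain CRF, trained by maximum likelihood
   (∂NLL/∂emissions = marginals − gold) and decoded exactly with Viterbi.
   Precision, recall and F1 are TP/(TP+FP), TP/(TP+FN) and their harmonic
   mean, computed per `group::attribute` label with exact-span matching.
   A deterministic longest-match lexicon tagger serves as the
   pre-annotation baseline, and relations are linked by nearest-compatible
   rules.
2. **Normalization.** Surfaces collapse to canonical attributes through a
   concept dictionary (CUI-bearing), a rule table (synonyms, comparators,
   temporal windows, units; case-insensitive and whitespace-stripped), and
   manual-curation overrides.  The cascade is idempotent and every output
   carries a provenance label.
3. **Knowledge base.** Normalized annotations fold into
   Entity-Attribute-Value records, e.g. `(laboratory_test, AST, ≤2.5×ULN)`.
   Hypernyms such as *adequate organ function* or *cardiovascular disease*
   expand into hyponym/value lists, representative laboratory thresholds
   are the modal value across trials, and bundled ICD-9/10, LOINC (with
   normal ranges) and RxNorm tables make records computable.
4. **Patient matching.** Patients' local laboratory tests map to LOINC via
   a four-rule cascade (popularity rank → serum/plasma → gram-over-molar
   unit → methodless); absolute values convert to multiples of the
   upper/lower limit of normal (value / ULN, sex-specific); criteria
   evaluate three-valued (match / no match / unknown) with exclusion
   inversion and exception rescue; and a sequential funnel reports
   surviving patient counts per criterion.

A first-class synthetic-data module generates annotated criterion corpora
(from templates covering the full schema) and patient cohorts with
*planted* eligibility, so every stage is testable offline.

## Worked example

Simulate a 2775-patient cohort and run the default trial design —
nonsquamous histology, stage III/IV, AST and ALT ≤ 2.5×ULN, ECOG ≤ 1:

```bash
elikb simulate cohort --seed 1 --n 2775 --out cohort/
elikb funnel --criteria cohort/criteria.json --patients cohort/ \
             --index-date 2020-01-01 --out funnel.json
```

```
diagnosis histology nonsquamous: 2775 -> 2170
diagnosis stage III/IV: 2170 -> 391
laboratory_test AST ≤2.5xULN: 391 -> 362
laboratory_test ALT ≤2.5xULN: 362 -> 328
vital ECOG ≤1: 328 -> 136
final eligible: 136 / 2775
```

Each line is one criterion applied conjunctively: 78% of the cohort has
nonsquamous histology, the stage restriction is the harshest single filter,
the liver-function thresholds cost comparatively little, and the ECOG
restriction more than halves the remainder.  The generator also writes
`ground_truth.json` with the counts planted at sampling time; the funnel
reproduces them exactly.

Hypernym expansion from the bundled knowledge base:

```bash
$ elikb expand --hypernym "normal hepatic function"
AST	≤2.5x ULN
ALT	≤2.5x ULN
Total bilirubin	≤1.5x ULN
```

The extraction stage composes the same way: `elikb simulate criteria` emits
a templated corpus with gold standoff annotations, `elikb train` fits the
BiLSTM-CRF on an 80/20 split, `elikb extract` tags new criteria, `elikb
eval` scores them, and `elikb normalize` / `elikb build-kb` produce the EAV
table.

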