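# Methods

This note documents the model implemented by `abc-autoscore`, its
assumptions, parameter defaults, numerical choices and the scope of what the
synthetic-data tests do and do not demonstrate.

## The instrument

The Addiction Behaviors Checklist is a 20-item observational instrument:
clinicians endorse items describing aberrant opioid-related behaviors
(hoarding medication, running out early, obtaining opioids from multiple
prescribers, anger when medications are discussed, …) and the total score is
the count of endorsed items. Automation replaces the clinician's endorsement
with evidence extracted from their own notes: an item is endorsed for a
patient iff at least one pattern match for that item survives the filter
chain in any of the patient's notes inside the scoring window. Match
multiplicity is deliberately ignored — the instrument is a checklist,
not a frequency count — which also makes scores invariant to duplicated
notes or repeated boilerplate.

## Match pipeline

Matching is sentence-scoped. The stages, in order:

1. **Core expression.** Each item has ≥ 1 case-insensitive regular
   expression; the default configuration carries 27 expressions across the
   20 items. A hit's character span (0-based, half-open, note-level) is the
   audit anchor.
2. **Opioid context.** Items whose trigger words are not intrinsically
   opioid-specific ("angry", "lost", "needs") require a term from the opioid
   lexicon in the same sentence. Lexicon entries are word-initial stems
   (`narc` covers "narcotic(s)"; intentional misspellings `opiod`,
   `stockpil`, `analges` are entries, not typos). Two items (hoarding,
   needing/having to have) additionally require the opioid term to *follow*
   the trigger, mirroring the "followed by" construction of the hoarding
   rule; all other items accept the term anywhere in the sentence, since
   clinical word order is otherwise uninformative.
3. **Negation.** A negation-lexicon term (7 entries: denies, denied, no,
   not, without, never, negative for) occurring strictly *before* the
   trigger within the sentence vetoes the hit. The window is the whole
   preceding part of the sentence — no token-distance cap — trading a little
   precision for simplicity and transparency.
4. **False-positive prefix.** A hit preceded anywhere earlier in the note by
   "discharge instructions" is discarded. The scan is note-wide rather than
   sentence-wide because the phrase functions as a section header: all
   medication mentions after it are boilerplate until the note ends.

Sentence segmentation splits on `.`, `!`, `?` and newlines, with a short
abbreviation stop-list (Dr., mg., …) and a decimal guard (2.5 does not
split). Spans partition the non-whitespace text, so audits can always
reconstruct the source. Segmentation never needs to be perfect: an
over-split sentence can only make the context/negation filters more
conservative.

Filter ordering gives the monotonicity property used throughout the tests:
enabling any filter can only remove matches, never add them.

### Reconstructed defaults

The original instrument's full lexicons and expression set are not
distributed with the package; the shipped YAML is an authored reconstruction
built from the published item texts, the documented hoarding-item stems and
opioid fragments, and a minimal 7-term negation lexicon. Which items enable
which filters is likewise a reconstruction (opioid context is required
exactly where the trigger vocabulary is opioid-nonspecific). Everything is
externalized in `data/default_patterns.yaml`, schema-validated on load, and
hashed (SHA-256 of the canonical JSON form) into all outputs so results are
traceable to an exact instrument definition.

## Cohort and scoring rules

* Chronic-pain cohort: a qualifying ICD code on ≥ 2 *distinct calendar
  dates* (timestamps truncated to dates), age ≥ 13 years at the earliest
  qualifying date. Patients lacking a birth date are excluded with a
  warning rather than assumed adult. Code matching is exact string equality
  after uppercasing/stripping, not prefix matching; the default code set is
  the four published examples (338.2, 338.21, G89.2, G89.21) and is
  user-extensible.
* Scoring window: optionally only notes dated on or before a cutoff
  (consent-date semantics from the external-validation design); default is
  the full record.
* Patients with zero notes are retained with `no_notes_flag` and total 0 and
  excluded from evaluation by default (they were never scanned);
  `include_no_notes` keeps them as score 0.
* Threshold selection maximizes F1 over τ ∈ {0, …, 20}; "best balance of
  sensitivity and PPV" is operationalized as F1 because that is the summary
  reported at chosen operating points. Ties go to the smallest τ (favoring
  sensitivity), compared with a 1e-12 tolerance because mathematically equal
  F1 values can differ by an ulp across evaluation orders.

## Evaluation battery

* Confusion metrics use explicit denominators; any metric with a zero
  denominator is NaN, never 0. F1 is the harmonic mean of PPV and
  sensitivity.
* ROC-AUC is the tie-corrected rank statistic
  P(score_case > score_control) + ½ P(equal), computed from average ranks;
  for integer scores the operating curve enumerates thresholds
  {0, …, max+1} with no interpolation (for step curves the rank and
  trapezoidal formulations coincide). A binary predictor's AUC reduces
  exactly to (sensitivity + specificity)/2, which is how the diagnosis-code
  baseline is scored.
* Recall–precision curves keep one point per achievable integer threshold
  and drop thresholds with no positive predictions (undefined precision).
* φ coefficients use the closed-form 2×2 formula
  (n11·n00 − n10·n01)/√((n11+n10)(n01+n00)(n11+n01)(n10+n00)); items with
  zero variance yield flagged-undefined cells rather than imputed values.
  φ equals the Pearson correlation of the 0/1 vectors, which the tests use
  as an independent oracle.
* Confidence intervals are nonparametric patient-level percentile
  bootstraps, B = 2000 by default, deterministic given a seed. For metrics
  derived from a 2×2 table, patient resampling is implemented as multinomial
  resampling of the four cells (an exact equivalence). Resamples on which a
  statistic is undefined (e.g. no cases drawn) are redrawn and counted; the
  estimator choice is a package decision, as the source analyses report 95%
  CIs without naming a method.

## Synthetic corpus generator

The generator emulates the *structure* of a chronic-pain EHR cohort, not its
language:

* **Note volume**: 1 + negative-binomial counts (default mean 5,
  dispersion 1.2) to mimic heavy-tailed real-world note counts, at desk
  scale. Real cohorts run to hundreds of notes per patient; the
  package's complexity is linear in note count, so scale-up is routine.
* **Per-item mention prevalence**: 20 probabilities, defaults 0.03–0.22
  with the general-substance-use and analgesic-discussion items most
  frequent, matching the observed dominance of those behaviors in clinical
  documentation.
* **Noise channels**: negated mentions (default rate 0.15 per item-patient),
  non-opioid decoys (0.10) for items with an opioid-context filter, and
  discharge-instruction notes (0.15 per patient) whose post-header sentences
  would match an item but must be vetoed by the prefix filter.
* **Labels**: case status is Bernoulli with logit-linear probability in the
  true total score (intercept −1.6, slope 0.9), giving a monotone
  score–risk link and roughly 30–40% case prevalence under defaults; cases
  are split some/high evidence 65/35.
* **Diagnosis codes**: every patient gets chronic-pain codes on 2 distinct
  days (so the cohort builder admits everyone); OUD codes appear on 2
  distinct days with probability 0.30 for cases and 0.02 for controls, plus
  a 0.05 single-day spurious-code channel that must stay negative under the
  ≥ 2-day rule. Because case probability is monotone in score, code
  prevalence rises with the score — the qualitative gradient seen in real
  score-stratified tables.

Every planted sentence comes from a fixed template bank aligned with the
default pattern configuration, and the ground truth records exactly which
items were truly planted. This makes **exact recovery** a testable contract:
match → score on a generated corpus must reproduce every planted item flag
(and nothing else). The test suite verifies the alignment sentence by
sentence — each positive template matches exactly its own item; negated,
decoy, filler and discharge templates match nothing.

What passing these tests shows: the engine implements the specified filter
semantics exactly, end to end, including interactions (negation inside
sentences, note-level prefix exclusion, window logic). What it does not
show: performance on real clinical text, whose phrasing variety, typos,
copy-forward structure and section headers the template bank deliberately
does not model. `hard_mode` plants paraphrases outside the pattern
vocabulary to create known false negatives for benchmarking; it is excluded
from the recovery contract.

## Published reference points

The headline performance figures for the instrument itself (primary-site
F1 0.73 and AUC 0.82; validation-site F1 0.70 and AUC 0.86 at thresholds 2
and 6 respectively; item φ range −0.01 to 0.32) were computed on protected
EHR corpora and cannot be reproduced here; they are context, not targets.
Two quantities are fully determined by printed counts and are pinned by
tests and the acceptance script: rebuilding the adjudication-by-code
contingency (49 no / 33 some / 17 high evidence; 0/1/1 code-positive on ≥ 2
days) gives the diagnosis-code baseline F1 = 0.08 and rank-AUC = 0.52 at the
printed 2-decimal precision.

## Numerical and degenerate-input choices

* Offsets are 0-based half-open everywhere; identical spans from multiple
  core expressions of one item are deduplicated, distinct spans are kept.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical corpora and outputs. Derived seeds stay below
  2³¹.
* Empty note text, empty match lists, all-one-class labels, zero-variance
  items and zero-denominator metrics are all explicit cases: the first two
  produce empty/zero outputs, the rest raise or propagate NaN as documented.
* The bootstrap-coverage experiment in the acceptance checks uses 120 cases
  / 80 controls, true sensitivity 0.7, B = 500 over 500 replicates — sizes
  chosen so the binomial granularity of a percentile CI for a proportion
  sits well inside a ±3-point band around nominal 95%.

## Known limitations

* Negation is positional, not syntactic: "not only taking more than
  prescribed" would be (wrongly) vetoed, and post-trigger negation ("urine
  screen showed no unexpected substances") is not caught. Template design
  avoids these constructions; real text will not.
* The prefix-exclusion scan has no end-of-section detection; a discharge
  header suppresses all later matches in that note.
* The 27 default expressions are a reconstruction; item-to-expression
  assignment and per-item filter enablement at the original sites are not
  public. The config format supports any assignment.
* Per-visit (longitudinal) scoring, FHIR connectivity, concept-extraction
  engines and statistical text classifiers are out of scope by design.
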