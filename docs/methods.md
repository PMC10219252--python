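# Methods

## Problem and approach

Fabry disease (FD) is an X-linked lysosomal storage disorder with an
incidence around 1:40,000 and a famously non-specific, multi-system
presentation; diagnosis is typically delayed by years. `fdscreen`
implements a transparent, factor-based screening pipeline over electronic
health records (EHRs): free-text clinical notes are mined for FD-relevant
findings with a rule-based NLP pipeline, findings are combined with ICD-10
codes and laboratory values into 13 scored clinical features, the feature
scores are summed into a per-patient risk factor, and patients whose risk
factor reaches a cut-off are flagged for confirmatory testing (dried blood
spot enzyme assay in practice). Because the prevalence is tiny, the system
is a screening triage, not a classifier: the operating goal is to shrink
the pool sent to physicians by orders of magnitude while keeping
sensitivity high.

## Entity extraction

Extraction is a deterministic nine-step pipeline:

1. **Pattern compilation.** Each dictionary term (canonical form plus
   synonyms) is compiled into token-level patterns: a sequence of per-token
   regexes matched with `fullmatch`, so matches are anchored at token
   boundaries and never fire inside a longer word.
2. **Sentence splitting.** Rule-based: split after `.`/`!`/`?` followed by
   whitespace and a capital or digit.
3. **Normalization.** Tokens are lower-cased; out-of-vocabulary alphabetic
   tokens of length >= 4 are corrected to a dictionary token at Levenshtein
   distance 1 (in-vocabulary tokens are never rewritten; the length floor
   keeps short function words from being "corrected" into dictionary
   tokens); an ordered suffix-rewrite table performs lemmatization
   (first matching rule wins). All rules are config data, so the pipeline
   is language-portable; the shipped lexicon is English.
4. **Tokenization.** Whitespace split with punctuation separated
   (`\w+|[^\w\s]`).
5. **Pattern search.** All patterns are scanned over the token sequence,
   with a first-literal index for speed. Overlaps are resolved
   longest-match-first, ties by leftmost start, then dictionary order —
   so "cornea verticillata" beats a bare "cornea" entry on the same span.
6. **Negation detection.** A mention is negated iff a cue token ("no",
   "not", "without", "denies", ...) occurs within 5 tokens before the
   mention inside the same sentence, with no adversative conjunction
   ("but", "however", ...) in between. Window, cues and reset tokens are
   configurable.
7. **Dictionary curation.** `add_to_lexicon` adds terms at runtime;
   duplicate canonical forms are conflicts. Abbreviations match only if
   explicitly listed as synonyms.
8. **Similarity linking.** Tokens not covered by a pattern match, at least
   4 characters long and not in the dictionary vocabulary are embedded and
   linked to the dictionary entry with maximal cosine similarity, if that
   maximum reaches the threshold (default 0.85). Pattern matches always
   take precedence on a span.
9. **Emission.** Entities carry sentence index, 0-based half-open token
   span, polarity, link method and similarity; output is ordered by
   (sentence, span start) and bit-for-bit deterministic.

**Embedding.** The default embedder hashes character trigrams of the
normalized phrase into 256 buckets (BLAKE2-based hashing, independent of
`PYTHONHASHSEED`) and L2-normalizes the count vector. Morphological
variants share most trigrams ("angiokeratomata" vs "angiokeratoma" scores
~0.92) while unrelated words score near zero. The provider is a small
duck-typed interface, so pretrained word vectors can be substituted without
touching the matcher. The 0.85 threshold was chosen so that inflectional
variants of dictionary terms link while cross-term similarities (measured
at < 0.5 for all pairs in the shipped lexicon) stay well below it.

## Feature catalog and scoring

The 13 features span five sign groups — cardiovascular (hypertrophic
cardiomyopathy, myocardial infarction, arrhythmia/conduction abnormality),
kidney (renal failure, proteinuria), skin (angiokeratoma,
hypohidrosis/heat-cold intolerance), neurological (stroke/TIA, neuropathic
pain/acroparesthesia, hearing impairment, gastrointestinal symptoms,
recurrent fever) and eye (cornea verticillata/eye fundus lesions). The
shipped catalog is a **reconstructed default**: the original scoring
table is not public, so membership, base scores (0–3) and age modifiers
here encode the published principles — highly FD-specific findings
(angiokeratoma, acroparesthesia) score 3, findings common in the general
population score 1, and features typical of the elderly (stroke, MI, renal
failure, hearing loss, eye fundus lesions) gain +1 (capped at 3) when they
manifest below age 55. Membership and scores are YAML configuration, not
code. A present feature scores 0 when absent or vetoed, so the risk factor
is exactly the sum of feature scores, bounded by 39.

**Evidence channels.** A feature is present if at least one affirmed text
mention, ICD-10 code (matched by string prefix, e.g. `I63` covers
`I63.x`), or lab finding (eGFR < 60 mL/min/1.73 m², urine protein >
150 mg/24 h) supports it. `expand_icd10` provides full code descriptions
(longest-prefix fallback) for human-readable evidence strings; evidence
matching itself uses code prefixes, which is equivalent for the bundled
table and keeps entity-level provenance exact. Negated mentions never
count as evidence anywhere.

**Vetoes.** A present feature is vetoed when a confirmed alternative cause
is documented in the same record: renal failure by nephropathies,
amyloidosis, sarcoidosis, Alport syndrome, nephrectomy, urolithiasis or
congenital renal defects; stroke by patent foramen ovale or trauma.
"Confirmed" means any affirmed mention or matching ICD-10 code — no
certainty grading. Vetoing is idempotent and removing the confounder
restores the feature.

**Cohort filters.** Inclusion: age 18–75 (inclusive). Exclusion:
palliative care, alcohol dependency, disseminated cancer, blood cancer,
chemotherapy — evidenced the same way as vetoes. The reported reason is
the first triggered criterion (age first, then catalog order).

## Screening evaluation

Predicted positive means risk factor >= cut-off (default 4). The
confusion matrix yields accuracy (TP+TN)/N, precision TP/(TP+FP), recall
TP/(TP+FN), specificity TN/(TN+FP) and F1 = 2PR/(P+R); zero-denominator
metrics are NaN and flagged rather than raised. The cut-off sweep (default
3–11) reports counts and rates per integer cut-off; sensitivity is
non-increasing and specificity non-decreasing by construction. ROC curves
use every distinct score threshold with trapezoidal area (equal to the
normalized Mann–Whitney U statistic); the precision–recall area uses the
step-wise precision-at-recall convention (sum over thresholds of
ΔR·P). Enrichment of the flagged group is k = round(FP/TP) (one case per
k flagged controls) and fold = N/k against a 1-in-N population prevalence.
Group comparisons use the two-sided Mann–Whitney test for numeric
attributes, chi-squared for binary traits when all expected counts are
>= 5 and Fisher's exact test otherwise; a trait with zero incidence in a
group is reported untested.

## Synthetic cohorts

The generator emulates the study conditions at desk scale: 5 cases vs
7,450 controls (~1:1,490 imbalance), case ages N(45.2, 10.5) and control
ages N(55.5, 13.3) clipped to 18–75, 38.5%/50.5% female. Features are
drawn per patient as independent Bernoullis (catalog order) from
per-group probability tables; each planted feature is realized through
one channel — a templated text mention (70% weight), an ICD-10 code, or a
structured lab value — with mention-level noise: negation (rate 0.10),
single-character typos (0.05) and morphological paraphrases (0.05).
Kidney/stroke features are accompanied by a vetoing confounder mention at
rate 0.15. Gold annotations record every planted mention (term, sentence,
token span, polarity), the intended post-veto feature set and the
catalog-consistent intended risk factor.

Two calibration notes. First, the control probability table concentrates
group mass on common score-1 features (arrhythmia, GI symptoms): with
independent features, spreading the published sign-group frequencies
(~34% cardiovascular, ~26% neurological, ~10% kidney) evenly across
features produces a control score tail far heavier than a real hospital
population's risk-factor distribution, so the table prioritizes the
score distribution (control mean ~0.7, >98% of controls in 0–3) and
accepts cardio/neuro marginals near 25% and kidney near 5%. Second,
cases carry at least `min_case_features = 3` documented features: the
study group of a screening validation exists *because* those patients'
records documented the phenotype, so a "diagnosed case" with an empty
chart would be an ascertainment artifact. This is a feature-count rule,
independent of scores.

The audit corpus generator produces, per dictionary term, annotated
descriptions containing exactly one target mention (negated at rate 0.15,
typo'd at 0.08) plus distractor sentences and, at rate 0.10, a near-miss
distractor — a morphological neighbor of a *different* single-token term,
absent from the gold — so an over-linking extractor pays in precision.

**What the generator does not model:** real clinical prose (templates and
a fixed distractor pool instead), Polish morphology, comorbidity
correlations between features, longitudinal timelines, section structure,
abbreviation-heavy shorthand, and genuinely ambiguous mentions. Passing
tests therefore demonstrate the internal coherence of the pipeline
(exact recovery in the no-noise limit, robustness to the modeled noise),
not performance on real hospital text.

## Numerical and determinism choices

- All randomness flows from a single `numpy` `default_rng` seeded from the
  spec; the per-patient draw order is fixed and documented in the module
  docstring, so a seed determines the output byte-for-byte.
- Token spans are 0-based half-open; sentence and note indices 0-based.
- Typo correction candidates are tried in dictionary insertion order
  (deterministic first match); score ties in ranking preserve input order
  (stable sort).
- `round()` (banker's rounding) is used for the enrichment ratio k.
- Degenerate inputs: empty notes yield no entities; empty lexicons yield
  no links (not an error); single-class cohorts raise on curve
  computation; zero-denominator rates are NaN with an `undefined` flag.

## Default problem sizes

The default test and acceptance workloads are desk-scale by design: the
audit corpus is 100 descriptions per term (3,600 documents for the
36-term lexicon), the separated-cohort check runs the full default
5 + 7,450 cohort, oracle-equivalence checks use 100 random cohorts of up
to 40 patients, and the no-noise recovery check uses 5 + 400 patients.

## Known limitations

- The feature catalog is a reconstruction; absolute risk-factor values are
  not comparable to the original scoring system, only the mechanics are.
- Similarity linking operates on single tokens; multi-token paraphrases of
  multi-token terms ("whorl-like corneal deposits") are not linked.
- The minimum per-term audit precision depends on how many near-miss
  distractors land on a term; it is reported, not guaranteed, and a
  handful of percentage points above the 70% floor under default noise.
- No confidence intervals on AUC, no calibration of the score, no learned
  weights — the factor model is deliberately fully explainable.
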