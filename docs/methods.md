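# Methods

This note documents the models and procedures implemented in `phenotyper`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data experiments do and do not demonstrate.

## Problem setting

Emergency-department (ED) visits by patients with opioid-related diagnoses
are heterogeneous: chronic opioid use with heavy comorbidity burden, acute
intoxication and overdose, psychiatric crises, and pain-driven presentations
all arrive under the same diagnostic umbrella. The pipeline derives
*computational phenotypes* — data-driven visit subgroups — from a combination
of clinical note content and structured EHR fields, then profiles each
subgroup's downstream outcomes (survival, comorbidity, ED returns, medication
prescriptions) to show the subgroups differ in clinically meaningful ways.

The pipeline has six analysis stages. Each communicates with the next only
through files, so any stage's input can be replaced with output from an
external tool.

## 1. Concept extraction

Notes are reduced to clinical concept mentions using a lexicon of surface
forms mapped to concept identifiers (CUIs) and UMLS-style semantic types.
Matching is deterministic: text and lexicon entries are normalized
(lowercase, punctuation stripped to spaces, whitespace collapsed) and scanned
left-to-right with greedy longest match at token boundaries; matches never
overlap. Mentions are then filtered by a configurable semantic-type
allow-list (disorders, findings, procedures, chemicals/drugs, anatomy by
default); all other note text is discarded.

A production deployment would use a statistical annotator (MedCAT or
similar) with disambiguation and spelling correction. The dictionary matcher
is not an approximation of that model's accuracy — it is the package's
deliberate choice of a reproducible extractor whose output format
(mentions JSONL) is the integration point where real annotator output can be
substituted. Consequences: no negation handling, no sense disambiguation,
and recall limited to lexicon coverage. Ties between equal-length candidates
cannot arise (normalized surface forms are unique by construction; loading
rejects collisions).

## 2. Corpus construction

Per encounter, concept tokens from all of its notes are pooled (multiset
union) with structured-data tokens:

* one token per diagnosis-group and medication-class name present;
* per lab measurement, the plain lab-name token, plus a single combined
  token `high <name>` / `low <name>` when the value lies strictly beyond
  two standard deviations of the **background cohort's** mean for that lab.
  Lab references use the sample SD (ddof = 1); a lab observed once gets
  SD 0 and can never earn a modifier.

Vocabulary selection is cohort-contrastive, using a matched background ED
cohort as the reference:

1. **Ubiquity filter.** A token is removed when its *document frequency*
   (fraction of encounters containing it at least once) strictly exceeds 5%
   in **both** cohorts. This targets template boilerplate and care-process
   jargon that appears everywhere regardless of clinical content. Document
   frequency, not raw token share, is used because ubiquity across notes is
   what makes a token uninformative; the boundary is strict (exactly 5%
   survives).
2. **Chi-square keep-word test.** For each surviving token, a 2×2 table of
   cohort × document-level presence is tested with Pearson's chi-square
   (1 df, no continuity correction); tokens with p < 0.05 are kept. No
   multiple-testing correction is applied — the filter is a vocabulary
   screen, not an inference procedure, and raw p < 0.05 is the intended
   operating point. Degenerate tables (a token in no or in every document of
   both cohorts) are skipped with a warning.

Term frequencies count repeated mentions within a note (the corpus is a
term-frequency corpus); the two filters above use presence only. Encounters
whose bag is empty after filtering are retained with an empty row and
flagged, so every encounter still receives an embedding (it falls back to
the uniform topic prior). The vocabulary index is sorted lexicographically
for reproducibility.

## 3. Topic model

LDA is fitted by collapsed Gibbs sampling — a from-scratch implementation of
the standard collapsed conditional

    p(z_t = k | rest) ∝ (n_dk + α) · (n_kw + β) / (n_k + Vβ)

with a numba-compiled inner loop (single chain; the RNG is seeded inside the
kernel, so a fixed seed reproduces the chain bit-for-bit). Defaults:
1000 sweeps, symmetric α = 50/K, β = 0.01 — the Mallet-style conventions.
By default φ and θ are the posterior means computed from the final sweep's
counts (deterministic given the seed); averaging over post-burn-in sweeps
(burn-in 200) is available via `average_samples=True`. Hyperparameter
optimization during sampling is not implemented. Empty documents receive the
uniform θ row automatically from the estimator.

Each encounter's **embedding** is its θ row: the proportion of each topic
within the encounter's notes. Embeddings live on the (K−1)-simplex; rows sum
to 1 by construction.

**Topic-count selection.** Topic quality is scored by UMass coherence: for a
topic's top-m words (m = 10) ranked by φ, the sum over ordered pairs
(w_i, w_j), i < j, of log[(D(w_i, w_j) + 1) / D(w_j)], with D the document
(co-)occurrence counts in the training corpus. UMass was chosen because it
is intrinsic — no external reference corpus is needed. "Coherence plateau"
is made operational as: the chosen K is the smallest grid value whose mean
coherence is within ε (default 0.05) of the grid maximum, measured as a
fraction of the coherence range over the grid. Ties therefore resolve to the
most parsimonious model.

*Known limitation.* When the data contain a weak topic shared across all
subgroups, UMass coherence can peak at a *smaller* K than planted: the weak
topic's top words rarely co-occur, so models that resolve it score worse
than models that absorb it. On such corpora the plateau rule under-selects
K, which in turn can merge clusters downstream. The planted-topic selection
experiment uses equally strong topics, where the rule recovers K* reliably;
the end-to-end recovery experiment therefore fixes K at the planted value,
mirroring the practice of fixing K from a separate coherence analysis before
the clustering stage.

## 4. Clustering

K-means (k-means++ seeding, best of n_init = 10 restarts by inertia,
tol = 1e-6, max 300 Lloyd iterations; scikit-learn backend) on the raw
simplex embeddings with Euclidean distance — the simplest defensible
geometry; compositional alternatives (Aitchison, Hellinger) can be applied
by transforming the embedding before clustering. Quality metrics:

* **Silhouette** s = (b − a)/max(a, b), with a the mean intra-cluster
  distance (excluding self) and b the smallest mean distance to another
  cluster. Conventions: singleton clusters and 0/0 (coincident points)
  score 0.
* **Dunn index**: minimum inter-cluster point distance divided by maximum
  intra-cluster diameter; undefined (error) when both are zero.

The cluster count maximizes mean silhouette over the grid, ties broken by
higher Dunn, then smaller k. The grid and the tie hierarchy are
configuration, not statistics: silhouette leads because it is the only one
of the metrics with a per-point decomposition that supports inspection.

## 5. Outcome profiling

Per discovered cluster:

* **Survival**: Kaplan-Meier product-limit estimator from days since the
  index ED discharge, death flag = 1, administrative censoring otherwise
  (lifelines backend); S(365) reported, full step curve retained. Pairwise
  cluster separation is tested with the log-rank test.
* **Charlson comorbidity index**: Quan (2005) ICD-10 coding algorithm with
  the original Charlson weights, shipped as an editable CSV
  (`data/charlson_icd10.csv`). Codes match by longest prefix after dot
  removal; each category counts once; severity hierarchies apply
  (metastatic tumor ⊃ other malignancy, severe ⊃ mild liver disease,
  complicated ⊃ uncomplicated diabetes). Median and mean are both reported.
* **ED returns**: fraction of encounters with ≥ 1 qualifying return within
  (0, w] days of discharge, w ∈ {183, 365} (6 and 12 months, inclusive
  right boundary). Opioid-related returns use a separate date list, defined
  upstream by configurable code-list matching on return-visit diagnoses.
* **Medication rates**: per-encounter fraction with buprenorphine,
  methadone, naloxone outpatient prescriptions.
* **Relative risk** of each structured variable in cluster c:
  RR = (a/n_c) / ((A − a)/(N − n_c)) — within-cluster rate over the rate in
  all remaining encounters. A − a = 0 with a > 0 returns +∞.
* **Rate flags**: each cluster rate is compared against the pooled remaining
  population with the same uncorrected Pearson chi-square used for
  keep-words; flags are increased / decreased / neutral at α = 0.05.

Cohort summary tables report n, median [Q1, Q3] age, and counts with
percentages to one decimal for each categorical level and binary variable,
per cluster and overall.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, with
planted ground truth for every stage:

* **Cohorts.** An opioid cohort and a background ED cohort; background
  demographics are resampled jointly (age, sex, race) from the opioid
  cohort's empirical distribution, emulating matched sampling.
* **Notes.** Per opioid encounter: cluster c ~ Categorical, θ ~
  Dirichlet(κ · profile_c) (κ = `dirichlet_alpha_true`, default 25 — the
  total concentration; the mean is the cluster's topic profile), document
  length ~ negative binomial (mean 100, dispersion 10; note lengths vary
  widely in practice), tokens drawn topic-then-word. Background encounters
  draw from a single background word distribution.
* **Vocabulary layout.** Common words carry 12% of every distribution's
  mass (removed by the ubiquity filter), neutral words 6% in both cohorts
  (rejected by the chi-square test), and each topic concentrates 80% on its
  own word block. Default cluster profiles give each cluster one dominant
  topic (80%) with the rest spread over all topics, keeping every planted
  topic identifiable and pairwise profile separation at TV = 0.8.
* **Structured data.** Lab values are cohort-specific normals (background
  mean/SD plus an additive opioid shift); ICD-10 codes from a configurable
  pool with cluster-conditional prevalences (including Charlson-mapped codes
  so comorbidity burden differs by cluster).
* **Outcomes.** Death times are exponential with cluster-specific daily
  hazards (defaults span one-year survival ≈ 0.85–0.96), administratively
  censored at 730 days; 6/12-month return indicators and medication flags
  are cluster-conditional Bernoulli draws (12-month all-cause returns
  0.09–0.34, opioid returns 0.08–0.17, methadone 0.17–0.43, matching
  realistic ED ranges). Returns are drawn marginally — they are not censored
  at death, so empirical return rates estimate the planted probabilities
  exactly.
* **Rendered text** (optional) interleaves lexicon surface forms with filler
  words for exercising the extractor; token-level notes bypass extraction
  for pure topic-model experiments.

What passing tests on these data show: the sampler, filters, estimators and
selection rules recover planted structure at realistic sizes, and the
pipeline is deterministic end to end. What they do not show: performance on
real clinical language (no negation, misspellings, or sense ambiguity), on
topics without block structure, or on outcome processes with informative
censoring or competing risks.

## Numerical and design choices

* Strict inequalities at the 5% document-frequency boundary and at the
  ±2 SD lab boundary; values exactly at a boundary take no action.
* Chi-square without Yates correction everywhere, so keep-word statistics
  and rate flags are mutually consistent and match the textbook
  Σ(O−E)²/E form to 1e-10 (asserted against an independent oracle).
* Top-word ranking breaks φ ties lexicographically; the vocabulary index is
  sorted; k-means uses a fixed seed policy — all outputs are reproducible
  bit-for-bit given (config, seed).
* Problem sizes in the test and acceptance experiments (500 docs × ~100
  tokens for topic recovery, 2000 encounters for cluster recovery, 8000 for
  survival calibration, 1000 + 1000 for the end-to-end run) were chosen as
  the smallest scales at which the binomial/TV tolerances of the recovery
  claims are informative.
* Seeds are small integers; all derived seeds stay below 2³¹.

## Known limitations

* The dictionary extractor's recall is bounded by lexicon coverage; the
  packaged lexicon is a demonstration vocabulary, not a clinical resource.
* UMass-plateau topic selection can under-select K in the presence of weak
  shared topics (see above).
* Medication rates are per-encounter; a per-patient reading requires
  deduplicating encounters upstream.
* The Charlson table covers the Quan ICD-10 mapping only; ICD-9 codes score
  zero.
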