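# phenotyper

Computational phenotyping of opioid-related emergency-department (ED)
presentations from electronic health record (EHR) data.

ED visits by patients with opioid-related diagnoses span acute overdose,
chronic use with heavy comorbidity burden, psychiatric crises, and
pain-driven presentations. `phenotyper` derives *computational phenotypes* —
data-driven visit subgroups — by combining clinical note content with
structured EHR fields, and then profiles each subgroup's outcomes to show
the subgroups differ in clinically meaningful ways. It is aimed at clinical
informatics and epidemiology groups who want a tested, reproducible
implementation of this workflow, together with a synthetic EHR generator
that makes every stage verifiable without access to protected health data.

## Method

Given an opioid cohort and a demographically matched background ED cohort:

1. **Concept extraction** — notes are mapped to clinical concept identifiers
   (CUIs) by deterministic longest-match dictionary lookup and filtered by
   UMLS-style semantic type. Output from a full NLP annotator (e.g. MedCAT)
   can be substituted at this boundary via the same mentions format.
2. **Corpus construction** — concept tokens are pooled per encounter with
   structured-data tokens (diagnosis groups, medication classes, lab names
   with `high`/`low` modifiers beyond ±2 background SD). Tokens in > 5% of
   documents in *both* cohorts are removed; among the rest, *keep words*
   are those whose document-level presence differs between cohorts by
   Pearson chi-square (1 df, no continuity correction, p < 0.05).
3. **Topic modeling** — LDA over the keep-word term-frequency corpus, fitted
   by collapsed Gibbs sampling: p(z=k | rest) ∝ (n_dk+α)(n_kw+β)/(n_k+Vβ),
   with α = 50/K, β = 0.01. The topic count K is chosen at the UMass
   coherence plateau. Each encounter is embedded as its topic-proportion
   vector θ on the (K−1)-simplex (entries sum to 1).
4. **Clustering** — K-means on the embeddings; cluster count chosen by mean
   silhouette with Dunn-index tie-breaks.
5. **Outcomes** — per cluster: Kaplan-Meier survival S(t) = Π(1 − d_i/n_i)
   after discharge, Charlson comorbidity index (Quan ICD-10 mapping),
   6/12-month all-cause and opioid-related ED return rates,
   buprenorphine/methadone/naloxone prescription rates, chi-square
   increased/decreased flags vs the remaining population, and relative
   risks RR = (a/n_c) / ((A−a)/(N−n_c)) for structured variables.

The synthetic generator plants topics, clusters and cluster-conditional
outcome rates with a full truth manifest, so recovery of every quantity is
testable. See `docs/methods.md` for models, defaults and limitations.

## Worked example

Run the full pipeline on a small synthetic dataset (4 planted clusters over
5 planted topics, 300 opioid + 300 background encounters):

```python
from phenotyper.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    outdir="demo", seed=5,
    simulate={"n_opioid_encounters": 300, "n_background_encounters": 300,
              "doc_length_mean": 60.0},
    topics={"k": 5, "n_iterations": 200},
    cluster={"k_grid": [2, 3, 4, 5, 6]},
)
run_pipeline(cfg)
```

Every stage artifact lands under `demo/` with a manifest of parameters and
checksums. The cluster-count search (`demo/clusters/metrics.csv`) selects
k = 4 — the planted number — by mean silhouette:

```
 k  mean_silhouette  dunn  inertia
 2            0.424 0.264   21.410
 3            0.612 0.264   11.339
 4            0.791 0.555    2.076
 5            0.699 0.086    1.705
 6            0.583 0.048    1.442
```

and the per-cluster outcome report (`demo/report/per_cluster.csv`) separates
the planted outcome profiles — e.g. a low-survival, higher-comorbidity
cluster (row 0) against a high-survival cluster with frequent ED returns
(row 1):

```
      n  survival_365d  cci_median  all_cause_365d  methadone  naloxone
0  65.0          0.831         2.0           0.077      0.154     0.215
1  89.0          0.978         0.0           0.348      0.270     0.124
2  83.0          0.880         0.0           0.313      0.373     0.145
3  63.0          0.984         0.0           0.190      0.206     0.016
```

Comparing the discovered labels against the truth manifest
(`demo/dataset/truth.json`) gives an adjusted Rand index of 1.0: the
pipeline recovers the planted cluster structure exactly at this separation.

The same stages are available from the shell: `phenotyper simulate`,
`phenotyper extract`, and `phenotyper run --config pipeline.yaml`.

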