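# cytorisk

Unsupervised risk stratification of single-cell cytometry cohorts.

`cytorisk` is for researchers with a pilot cohort of patient samples
profiled by mass or flow cytometry (tens of patients, thousands of cells
each, ~10-40 protein markers) and censored clinical outcomes (overall or
progression-free survival). It answers, without any supervision or prior
cell-type annotation: *are there cell populations whose abundance in a
patient's sample stratifies that patient's risk?* — and then validates the
answer statistically and distills it into a two-marker gate usable on
simpler platforms.

## Method

One run executes:

1. **Equal subsampling** — every patient contributes the same number of
   cells to the pooled analysis, so no sample dominates.
2. **Embedding** — t-SNE, UMAP, or none (cluster directly on marker
   space); the workflow is modular in the dimensionality-reduction tool.
3. **SOM metaclustering** — a self-organizing map is trained on the
   pooled cells and its codebook is merged into k populations by
   hierarchical clustering. k is chosen automatically: for each marker f,
   the smallest k whose size-weighted within-cluster variance
   V(f,k) = Σ_c (n_c/N)·var_c(f) has reached (nearly) its minimum over the
   searched range; the cohort k is the median over markers.
4. **Outcome-guided testing** — for each cluster, per-patient abundance
   a_p (percent of the patient's cells) is split at the cut point
   IQR = Q3 − Q1 of {a_p}; a univariate Cox proportional-hazards model
   h(t) = h₀(t)·e^{β·1[high]} compares high vs low. Clusters with p < 0.05
   and HR = e^β > 1 are negative-prognostic; HR < 1, positive-prognostic.
   A multivariate model h(t) = h₀(t)·e^{β_ab·a + β_age·Age + …} tests
   whether the abundance effect is continuous and independent of clinical
   covariates, with Schoenfeld-residual diagnostics.
5. **Marker enrichment labels** — each population is described against
   the remaining cells on a signed −10…+10 scale,
   raw = |Med_c − Med_ref| + IQR_ref/IQR_c − 1 (signed, run-max scaled).
6. **Validation** — repeated re-clustering scores each cluster's
   stability by the best-match F-measure (F = 2PR/(P+R); mean F ≤ 0.5 is
   unstable), and repeated cell subsampling re-runs the whole pipeline to
   ask which prognostic *phenotypes* (MEM labels, compared by RMSD
   similarity) recur in ≥ 50% of runs.
7. **Gate distillation** — the most discriminating marker pair between the
   pooled negative- and positive-prognostic cells defines two rectangular
   gates; patients are re-stratified by gated-cell fractions.

See `docs/methods.md` for assumptions, numerical conventions and
limitations.

## Worked example

Everything below runs on a synthetic cohort with two planted prognostic
populations (the generator is part of the package), so it is fully
reproducible:

```python
import cytorisk as ck

# 28 patients x 300 cells x 10 markers; cluster 0 is planted as
# negative-prognostic (+0.07 log-HR per percent), cluster 1 as positive
tables, cohort, truth = ck.make_fixture(
    "planted_gnp_gpp", seed=7, cells_per_patient=300, n_markers=10
)

cfg = ck.RunConfig(embedding_method="none", k_range=(4, 12), seed=7)
res = ck.RiskStratification(tables, cohort, config=cfg).fit()
print(res.summary())
```

```
Cytometry risk stratification results
========================================================================
Patients: 28    Pooled cells: 8400    Markers: 10
Embedding: none    Endpoint: OS    alpha: 0.05
Cluster number search: k in [4, 12] -> k_opt = 8
Prognostic clusters: 2 (negative: [1], positive: [3])
------------------------------------------------------------------------
          cut      HR  ci_low ci_high       p direction  n_high  n_low
cluster
1        27.1    5.73    2.21    14.9  0.0003  negative      13     15
2           0       -       -       -       -        NS       0     28
3        38.7  0.0654  0.0172   0.248  0.0000  positive      10     18
4           0       -       -       -       -        NS       0     28
5           8    1.45   0.575    3.64  0.4327        NS       7     21
6        16.6     1.7   0.717    4.03  0.2277        NS       8     20
7        6     0.799   0.316    2.02  0.6360        NS        7     21
8        18.9    1.67   0.709    3.94  0.2399        NS       8     20
```

Reading: the search settled on 8 populations (two of which collected no
cells and are reported NS with degenerate cuts). Cluster 1's abundance
above its IQR cut point of 27.1% carries a hazard ratio of 5.73
(p = 0.0003) for death — high-abundance patients die sooner — while
cluster 3 is protective (HR 0.065). Both match the planted truth.
Continuing:

```python
res.compute_stability(n_runs=20)      # mean F per cluster vs 19 re-clusterings
gate = res.derive_gate()              # -> marker_01 (NP) / marker_02 (PP)
fr   = ck.gate_fractions(res.pooled, gate)
strat = ck.stratify_by_gate(fr, cohort)
print(gate.marker_np, gate.marker_pp, round(strat["HR"], 2))
# marker_01 marker_02 14.69
```

The two-marker gate recovers the planted signature (marker_01⁺/marker_02⁻
cells behave like the negative-prognostic population) and separates the
NP-high from PP-high patients (HR 14.7, p < 0.001).

The same workflow is available from the shell:

```bash
cytorisk simulate --fixture planted_gnp_gpp --out-dir data/
cytorisk run --data-dir data/ --out-dir results/ --seed 38
cytorisk stability --data-dir data/ --out-dir results/ --n-subsamples 10
cytorisk gate --data-dir data/ --out-dir results/
```

`run` writes the abundance table, survival statistics, cluster-number
search curves, MEM labels, per-patient categories, annotated per-cell
events (CSV or FCS) and the plot bundle (embedding maps, Kaplan-Meier
curves, MEM heatmap).

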