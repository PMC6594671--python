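# dietsurv

Pathway expression scoring, survival stratification and diet-normalization
analysis for tumor transcriptomes.

Tumors characteristically run high glycolysis and low fatty-acid
β-oxidation (FAO) — the Warburg effect, with the two programs mutually
inhibitory through the Randle cycle. Two questions follow for anyone
with an expression matrix and clinical follow-up. In patient cohorts: do
tumors with a high FAO / low glycolysis transcriptional balance carry a
survival advantage? And in dietary-intervention designs: which
tumor-dysregulated transcripts does a high-fat diet normalize back
toward the healthy-tissue baseline? `dietsurv` packages the full
transcript-level toolchain for both questions, plus synthetic-cohort
generators with planted effects so every stage is testable without any
external download.

## What it computes

- **Pathway scores** — per sample, the mean of incremented
  log2-transformed expression (`log2(x+1)`) over a gene panel: an FAO
  score, a glycolysis score, or any panel from a GMT file.
- **Stratification** — high/low split at the cohort median score
  (ties to low), concurrent two-pathway quadrants
  (`FAO_high_gly_low` vs `FAO_low_gly_high`), and k-means cluster
  strata on a t-SNE embedding.
- **Survival** — Kaplan–Meier product-limit curves
  `S(t) = Π (1 − dᵢ/nᵢ)`, median survival, and the Mantel–Cox log-rank
  test (omnibus, pairwise, and a small-sample permutation variant),
  implemented from the formulas and cross-checked against independent
  references in the tests. Time is `max(days_to_death,
  days_to_last_followup)`, censored when no death day is recorded.
- **Differential expression & rescue calls** — Welch t-tests on the
  log2 scale with Benjamini–Hochberg q-values and a fold-change gate;
  directional overlap of significant sets; and per-gene
  rescue indices `r = (HFD_tumor − NFD_tumor)/(liver − NFD_tumor)`
  classifying each diet's effect as unrescued / partial / complete /
  overshoot, with a `normalized_by_both` call.
- **Embedding & importance** — deterministic t-SNE of panel
  expression, cluster-wise survival comparison, and random-forest
  permutation importance ranking the transcripts most determinant of
  the cluster patterns.

## Worked example

Simulate a 400-patient cohort in which the glycolysis program raises
the death hazard and FAO lowers it (log-hazard coefficients ±0.7),
score and stratify it, and compare quadrant survival:

```python
import dietsurv as ds

spec = ds.CohortSimSpec(n_samples=400, beta_gly=0.7, beta_fao=-0.7, seed=1)
matrix, records, truth = ds.simulate_cohort(spec)
scores = ds.pathway_score(matrix, ds.cohort_gene_sets(spec))
quad = ds.quadrant_groups(scores)
surv = ds.derive_survival_table(records)

groups, names = [], ["FAO_high_gly_low", "FAO_low_gly_high"]
for name in names:
    ids = quad.labels.index[quad.labels == name]
    t, e = surv.loc[ids, "time"], surv.loc[ids, "event"]
    med = ds.median_survival(ds.km_estimate(t, e))
    print(f"{name}: n={len(ids)}, median survival {med:.0f} days")
    groups.append((t.to_numpy(), e.to_numpy()))
res = ds.logrank(groups, names)
print(f"log-rank chi2={res.statistic:.1f}, df={res.df}, p={res.p_value:.2e}")
```

prints

```
FAO_high_gly_low: n=91, median survival 2089 days
FAO_low_gly_high: n=91, median survival 265 days
log-rank chi2=67.1, df=1, p=2.61e-16
```

Each quadrant holds roughly a quarter of the cohort (91/400); the
favorable FAO-high/glycolysis-low quadrant's median survival is about
eightfold that of the mirror group, and the log-rank test rejects
equality decisively — the planted hazard structure, recovered from
expression alone.

The same stages are available from the shell via the `dietsurv` CLI
(`simulate-cohort`, `simulate-mouse`, `score`, `stratify`, `survival`,
`de`, `normalize-calls`, `embed`, `importance`) and as two composite
workflows (`run-cohort`, `run-mouse`) that write every stage output
plus a JSON manifest with config, input digests and seed for exact
reruns.

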