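# mibc-subtyper

Molecular subtyping, survival stratification and drug-target screening for
muscle-invasive bladder cancer (MIBC) expression panels.

MIBC splits into transcriptomic subtypes analogous to breast cancer
subclasses — **luminal** (KRT20, UPK2, PPARG, FGFR3, CD24), **basal**
(KRT5, KRT14, CD44) and **p53-like/"infiltrated"** (immune and stromal
genes: FAS, NCAM1, CCL2, CD14) — with markedly different prognosis and
drug-target expression.  This package implements the full analysis chain
needed to call those subtypes from a targeted NanoString nCounter panel or
from log2 microarray intensities, and to quantify their clinical impact:

- **Normalization** — the nCounter chain (positive-control scaling →
  negative-control background subtraction → housekeeping scaling on the
  geometric mean of 6 reference genes → log2), and classic quantile
  normalization for arrays.
- **Consensus panel** — per-cohort hierarchical gene clustering (distance
  `1 − r` with Pearson `r` across samples, Ward agglomeration, tree cut at
  k = 3), semi-supervised cluster labeling by seed-marker overlap
  (exhaustive 3!-optimal assignment), and a cross-cohort Venn intersection
  keeping only genes labeled identically in every cohort.
- **Subtype calls** — unsupervised sample clustering on the z-scored
  consensus panel (same distance/linkage), clusters named by their mean
  signature z-scores; Pearson nearest-centroid prediction for new cohorts.
- **Survival** — Kaplan–Meier product-limit curves, the k-sample log-rank
  test, and Cox proportional-hazards regression (Efron ties) with forward
  selection, on the luminal vs non-luminal dichotomization and the usual
  clinical covariates (pT3–4 vs lower, N+, M+, chemotherapy, sex, age).
- **Group tests** — the Freeman–Halton exact Fisher test for r×c tables
  (probability-ordered enumeration in log space, Monte Carlo fallback) and
  the tie-corrected Kruskal–Wallis test, including a clustering-independent
  drug-target screen (ERBB2, FGFR1/2/4, PDGFRB, AR, ESR1/2, PGR, claudins).
- **GSEA** — a minimal weighted-KS enrichment score with phenotype
  permutations (NES, add-one nominal p, single-set FDR).
- **Synthetic cohorts** — a negative-binomial/exponential generator that
  plants the whole structure above (3 subtypes, 64-gene panel with 36
  cross-cohort-stable genes, spike-in ladder, drug-target shifts, immune
  infiltration, subtype-dependent survival), so every stage is testable
  without patient-level data.

## Worked example

```python
from mibc_subtyper import (SimulationConfig, generate_cohort, normalize_ncounter,
                           call_subtypes, cox_fit, stratify_luminal, ConsensusPanel)
from mibc_subtyper.synthetic_cohort import default_panel, truth_consensus_sets
from mibc_subtyper.survival_stats import km_by_group

cohort = generate_cohort(SimulationConfig(n_samples=47, seed=7))
log2_expr, report = normalize_ncounter(cohort.expression)
consensus = ConsensusPanel.from_labels(truth_consensus_sets(cohort.panel))
calls = call_subtypes(log2_expr, consensus)
print("subtype counts:", calls.counts())

df = cohort.clinical.data.set_index("sample_id")
curves = km_by_group(df["dss_time"].astype(float),
                     df["dss_event"].astype(bool),
                     calls.subtypes.reindex(df.index))
for name, curve in sorted(curves.items()):
    print(f"8-year DSS, {name}: {curve.survival_at(96):.2f}")

result = cox_fit(cohort.clinical, ["luminal", "stage", "node", "ac"],
                 endpoint="DSS", selection="forward",
                 luminal=stratify_luminal(calls))
row = result.summary.loc["luminal"]
print(f"luminal HR = {row['hr']:.2f} "
      f"(95% CI {row['ci_lower']:.2f}-{row['ci_upper']:.2f}, p = {row['p']:.3f})")
```

Output:

```
subtype counts: {'luminal': 8, 'basal': 14, 'infiltrated': 25}
8-year DSS, basal: 0.65
8-year DSS, infiltrated: 0.93
8-year DSS, luminal: 0.14
luminal HR = 6.73 (95% CI 2.27-19.93, p = 0.001)
```

A 47-patient nCounter-style cohort is simulated, normalized and clustered
into the three subtypes on the 36-gene consensus panel.  The luminal
subtype shows the worst disease-specific survival, and forward selection
keeps only the luminal-vs-non-luminal indicator in the Cox model — a
roughly five-fold disease-specific death hazard (here 6.73 with a wide CI
at n = 47, as expected at this cohort size).

The same workflow is available from the shell:

```sh
mibc-subtyper simulate --seed 7 --out demo/
mibc-subtyper normalize --platform ncounter --in demo/expression.tsv --out demo/norm.tsv
mibc-subtyper run --out demo_full/          # full 4-cohort end-to-end run
```

## Layout

```
src/mibc_subtyper/    io_formats, synthetic_cohort, normalization,
                      consensus_panel, subtype_caller, survival_stats,
                      group_tests, gsea_lite, pipeline, cli
tests/                pytest suite (unit, property and acceptance tests)
docs/methods.md       modeling and statistical notes
```
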