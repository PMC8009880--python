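# neostrat

Agnostic stratification of neonatal nutritional practice from routine daily
feeding records, with a reproducibility protocol and deconfounded
nutrition–outcome association analysis.

Very preterm infants (gestational age < 32 weeks) receive six daily binary
nutrition components — maternal milk (MM), human donor milk (HDM),
breast-milk fortifier (BMF), formula milk (FM), parenteral nutrition (PN)
and glucose-electrolyte solution (GE). Over a median ~49-day stay the space
of possible per-component day-count combinations is astronomically large
(49⁶ ≈ 13.8 billion), yet actual practice concentrates in a modest number of
recurring patterns. `neostrat` discovers those patterns without supervision,
checks that the discovered stratification is reproducible, groups clusters
by admission profile, and estimates the association of belonging to one
nutritional cluster versus another with clinical outcomes. It is aimed at
biostatisticians and clinical-informatics researchers working with
registry-style episodic + daily neonatal tables.

## The model

Each infant is encoded as a vector `x ∈ [0,1]⁶` of proportions of days each
component was given over time in care, collected in an `N × 6` matrix
`X_nl`. Stratification uses a Dirichlet-process Gaussian mixture (DPGMM):
a truncated stick-breaking prior `v_k ~ Beta(1, α)`,
`π_k = v_k ∏_{j<k}(1−v_j)` over mixture weights (concentration `α = 10⁻⁵`
by default, preferring few uneven clusters) with Normal–Wishart priors over
per-component means and full covariances, centred on the dataset mean and
covariance. The approximate posterior is found by coordinate-ascent
variational inference maximising the evidence lower bound (ELBO), stopping
when the improvement falls below 10⁻³; infants are assigned to the component
with the highest posterior responsibility.

Around the mixture sit:

* **a synthetic cohort generator** planting nutritional archetypes,
  admission covariates, realistic stay lengths and outcome effects into
  registry-shaped episodic/daily CSV tables, with full ground truth;
* **curation**: LOCF resolution of episodic constants, timestamp-union
  merging of transfer-day duplicates, removal of incomplete days, LMS
  growth-reference z-scores `z = ((w/M)^L − 1)/(L·S)`, derivation of
  mortality, severe NEC, BPD, MM-at-discharge, length of stay and 36-week
  weight z-scores;
* **reproducibility**: the clustering F-measure
  `F_total = Σ_i (n_i·/n) · max_j F(i,j)` (class-weighted best-match
  harmonic mean of cluster purity and completeness), run-to-run and
  odd/even-birth-year split protocols, posterior predictive checks, and
  Mann–Whitney/Fisher comparisons of matched cluster pairs with Bonferroni
  correction;
* **admission grouping**: across-cluster z-scores of mean admission
  variables, Ward hierarchical clustering and PCA projection, with lettered
  admission groups from an explicit dendrogram cut;
* **deconfounder**: probabilistic-PCA factor model (3 latents) fitted to
  the mean-centred covariates of a two-cluster contrast, verified by a PPC
  on a 20% hold-out, whose latent means augment linear/logistic outcome
  regressions.

## Worked example

```python
import pandas as pd
import neostrat as ns

spec = ns.CohortSpec(n_infants=2000, seed=42)          # 3 planted archetypes
episodes, daily, truth = ns.generate_cohort(spec)
cohort = ns.curate(episodes, daily)

model = ns.DirichletProcessGMM(truncation=20, random_state=0).fit(cohort.matrix)
labels = model.predict(cohort.matrix)
print(model.n_effective_clusters(labels=labels))       # -> 3
print(ns.f_measure(truth.labels.loc[cohort.nutrition.index], labels))  # -> 1.0

sizes = pd.Series(labels).value_counts()
design, factor, result = ns.deconfound(
    cohort.infants, labels, sizes.index[0], sizes.index[1],
    "w36_zscore", seed=0)
print(result.table.loc["Nutritional Treatment"])
```

Output on this seed:

```
curated infants: 2000 | median LoS: 45.0
clusters holding >=1%: 3
F vs planted archetypes: 1.0
    size  ga_weeks  mortality   bpd    MM   HDM   BMF    FM    PN    GE
14  1008     29.21       0.05  0.16  0.55  0.12  0.14  0.70  0.22  0.16
6    579     28.54       0.06  0.13  0.90  0.12  0.30  0.12  0.22  0.15
0    413     25.48       0.49  0.37  0.35  0.13  0.12  0.18  0.70  0.55
treatment effect on W36 z-score: 0.39 [0.32, 0.46], p=1.6e-24
factor-model PPC p = 0.65; adjusted r2 = 0.68
```

The three recovered clusters reproduce the planted archetypes — a
formula/maternal-milk trade-off group, a maternal-milk-dominant group with
fortifier, and a parenteral-intensive group of sicker, more preterm infants
(note its mortality and BPD rates). The treatment coefficient estimates the
planted contrast in 36-week weight z-score between the formula-mix and
maternal-milk clusters (+0.15 − (−0.18) = 0.33 planted); the factor-model
PPC p-value near 0.5 indicates the substitute-confounder model describes
the covariates adequately.

The same pipeline is scriptable from a shell:

```bash
neostrat simulate --n 2000 --seed 42 --out cohort/
neostrat curate --episodes cohort/episodes.csv --daily cohort/daily.csv --out curated/
neostrat fit --matrix curated/nutrition_matrix.csv --out fitted/
neostrat run-all --seed 42 --out run/          # full pipeline + manifest
```

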