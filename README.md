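# taxometrics

Taxometric analysis of ordinal symptom indicators: is a construct **taxonic**
(a qualitatively distinct latent class exists, e.g. "disordered" vs. not) or
**dimensional** (severity varies along a continuum)? The question matters for
how conditions such as Internet Gaming Disorder are diagnosed: a threshold on
a continuum behaves very differently from a boundary around a real class.

The package implements the modern comparison-curve workflow on case × item
questionnaire data (e.g. the 18-item CSAS, two 4-point items per DSM-5
criterion):

1. **Indicators** — each criterion's two items (recoded 0–3) are summed into
   one 0–6 indicator; DSM-5 (9 indicators) and ICD-11 (4 indicators) sets are
   built in. Pre-taxometric suitability checks: indicator validity
   *d* > 1.25 between the putative groups (5-of-9 / 4-of-4 criterion rules),
   full-sample mean inter-indicator *r* > .30, within-group (nuisance)
   *r* ≤ .30.
2. **Curves** — the three non-redundant procedures: MAMBAC (mean above minus
   below a cut), MAXEIG (largest eigenvalue of the zero-diagonal covariance
   of the output indicators in sliding windows), and L-Mode (kernel density
   of one-factor principal-axis scores). Taxa produce peaked / multimodal
   curves; continua produce flat, dish-shaped or unimodal ones.
3. **Comparison data** — two finite populations (default *N* = 100,000) that
   reproduce the empirical marginals and correlations by iterative rank
   remapping of bootstrap marginals, one generated under a categorical model
   at an assumed base rate *p*, one under a dimensional model. *K* = 100
   samples of the empirical *n* are drawn from each.
4. **CCFI** — with RMS curve distances FitDim and FitCat to the two sample
   bands,

   CCFI = FitDim / (FitDim + FitCat) ∈ [0, 1],

   values below 0.50 favour a dimensional structure, above 0.50 a categorical
   one. The verdict uses the mean CCFI over the three procedures, and the
   **CCFI profile** repeats the analysis over the base-rate grid
   *p* = .025, .050, …, .975; under a true taxon the profile peaks near the
   true base rate.

A synthetic-data module generates ordinal indicator data with known latent
structure (single-factor continua or two-group mixtures with controllable
base rate, separation and nuisance correlation), calibrated so that marginal
means/SDs and the mean inter-indicator correlation match values reported for
large adolescent gaming-symptom surveys.

## Worked example

```python
import taxometrics as tx

# a planted taxon: 25% of 1,000 cases, separation d = 2, nuisance r = .2
sample = tx.make_taxonic(1000, n_indicators=4, base_rate=0.25,
                         separation=2.0, within_group_r=0.2, seed=11)

report = tx.suitability_report(sample.indicators, sample.labels)
print("indicator validity d:", report.cohens_d.round(2))
print("mean inter-indicator r:", round(report.mean_inter_r, 3))

est = tx.CCFIAnalysis(base_rate=0.25, n_pop=10_000, k_samples=10,
                      random_state=11).fit(sample.indicators)
print("CCFI per procedure:", {k: round(v, 3) for k, v in est.ccfi_.items()})
print("mean CCFI:", round(est.mean_ccfi_, 3), "->", est.verdict_)
```

prints

```
indicator validity d: [1.9  1.93 1.96 2.  ]
mean inter-indicator r: 0.518
CCFI per procedure: {'mambac': 0.771, 'maxeig': 0.777, 'lmode': 0.792}
mean CCFI: 0.78 -> taxonic
```

Every indicator separates the planted groups by roughly the requested
*d* = 2, and all three procedures put the CCFI well above 0.50, so the mean
CCFI correctly flags the planted class. On a single-factor dataset the same
call lands well below 0.50.

`CCFIProfile` runs the same comparison over the base-rate grid and exposes
`mean_profile_`, `argmax_base_rate_` and `verdict_` (`dimensional` below
0.45, `taxonic` above 0.55, otherwise `ambiguous`).

## Command line

```bash
# synthetic fixture: 1,000 cases, 9 calibrated indicators, single factor
taxometrics simulate --preset csas-dsm5 --structure dimensional -n 1000 \
    --seed 1 -o dim.csv

# full pipeline: suitability, curve panels, CCFI profile, JSON + PNG report
taxometrics analyze survey.csv --level items --set dsm5 --stratify sex \
    --seed 1 --outdir report/
```

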