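# tilquant

Region-based quantification of tumour-infiltrating lymphocytes (TILs) with
prognostic survival analysis, for computational-pathology groups working with
cell detections from multiplexed immunohistochemistry projected onto annotated
H&E slides.

Given a tumour-bulk outline, an epithelium/stroma segmentation raster and
per-marker lymphocyte detections (CD3, CD8, FOXP3), `tilquant` builds seven
measurement regions — the intratumoural area (**ITA**) and its epithelial
(**ITT**) and stromal (**ITS**) parts, plus invasive-margin bands of total
width 1 mm (**IM1**, outline ± 500 µm) and 2 mm (**IM2**, outline ± 1 mm) with
inner/outer density ratios (**IM1IO**, **IM2IO**) — and computes, per marker
*m* and region *r*:

- density ρ<sub>m,r</sub> = count / area(r) in cells/mm²,
- the survival covariate z<sub>m,r</sub> = ρ<sub>m,r</sub>/100 (CD3, CD8) or
  ρ<sub>m,r</sub>/10 (FOXP3),
- between-marker count ratios (CD8/CD3, FOXP3/CD3, CD8/FOXP3).

Each measure enters a univariable Cox proportional-hazards model
h(t|z) = h₀(t)·exp(βz) for relapse-free and overall survival; the hazard
ratio exp(β̂) is reported with a percentile bootstrap 95% CI (5000 patient
resamples by default, Efron tie handling) and a Wald p-value, and the
intratumoural measures are additionally median-dichotomized for Kaplan–Meier
curves with log-rank tests. A synthetic cohort generator (perturbed-disk
tumours, inhomogeneous Poisson infiltrates with inflamed / excluded / desert
phenotypes, Weibull proportional-hazards outcomes) exercises the whole
pipeline without any imaging data. See `docs/methods.md` for the model
details and design choices.

## Worked example

Simulate a 94-case cohort and run the full analysis (the `simulate` section
accepts any `SimConfig` field):

```python
from tilquant.pipeline import run_pipeline

res = run_pipeline(
    {"seed": 7, "n_boot": 1000, "simulate": {"n_cases": 94, "seed": 7}},
    out_dir="demo",
)
m = res.measures
print("CD3_ITA covariate: median %.2f IQR %.2f-%.2f" %
      (m.CD3_ITA.median(), m.CD3_ITA.quantile(.25), m.CD3_ITA.quantile(.75)))
cols = ["measure", "outcome", "hr", "ci_low", "ci_high", "p"]
print(res.cox_results.query("measure == 'CD3_ITA'")[cols].round(3).to_string(index=False))
```

prints

```
CD3_ITA covariate: median 2.17 IQR 1.48-3.27
measure outcome    hr  ci_low  ci_high     p
CD3_ITA     RFS 0.912   0.681    1.101 0.423
CD3_ITA      OS 0.840   0.657    1.033 0.094
```

Read: the cohort's intratumoural CD3 density is ~217 cells/mm² at the median
(the covariate counts increments of 100 cells/mm²), and each additional
increment multiplies the death hazard by 0.840 (95% CI 0.657–1.033) — the
generator's true effect is 0.85 per unit, and with only 22 relapses and 37
deaths among 94 patients the interval is wide, as expected at this cohort
size. `demo/` also contains the per-case measures table, the full Cox table
for all 44 measures × 2 outcomes (with Bonferroni-survival annotations),
median-split Kaplan–Meier results, and a seeded run log.

The same run from a shell:

```bash
tilquant simulate --out-dir cohort --seed 7 --n-cases 94
tilquant regions  --manifest cohort/manifest.yaml --out-dir results
tilquant quantify --manifest cohort/manifest.yaml --out-dir results --heatmaps
tilquant survive  --measures results/measures.csv --outcomes cohort/outcomes.csv \
                  --out-dir results --n-boot 5000 --seed 7
# or everything at once from a YAML config:
tilquant all --config config.yaml
```

`tilquant --help` lists every measure exactly as the output columns spell it
(`CD3_ITA` … `CD8_FOXP3_ratio_IM2IO`).

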