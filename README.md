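# tmtme

Construction and evaluation of a combined **telomere / tumor-microenvironment
(TM-TME) prognostic classifier** for glioma-style expression cohorts.

Lower-grade gliomas progress unpredictably, and single-gene biomarkers
stratify prognosis poorly. This package implements a reusable, tested
version of a two-axis risk construction for right-censored cohorts: one
axis summarizes telomere-maintenance gene expression, the other the
favorable immune-cell content of the tumor microenvironment, and their
crossed median splits define prognostic subgroups. It is aimed at
biostatisticians and computational biologists who want the full pipeline —
gene screening, penalized selection, bootstrap-stabilized weighting,
scoring, subgrouping, survival evaluation — as a library with a thin CLI,
plus a synthetic-cohort generator so every stage is testable without
downloading any cohort.

## The method

Given a training cohort with expression `exp(gene_i)` (log2(TPM+1)),
immune-cell fractions `fra(cell_j)` (simplex rows, e.g. CIBERSORT output)
and overall survival:

1. univariate Cox screen of candidate genes (Wald p < α), then lasso-Cox
   selection with cross-validated penalty → the gene signature;
2. multivariate Cox fits give per-feature coefficients **Coef**; B
   bootstrap refits give their standard deviations **SD**; each feature's
   weight is Coef/SD;
3. scores per sample

   TM score = Σᵢ (Coefᵢ/SDᵢ) · exp(geneᵢ)    TME score = −Σⱼ (Coefⱼ/SDⱼ) · fra(cellⱼ)

   so high TM = worse, high TME = better prognosis;
4. each cohort is split at its **own** TM and TME medians, crossed into
   four groups, and TM_L+TME_L / TM_H+TME_H are merged into "Mixed",
   giving the three-level classifier TM_L+TME_H > Mixed > TM_H+TME_L;
5. evaluation: Kaplan–Meier curves, k-sample log-rank, Cox hazard ratios
   versus TM_L+TME_H, and IPCW time-dependent AUC at 3/5/7 years for the
   combined risk z(TM) − z(TME).

A validation cohort is scored with the *training* weights but split at its
*own* medians. See `docs/methods.md` for estimators, defaults, and what
the synthetic cohorts do and do not emulate.

## Worked example

```python
from tmtme import SyntheticCohortConfig, generate_cohort, TMTMEClassifier

train = generate_cohort(SyntheticCohortConfig(seed=0))
valid = generate_cohort(SyntheticCohortConfig(seed=1000))

clf = TMTMEClassifier(cell_cols=list(train.fractions.columns),
                      cells=train.truth["favorable_cells"], B=200, seed=0)
clf.fit(train.features(), train.survival)
print("signature genes:", len(clf.selected_genes_))

report = clf.evaluate(valid.features(), valid.survival)
print("validation subgroup sizes:", report["subgroup_counts"])
print("log-rank: chi2 = %.1f (df=%d), p = %.3g" % (
    report["logrank"]["statistic"], report["logrank"]["df"],
    report["logrank"]["p_value"]))
print("median survival (days):",
      {k: round(v) for k, v in report["median_survival"].items()})
print("AUC(risk):", {k: round(v, 3) for k, v in report["auc"]["risk"].items()})
```

prints

```
signature genes: 12
validation subgroup sizes: {'TM_L+TME_H': 149, 'Mixed': 302, 'TM_H+TME_L': 149}
log-rank: chi2 = 200.3 (df=2), p = 3.18e-44
median survival (days): {'TM_L+TME_H': 32915, 'Mixed': 7339, 'TM_H+TME_L': 2090}
AUC(risk): {'3y': 0.85, '5y': 0.81, '7y': 0.817}
```

The lasso recovered a 12-gene signature (the 10 planted prognostic genes
plus 2 passengers). On the held-out cohort — scored with training weights,
split at its own medians — the three subgroups separate sharply: the
favorable TM_L+TME_H group's median survival is ~16× that of TM_H+TME_L,
the 3-group log-rank is decisive, and the combined risk score predicts
3/5/7-year survival with AUC ≈ 0.81–0.85.

The same pipeline runs from the shell on TSV inputs:

```bash
tmtme simulate --seed 0 --outdir cohortA          # or bring your own TSVs
tmtme run --config config.yaml --seed 0 --outdir results/
```

where `config.yaml` names expression/fractions/clinical files for a
training (and optionally validation) cohort; `tmtme run` writes
`selection.json`, `weights.json`, per-cohort `scores.tsv` / `labels.tsv` /
`stats.json`, and a `run.log` with versions, seeds and dropped resamples.
Stage-wise subcommands (`select`, `train`, `score`, `classify`,
`evaluate`) expose the intermediate artifacts.

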