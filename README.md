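# mobindex

Contig-level co-localization analysis of metal-resistance genes (MRGs),
antibiotic-resistance genes (ARGs) and virulence factor genes (VFGs) in
assembled metagenomes, for microbiome researchers studying metal-driven
co-selection of resistance — e.g. in mining-impacted soils.

Given per-sample annotation tables (alignment hits of predicted proteins
against resistance/virulence/MGE catalogs, a contig table, and sample
metadata with metal concentrations and physicochemical properties), the
package computes three dimensionless indices per sample *i*:

- **Carrying rate** — the fraction of contigs bearing at least one gene of
  a class:
  `CR_i = N_i^contigs(MRGs/ARGs/VFGs) / N_i^contigs`
- **Co-occurrence rate** — the fraction of contigs bearing two or more gene
  classes simultaneously:
  `CoR_i = N_i^contigs(co-occurrence) / N_i^contigs`
- **Mobility potential** — the fraction of a class's genes co-located on a
  contig with a mobile genetic element (MGE: plasmid, IS, transposon,
  integron or ICE), a proxy for horizontal-transfer likelihood (not a
  transfer frequency):
  `MP_i = N_i(genes co-located with MGEs) / N_i(genes)`

All three are computed with exact rational arithmetic, so with 100,000
contigs one additional carrier changes CR by exactly 1 × 10⁻⁵. A sample
with zero genes of a class has an *undefined* MP, reported as missing,
never as zero.

Around the indices the package provides the full statistical layer such a
study needs: alpha diversity (Shannon, richness, Pielou), Student's
t/Wilcoxon group tests, Bray–Curtis and Horn (1 − Morisita–Horn)
dissimilarities, principal coordinate analysis, permutation PERMANOVA
(exhaustive when feasible), and an environmental-driver regression cascade
— VIF screening (≥ 5 excluded), multiple linear regression, Huber
M-estimation, and Bayesian linear regression with weakly-informative
priors (coefficients ~ normal(0, 0.5), residual sd ~ exponential(5)) with
split R-hat / ESS / posterior-predictive diagnostics — plus Spearman
correlation matrices. A synthetic-data generator emulates the whole study
design (12 samples: 8 metal-contaminated, 4 control) with closed-form
ground-truth index expectations, so every statistic is testable without
any sequencing data.

## Worked example

`examples/03_regression_cascade.py` simulates an index-like response —
ARG mobility potential linear in vanadium with a true effect of
4.7 × 10⁻⁵ per mg/kg — and fits it twice:

```
cascade selected: mlr
branch trail    : vif_screen: retained ['V'], excluded [] | assumptions met -> mlr
V effect: 4.94e-05 per mg/kg (95% CI 4.26e-05 to 5.63e-05); true value 4.7e-05

Bayesian refit: posterior mean 4.88e-05 per mg/kg (95% credible interval 4.2e-05 to 5.56e-05)
max split R-hat = 1.000 (1.00 = converged), min bulk ESS = 7544
posterior predictive p-values: mean 0.50, sd 0.45 (near 0 or 1 would signal misfit)
```

The cascade kept ordinary least squares because the residuals passed both
the normality and homoscedasticity screens; both fits recover the true
per-mg/kg effect inside their 95% intervals, and the Bayesian diagnostics
(R-hat = 1.00, large effective sample sizes, moderate posterior-predictive
p-values) indicate a converged, well-fitting model.

The other examples cover the indices themselves
(`01_colocalization_indices.py`), diversity and PERMANOVA
(`02_diversity_and_permanova.py`) and the one-shot pipeline with its
machine-readable manifest and markdown report (`04_full_pipeline.py`).

## Command line

```bash
mobindex synth   --seed 17 --out demo/            # synthetic dataset + ground truth
mobindex indices --in demo/ --out indices.tsv     # CR/CoR/MP per sample
mobindex run     --config run.yaml                # full reproducible pipeline
```

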