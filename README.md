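# radharmon

Batch-effect harmonization and radiogenomic association scanning for
multi-scanner PET radiomic feature matrices.

## The problem

Radiomic texture features extracted from FDG PET/CT tumor images are
highly sensitive to the scanner and reconstruction protocol that produced
the image. When a cohort mixes instruments — say 208 lung-cancer patients
scanned on two different PET/CT systems ("batch 1" and "batch 2") — the
scanner signature can dwarf the biology, and any downstream association
between features and tumor genotype is confounded. `radharmon` implements
and compares the three standard remedies, quantifies how much scanner
signal each one leaves behind, and runs the downstream feature–mutation
association scan, so that the whole comparison is reproducible on
synthetic or user data.

It is aimed at radiomics/radiogenomics researchers who have a subjects ×
features table with a batch label (plus, optionally, binary mutation
calls and phantom measurements) and want a tested, scriptable version of
the harmonize → diagnose → associate workflow.

## Methods implemented

**Phantom ratio correction.** Both scanners image the same uniform
cylinder phantom; for each feature $g$ the ratio
$r_g = \text{phantom}^{(\text{ref})}_g / \text{phantom}^{(\text{other})}_g$
is multiplied onto the non-reference batch.

**ComBat (empirical Bayes location–scale).** Features are standardized,
per-batch location/scale parameters $\gamma_{ig}, \delta^2_{ig}$ are
estimated and shrunk toward parametric priors
($\gamma_{ig} \sim N(\bar\gamma_i, \tau_i^2)$,
$\delta^2_{ig} \sim \text{InverseGamma}(\lambda_i, \theta_i)$, fit by
method of moments, EB fixed point iterated to convergence), and the data
are back-transformed:
$Y^*_{ijg} = \frac{\sigma_g}{\delta^*_{ig}}(Z_{ijg} - \gamma^*_{ig}) + \alpha_g$.
Global mode aligns every batch to the pooled mean/variance; reference
mode aligns all batches to a designated batch, which passes through
unchanged. Verified numerically identical (≈1e-14) to Bioconductor
`sva::ComBat` in both modes.

**Linear batch removal (limma-style).** Per feature, least squares fits
an intercept plus sum-to-zero batch effects and subtracts the batch term;
with two batches both corrected batch means equal the unweighted average
of the observed batch means exactly.

**Diagnostics.** Residual batch effect is quantified by (i) the batch
silhouette $s_i = (b_i - a_i)/\max(a_i, b_i)$, (ii) the kBET rejection
rate — sample a subject, test its $k{=}10$ nearest neighbours' batch
composition against the global batch proportions with Pearson's
$\chi^2$, repeat 1000 times — and (iii) PCA scores colored by batch.
Before/after comparisons use Welch's t-test.

**Association scan.** Each retained gene (minor mutation frequency
≥ 0.05) is regressed on each feature with a univariable logistic model,
$\mathrm{logit}\,P(\text{mut}) = \beta_0 + \beta_1 x$; Wald
$z = \hat\beta_1/\mathrm{SE}$, two-sided normal $p$, Benjamini–Hochberg
adjustment within each feature across genes, and cross-method concordance
as the squared Pearson correlation of paired raw p-values.

A synthetic-data module generates two-batch cohorts with known
location–scale batch effects, heavy-tailed feature scales, mutation
frequencies, and planted feature→mutation couplings, so every stage is
testable without patient data.

## Worked example

```sh
python examples/harmonize_compare.py
```

```
method         kBET rate  mean |s|
uncorrected        1.000    0.4100
phantom            1.000    0.3964
combat-global      0.026    0.0047
combat-ref2        0.019    0.0050
linear             0.018    0.0088
```

Uncorrected, every sampled neighbourhood fails the kBET composition test
(rate 1.0) and subjects sit much closer to their own scanner's subjects
(mean |s| 0.41): the scanners separate cleanly. Phantom correction only
undoes the multiplicative scanner component, so the location shift keeps
the batches separable. ComBat and the linear method remove the batch
term statistically and drive both diagnostics to ≈0 — well-mixed batches.

```sh
python examples/association_scan.py
```

```
significant associations (BH-adjusted p < 0.05):
    feature     gene  estimate     se     z        p    p_adj
feature_001 gene_001       185   28.5  6.48 8.96e-11 4.48e-09
feature_008 gene_001      0.23 0.0452  5.09 3.56e-07 1.78e-05
feature_022 gene_004    -0.391 0.0884 -4.42 9.76e-06 0.000488
feature_001 gene_046     -58.6   18.3  -3.2  0.00138   0.0345
```

The three planted causal couplings are recovered as the top three hits
(the fourth row is a borderline false discovery, as expected at FDR
0.05). Estimates are log-odds per raw feature unit, so their magnitude
tracks each feature's scale. `examples/full_pipeline.py` runs all five
corrections end-to-end and prints the per-method diagnostics plus the
pairwise p-value concordance matrix; `examples/simulate_cohort.py` shows
the generator's knobs. The same stages are scriptable from a shell via
the `radharmon` CLI (`simulate`, `harmonize`, `diagnose`, `associate`,
`concordance`, `run-all`).

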