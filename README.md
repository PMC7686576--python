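# tcellatac

Differential chromatin accessibility and transcriptome analysis of human
CD4/CD8 T cell subsets across age — the full downstream pipeline from
per-sample ATAC-seq peak calls to differential accessibility, permutation
inference on principal components, motif-set enrichment and ribosomal
gene-set tests, together with a synthetic cohort generator so that every
stage is testable without any data download.

## Who this is for

Groups comparing open-chromatin (or expression) count matrices across a
factorial immune-cell design — lineage (CD4/CD8) x differentiation subset
(naive < central memory < effector memory) x age group (young/old) — with
repeated measures per donor. The statistical machinery is general: any
feature-by-sample count matrix with a group design and donor blocks fits.

## The model

Counts for peak *g* in sample *s* are normalized to
log-CPM, `y_gs = log2((c_gs + 0.5)/(N_s + 1) * 1e6)`, and modelled by
generalized least squares on the group-means design:

    y_g = X beta_g + e_g,   Var(e_gs) = sigma_g^2 / w_gs,
    Corr(e_gs, e_gs') = rho   for samples s, s' from the same donor,

where `w_gs` combines observation-level precision weights from a lowess
mean–variance trend (inverse fourth power of the smoothed quarter-root
residual SD, evaluated at fitted log-counts) with per-sample quality weights
(iterative moment estimator, clipped to [0.25, 4], geometric mean 1), and
`rho` is a consensus intra-donor correlation. Residual variances are shrunk
toward a scaled inverse chi-square prior by matching moments of the
log-variances (digamma/trigamma inversion for the prior df `d0` and prior
variance `s0^2`), giving moderated t statistics on `d0 + df` degrees of
freedom; multiplicity is handled with Benjamini–Hochberg.

The combined aging contrast per lineage is

    (naive/old - naive/young) + (CM/old - CM/young) + (EM/old - EM/young),

a shared age effect across differentiation subsets. Around the model sit a
consensus peak atlas (peaks shared by >= 2 samples, merged at >= 50%
reciprocal overlap of the shorter peak), variable-feature PCA with
donor-level stratified permutation tests (paired lineage sign-flip,
two-sample age relabelling, combined ordinal trend test, ordering
probability 1/g!), gap-statistic k-means clustering, hypergeometric
motif-set enrichment with family reduction, nearest-TSS gene assignment
(10 kb cap), EASE-score term enrichment, and Wilcoxon gene-set shift tests
for the ribosomal RPL/RPS/MRP sets.

## Worked example

```python
from tcellatac import (SimConfig, generate_cohort, normalize_and_weight,
                       fit_differential, aging_contrast, top_variable_features,
                       pca_scores, motif_enrichment, best_per_family)

cfg = SimConfig(seed=7)                      # 6 young + 4 old donors,
bundle = generate_cohort(cfg)                # 2 lineages x 3 subsets, 2000 peaks
wm = normalize_and_weight(bundle.atac_counts, bundle.samples["group"],
                          bundle.samples["donor"])
res = fit_differential(wm, [aging_contrast("CD4"), aging_contrast("CD8")])
for lin in ("CD4", "CD8"):
    tab = res.for_contrast(f"aging_{lin}")
    print(f"aging_{lin}: {(tab.q_value < 0.05).sum()} differential peaks (q<0.05)")

pca = pca_scores(wm.logcpm.loc[top_variable_features(wm.logcpm, 5000)], 3)
print("PC variance fractions:", [round(v, 3) for v in pca.variance_fractions])

tab = res.for_contrast("aging_CD8")
closing = set(tab.index[(tab.q_value < 0.05) & (tab.log_fc < 0)])
fam = best_per_family(motif_enrichment(closing, set(tab.index) - closing,
                                       bundle.motifs))
print(fam[["motif_id", "family", "p_value"]].head(3).to_string(index=False))
```

prints

```
aging_CD4: 166 differential peaks (q<0.05)
aging_CD8: 315 differential peaks (q<0.05)
PC variance fractions: [0.359, 0.144, 0.056]
 motif_id family      p_value
NRF1_like   NRF1 2.777973e-52
 YY1_like    YY1 4.804787e-45
 ETS_like    ETS 2.869808e-03
```

Read: the cohort plants roughly twice as many aging peaks in CD8 as in CD4,
and the moderated aging contrasts recover that asymmetry; PC1 of the 5000
most variable peaks carries the differentiation axis (36% of variance); and
the peaks closing with age in CD8 are dominated by NRF1-like and YY1-like
motif labels — the regulatory signature whose loss distinguishes aged CD8
from aged CD4 T cells.

## Command line

```sh
tcellatac simulate --seed 7 --out fixture/          # write a synthetic study
tcellatac run-all --config pipeline.yaml            # every stage, one command
tcellatac atlas | diff | pca | cluster | enrich | genesets   # stage by stage
```

A pipeline YAML needs `seed`, `output_dir` and either a `simulate:` block
(SimConfig fields) or an `inputs:` block (sample sheet CSV, per-sample peak
BEDs and/or a count TSV, gene model TSV, motif TSV, GMT). All outputs are
TSV plus a `manifest.json` and a `run_log.txt` that records seeds and
deliberate methodological deviations.

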