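# lungmeth

Genome-wide DNA-methylation analysis of early-stage non-small cell lung
cancer (NSCLC), built as a tested, reusable pipeline over promoter-centric
Infinium-27K-style beta values. It is written for epigenomics analysts who
want the full screening workflow — differential methylation, promoter
positional annotation, methylation–expression integration, and prognostic
marker discovery — with every statistic implemented transparently and
validated against brute-force oracles, and a synthetic-data generator that
emulates the study design so the whole pipeline runs with no external data.

## What it computes

**Beta values.** Per CpG and sample, β = M/(M+U) ∈ [0,1] (methylated over
total signal). Arrays are quantile normalized (rank-wise means; ties get the
mean of their tied target quantiles).

**Differential screening.** Per-CpG empirical-Bayes moderated t-tests: each
probe's pooled variance s²_g (df d_g) is shrunk toward a scaled
inverse-chi-square prior fitted by method of moments on log-variances,

    s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g),
    t_g = Δβ_g / (s̃_g √(1/n_A + 1/n_B)),   df = d₀ + d_g,

with Benjamini–Hochberg FDR and a dual calling rule: q < 0.05 **and**
|Δβ| ≥ 0.136. Contrasts: tumor vs normal, SCC vs AC, smoker vs non-smoker,
plus a moderated per-CpG regression of β on pack-years.

**Positional annotation.** Median and quartiles of signed TSS distance and
CpG-island fractions per direction; Welch two-sample t-test on the hyper vs
hypo distance vectors. The island caller applies the classic criteria
(≥200 bp, GC ≥ 50%, observed/expected CpG ≥ 0.6) over all windows and merges.

**Expression integration.** Pearson correlation of each called CpG's β with
its gene's median expression, with a permutation p-value obtained by jointly
permuting sample labels of the gene's expression-probe block and recomputing
the median profile; p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1). The
inverse-correlation census reports the fraction of called CpGs with r < 0.

**Survival screens.** After excluding patients surviving ≤ 1 month:
(1) per-CpG Kaplan–Meier over low [0,0.25) / medium [0.25,0.75) /
high [0.75,1] methylation groups, log-rank tested only when every non-empty
group has > 5 patients, BH-corrected; (2) a Cox (continuous β, Breslow ties,
Newton–Raphson) + Wilcoxon rank-sum (exact for small groups) screen of
1–24-month decedents vs ≥ 60-month survivors with the same 0.136 Δβ cutoff.

**QC.** Technical-replicate concordance, row-z-scored hierarchical
clustering (average linkage, Euclidean) of the top-100 |Δβ| significant
CpGs, and flagging of samples whose cluster contradicts their tissue label.

## Worked example

The numbered drivers under `analysis/` run the whole study on a simulated
cohort (48 stage-I tumors — 32 SCC, 16 AC — vs 18 cancer-free controls,
1000 promoter CpGs, planted Δβ = 0.2 effects):

```bash
python analysis/01_simulate.py
python analysis/02_normalize_qc.py
python analysis/03_differential.py
python analysis/04_cluster_heatmap.py
python analysis/05_annotation.py
python analysis/06_integration.py
python analysis/07_survival.py
```

Selected output (seed 1):

```
replicate concordance (Pearson r over all probes):
  T32|T32r: 0.9996
  T41|T41r: 0.9995
tumor_vs_normal: 52 hyper CpGs in 51 genes; 46 hypo CpGs in 45 genes
direction  n_cpgs  median_dist  frac_in_island
    hyper      52        -60.0          0.8269
     hypo      46       -965.0          0.1522
hyper vs hypo TSS distance: Welch t = 5.305, p = 7.75e-07
tumor_vs_normal: 68 of 98 differential CpGs inversely correlated (69.4%)
excluded 2 patients with <= 1 month survival
KM screen: 423 CpGs passed the >5-per-group rule; 0 significant after FDR
Cox+Wilcoxon screen (27 short vs 11 long survivors): 3 CpGs called
```

Reading this: the duplicate arrays agree at r ≈ 0.999; the planted
hypermethylation concentrates inside CpG islands near the TSS while
hypomethylation sits upstream outside islands (Welch p ≈ 8·10⁻⁷); about
two-thirds of the differential CpGs anticorrelate with their gene's
expression (the planted coupled fraction plus chance negatives); and the
survival screens recover planted prognostic CpGs (the best log-rank CpG is
the planted marker) while a single true marker cannot clear FDR across ~400
tested CpGs at n = 46 — the honest multiplicity cost of this cohort size.

The same steps are scriptable from a shell via the `lungmeth` CLI
(`simulate`, `normalize`, `diff`, `annotate`, `integrate`, `survive`, `qc`);
run `lungmeth --help`.

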