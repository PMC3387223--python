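# Methods

## The analysis model

The pipeline treats a promoter-array methylation study as five linked
analyses over a probes × samples matrix of beta values β = M/(M+U) ∈ [0,1].

### Normalization

Between-array differences are removed by quantile normalization on the beta
scale: each column's sorted values are replaced by the across-column
rank-wise mean, restored in original rank order. Tied input values receive
the mean of their tied target quantiles, which makes the map deterministic
and stable under sample permutation. Two consequences worth knowing:
normalization is an exact fixed point (idempotent) on tie-free columns, but
with ties the tie rule introduces drift on the order of 10⁻⁵ on repeated
application, and tied columns deviate from the shared distribution at tied
ranks. Normalization pools all arrays (tumors and normals together); an
optional logit/M-value transform exists but is off by default, since all
downstream effect sizes are defined on the beta scale.

### Differential testing

Per-CpG two-group comparisons use an empirical-Bayes moderated t. The
per-probe pooled variances s²_g (residual df d_g) are modeled as draws from
a scaled inverse-chi-square prior with df d₀ and scale s₀². The prior is
fitted by method of moments on z = log s²: the mean and variance of
e = z − ψ(d_g/2) + log(d_g/2) are matched against the digamma/trigamma
expressions, solving trigamma(d₀/2) = Var(e) − trigamma(d_g/2) by Newton
iteration. When the observed spread does not exceed the chi-square sampling
spread, d₀ = ∞ (complete shrinkage); exactly constant variances return that
constant as s₀². Posterior variances s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)
give t-statistics with d₀ + d_g df. At d₀ = 0 this is exactly the ordinary
pooled t (unit-tested to 10⁻¹⁰ against an independent implementation).

Calls combine BH FDR q < 0.05 with an effect cutoff |Δβ| ≥ 0.136, applied
inclusively ("at least" 13.6 percentage points of methylation). The same
moderated machinery drives the SCC−AC contrast (sign convention SCC minus
AC), the smoker vs non-smoker contrast (the 3-vs-44 imbalance is allowed;
power is correspondingly low), and a per-CpG simple regression of β on
pack-years with moderated residual variance. FDR is controlled per contrast.

### Positional annotation

TSS distances are signed (negative = upstream); quartiles use type-7 linear
interpolation between order statistics. The hyper-vs-hypo distance
comparison is a Welch unequal-variance t-test on the signed distances. The
CpG-island caller marks the union of all windows ≥ 200 bp with GC ≥ 0.5 and
observed/expected CpG ≥ 0.6, where obs/exp = (#CG × length)/(#C × #G);
coordinates are 0-based half-open. The implementation is an O(L²) prefix-sum
scan, adequate for promoter-scale sequences, and is equality-tested against
an exhaustive every-window oracle.

### Methylation–expression integration

Gene-level expression is the per-sample median across the gene's expression
probes (midpoint convention for even counts). For each called CpG the
Pearson correlation r between its β vector and the gene's median profile is
tested by permutation: sample labels of the expression-probe block are
permuted jointly, the median recomputed, and two-sided
p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1). Because a joint relabeling of
whole sample columns commutes with the per-column median, the implementation
permutes the precomputed median profile — the definition is unchanged but
each round is O(n) instead of O(probes × n). The inverse census counts
r < 0 among called CpGs (significance is reported alongside, not required).
n_perm is a free parameter; the analysis driver uses 1,000.

### Survival screens

Patients surviving ≤ 1 month are excluded first (post-operative deaths).

*Kaplan–Meier screen.* Betas are discretized: low [0, 0.25), medium
[0.25, 0.75), high [0.75, 1]. A CpG is tested only when at least two groups
are non-empty and every non-empty group holds more than five patients
(strictly > 5). The k-group log-rank statistic sums per-event-time observed
minus expected events against the multivariate hypergeometric variance;
p from chi-square with k−1 df; BH FDR across tested CpGs. Events precede
censorings at tied times.

*Cox + Wilcoxon screen.* Strata: short = survival in [1, 24] months with
the death observed; long = survival ≥ 60 months (dead or censored). Per CpG:
a single-covariate Cox fit of continuous β over all included patients
(Breslow tie handling, Newton–Raphson on the partial likelihood, damped
steps, Wald p), a Wilcoxon rank-sum test of β short vs long (exact null
distribution by dynamic programming when min(n₁,n₂) ≤ 8 without ties,
tie-corrected continuity-corrected normal approximation otherwise), and
Δβ = mean(short) − mean(long). A marker is called only when both p < 0.05
and |Δβ| ≥ 0.136 — the conjunctive reading is the only one that uses both
tests as filters. Degenerate Cox fits (constant covariate, < 2 events,
non-convergence in 50 iterations) are flagged and excluded from calls, not
raised.

### QC and clustering

Replicate concordance is the per-pair Pearson r over all probes within a
replicate group. The heatmap step z-scores each probe row (constant rows
become zeros, with a warning), clusters rows and columns agglomeratively
(average linkage on Euclidean distances — the choice is configurable and
recorded in the result), and cuts the sample tree at two clusters; samples
whose cluster majority tissue label contradicts their own are flagged for
human review, never auto-excluded.

## The synthetic-data generator

The generator emulates the study design end to end: 48 stage-I tumors
(32 SCC, 16 AC) vs 18 cancer-free controls; ~promoter-only probes, 1–3 per
gene, TSS distances uniform on [−1500, +1000] bp with island probability
decaying in |distance| (overall island fraction 0.7); bimodal baselines
(island probes low-methylated, non-island high); Beta-distributed noise
β ~ Beta(μν, (1−μ)ν) with precision ν = 50, which keeps values in [0,1] and
reproduces array heteroscedasticity. Default array size is 1000 probes in
600 genes — the 27,578/14,495 design is emulated structurally (the
full-scale manifest is generated in tests) but scaled down so the whole
pipeline and its seed-replicated recovery suites run quickly.

Planted structure, all recorded as ground truth:

* tumor-vs-normal effects: 5% hyper (+0.2) and 4% hypo (−0.2) CpGs, placed
  by weighted sampling at odds 8:1 favoring island/TSS-proximal probes
  (hyper) or non-island upstream probes (hypo), restricted to probes whose
  baseline can absorb the full effect without clipping; this makes the
  island-composition contrast recoverable but not degenerate;
* an analogous SCC-vs-AC layer (1% / 2%) inside the tumor arm;
* inverse expression coupling for 43.5% of the genes carrying a planted CpG:
  the gene's log2-normal expression mean receives −2.5 × (centered β);
  uncoupled genes split ~50/50 on correlation sign, so the simulated census
  runs above the coupled fraction — the census arithmetic, not its simulated
  value, is the validated quantity;
* one prognostic CpG drawn from the "patient-variable" probe subset (20% of
  background probes get per-patient low/mid/high mixture baselines at
  0.12/0.5/0.88, mirroring the minority of array probes that genuinely vary
  between individuals and making survival discretization non-degenerate);
  survival is exponential with hazard 0.008 · exp(1.0 · group index)/month,
  administratively censored at 120 months. The baseline was chosen so the
  expected short/long survivor strata approximate the emulated cohort's
  12 vs 15. Two patients are forced to ≤ 1 month survival to exercise the
  exclusion rule;
* smoking: 3 never-smokers (0 pack-years), one patient with missing smoking
  data, gamma-distributed pack-years for smokers; 4 CpGs hypomethylated in
  smokers by 0.15; the pack-years slope layer defaults to zero (no planted
  continuous-exposure signal);
* 2 technical replicate pairs (Gaussian noise, sd 0.01) and an optional
  purity knob (`n_diluted`, `dilution_purity`) that scales planted effects
  in selected tumors — its realistic range is not identifiable from the
  emulated study, so it defaults off.

What the generator does **not** emulate: raw two-channel intensities and
their background/dye biases, probe cross-hybridization, batch/chip layout
effects, copy-number confounding, and correlated probe blocks within CpG
islands. Passing recovery tests therefore demonstrates correctness of the
statistics under the assumed generative model, not robustness to those
real-data artifacts.

## Numerical and design choices

* Fixed seeds drive every stochastic component through
  `numpy.random.Generator`; identical seeds give bit-identical TSVs.
* TSV (UTF-8, tab, '.' decimal, empty cell = missing) is the canonical
  dialect; floats are written at 6 significant digits and round-trip exactly
  at that precision. Survival is recorded in months.
* BH q-values follow the step-up definition exactly (oracle-tested);
  moderated p-values with d₀ = ∞ use the normal limit.
* The Wilcoxon exact null distribution is computed by the Gaussian-binomial
  DP; two-sided p doubles the smaller tail (capped at 1).
* Log-rank variance uses the (n−d)/(n−1) hypergeometric factor with a
  pseudoinverse for the k−1-dimensional quadratic form, so exhausted groups
  never produce singular failures.
* Tie-breaks in top-CpG selection: |Δβ| descending, then q ascending, then
  CpG id lexicographic — deterministic heatmaps.

## Known limitations

* The KM screen on the default dataset reports the planted marker as its
  top log-rank hit but 0 FDR-significant CpGs: a single true marker cannot
  clear BH across ~400 tested CpGs at 46 patients. That is the intended
  multiplicity behavior, not a defect.
* The Cox + Wilcoxon combined call has limited power for hazard ratios
  near 2 at this cohort size (~40% recovery); the planted default (log-HR
  1.0 per group step) is recovered in > 90% of cohorts.
* The smoker contrast (3 vs 44) and pack-years regression are reported with
  their honest, low power; the generator plants no pack-years slope by
  default.
* Type-I calibration of the log-rank chi-square approximation is verified
  at n = 200 per replicate; at n ≈ 40 the approximation runs slightly
  anti-conservative (observed ~0.07 at nominal 0.05), which is a property
  of the test itself, not of this implementation.
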