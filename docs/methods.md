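# Methods

`polysweep` re-implements, as a tested library, the population-genomic
workflow used to study the diversification of an allotetraploid crop from a
reference genetic cluster: SNP filtering, windowed diversity and divergence
statistics, a cross-population composite-likelihood sweep scan combined with
a π-ratio track into candidate sweep regions, and differential-expression /
metabolic-network overlay statistics. This note records the models, the
parameters that matter, and the numerical and design choices.

## The neutral cross-population model

Two populations descend from a common ancestor: a *reference* population
(allele frequency `p1` at a biallelic SNP) and a diverged *object*
population (frequency `x`). Neutral drift is modelled as

    x | p1  ~  Normal(p1, ω · p1(1−p1))   truncated to (0, 1),

with the tail mass placed as point masses at 0 and 1 (drift to loss or
fixation). `ω` is a single genome-wide drift variance scale, dimensionless
and ≥ 0; for populations that split `t` generations ago with effective size
`N`, ω ≈ t/2N, so values of 0.02–0.2 cover recently diverged crop clusters.
Sampled counts are binomial: `m2 ~ Binom(n2, x)` for `n2` chromosomes.

`ω` is estimated by a moment estimator averaged over sites polymorphic in
the reference sample:

    ω̂ = mean[ ((p̂1−p̂2)² − p̂1q̂1/(n1−1) − p̂2q̂2/(n2−1)) / (p̂1q̂1 · n1/(n1−1)) ]

The sampling-noise corrections make numerator and denominator unbiased for
`(p1−p2)²` and `p1q1`; negative site terms are kept (dropping them would
bias the mean up) and the final estimate is floored at 0. Two opposing small
biases remain: boundary truncation removes tail variance (pushes ω̂ down),
and the ratio-of-noisy-estimates form pushes it up. In simulation they
nearly cancel — ω̂ ≈ 0.091 at ω = 0.1 and ≈ 0.022 at ω = 0.02 (5 seeds,
30 000 SNPs, n = 60/60) — inside a 10 % band.

## The hitchhiking alternative and the scan

A sweep at genetic distance `d` Morgans from a neutral SNP captures a
lineage with probability `κ = exp(−d/σ)`, where `σ` (Morgans) sets the
physical footprint. A neutral frequency `y` becomes

    x = κ + (1−κ)·y   with probability y   (lineage captured),
    x = (1−κ)·y       otherwise,

so at `d = 0` the site is forced to fixation or loss. The scan slides a
window of fixed genetic width (default 0.005 M) along a bp grid (default
2 kb). At each grid point the score is the composite likelihood ratio

    S = 2 · [ max_σ Σ_k w_k · log L_sweep(site k; κ_k(σ)) − Σ_k w_k · log L_neutral(site k) ]

maximized over a σ grid (default 12 log-spaced values in [1e-5, 1e-1] M,
spanning ~kb to ~Mb footprints at 1 cM/Mb) that always contains a neutral
entry (κ ≡ 0), so S ≥ 0 by construction. The weights `w_k = 1/m_k` down-
weight redundant evidence: `m_k` counts window SNPs (self included) whose
r² with SNP k is ≥ 0.7, computed in the scanned (object) population.
Windows holding more than `max_snps` SNPs (default 100) are uniformly
downsampled: each scan draws one random priority per SNP from the run seed
and every window keeps its lowest-priority SNPs. This is uniform within any
window yet consistent between neighbouring grid points; independent
per-window resampling was tried first and its jitter visibly degraded peak
localization.

Reference frequencies fixed in the sample are clamped to
[1/(2n1), 1−1/(2n1)] because the Gaussian variance degenerates at the
boundary.

### Numerical evaluation of the site likelihoods

The drift distribution is discretized once per site into probability atoms:
Gauss–Legendre nodes (default 64) on the ±8 SD support of the Gaussian
density, plus the two boundary point masses, the whole set renormalized to
sum to 1. Because every atom then carries an exact probability, both site
likelihoods normalize over outcomes to machine precision at any quadrature
size, and the sweep marginal is just an expectation over the same atoms —
no change of variables is needed and κ = 0 reduces to the neutral
likelihood exactly. When the drift SD falls below 1e-5 the density is a
spike and a single atom at `p1` is used, which makes the ω → 0 limit equal
the binomial pmf. Zero probabilities are floored at log = −745.

Inside the genome scan the sweep log-likelihood of each site is tabulated
at 129 κ knots (quadratically spaced toward κ = 1, where the function is
steepest) and linearly interpolated; the κ = 0 knot is pinned to the exact
neutral value. Maximum observed score error is ~3·10⁻⁴ relative, for a ~3×
speed-up. The public `neutral_site_loglik` / `sweep_site_loglik` functions
always evaluate exactly, and `ScanParams(interp_knots=0)` disables the
table.

## Diversity and divergence statistics

* **π** per site is `2m(n−m)/(n(n−1))`; a window's value is the summed site
  π divided by the *full window length in bp* (100 kb windows, 25 kb step
  by default). Only variant sites contribute to the numerator, which is why
  transcriptome-derived SNP sets yield values on the 10⁻⁵ scale.
* **F_ST** is Weir–Cockerham (1984) from diploid genotype counts, including
  the observed-heterozygosity component c, windowed in the "weighted" form
  Σa / Σ(a+b+c); windows with a zero denominator are flagged missing.
* **LD decay** is mean pairwise r² binned by physical distance (default
  3 Mb maximum, mirroring the kb-unit convention of the common CLI tool's
  `-MaxDist 3000`). Phased input uses haplotype D-based r²; unphased input
  falls back to genotype-dosage correlation (Rogers–Huff). Site filters
  (MAF ≥ 0.05, heterozygosity ≤ 0.88, missingness ≤ 0.25) apply to the LD
  computation only.
* **π ratio** is `(π_ref + ε)/(π_obj + ε)` on the 20 kb / 10 kb sweep-scan
  grid, with ε = half the smallest nonzero windowed π across both tracks —
  keeps ratios finite without disturbing ranking. Windows empty in both
  populations are missing.

## Candidate-region calculus

Grid-point scores are averaged into 20 kb windows at 10 kb step. Windows at
or above the genome-wide 80th percentile are selected (empirical quantile,
"higher" interpolation, ties included — deterministic and conservative);
selected windows that overlap or are step-adjacent merge into regions;
windows separated by a missing window do not merge. A region's score is its
maximum constituent window mean, and regions at or above the 95th
percentile of region scores are kept. The π-ratio track contributes its top
50 % of windows, merged the same way, without a second stage. The final
candidate set is the bp-level intersection; the overlap fraction reported
is the share of score regions touching at least one ratio region. Quantiles
are pooled across chromosomes. Genes overlap a region if their half-open
intervals share ≥ 1 bp.

The "top 5 %" stage is interpreted over *regions* (not windows); the caller
exposes both thresholds so the alternative reading is one argument away.

## Differential expression and network overlay

All accessions of a cluster are treated as replicates. For each non-
reference cluster, `log2_ratio = log2((mean FPKM + δ)/(mean FPKM_ref + δ))`
with δ = 1, and a Welch unequal-variance t-test on log2(FPKM + δ) supplies
the p-value; a gene is a DEG iff |log2_ratio| > 1.0 (strict) and p < 0.05
(strict). P-values are deliberately uncorrected by default to match the
thresholding convention this workflow follows; Benjamini–Hochberg is
available as an option. The original workflow's DE engine (Cuffdiff) models
count dispersion from read alignments; at the FPKM-matrix level consumed
here a declared Welch test is the transparent stand-in, with the same
thresholds, replicate treatment and comparisons.

Unique DEGs are genes significant in exactly one comparison; the full Venn
partition is returned and its counts sum to the union. The sub-genome
asymmetry test compares the observed (DEG_A, DEG_C) split against expected
proportions equal to the tested-gene split, by Pearson χ² with 1 df and no
continuity correction.

Reaction nodes of the metabolic network own ortholog IDs; a node's pooled
fold-change is log2 of the ratio of summed FPKM (over accessions and over
the node's DEG-mapped genes) between the derived and the reference cluster.
Sums pool all accessions (the natural reading of "sum expression"); nodes
with no DEG-mapped genes are grey, positive fold-changes red, negative
blue; a zero reference sum with nonzero derived sum is flagged infinite and
red. Local clustering coefficients are 2T/(k(k−1)) (0 for degree < 2), via
networkx.

## The synthetic-data generator

The generator emits exactly the model the scan assumes — ancestral
frequencies with density ∝ 1/x on [0.02, 0.98] (a neutral-like spectrum
with no fixed sites), truncated-Gaussian drift, Bernoulli haplotype
sampling, the κ-transform sweep — so parameter recovery is a meaningful
test of the inference. Defaults: 60 + 60 chromosomes, 2 Mb chromosome,
10 000 SNPs, ω = 0.1, 1 cM/Mb linear map. Realism limits, hence what
passing tests do *not* show: no linkage disequilibrium (an optional
Gaussian-copula AR(1) "copy-with-decay" mode with inter-site correlation
ρ^(Δbp/1000) exists solely for LD-decay testing), no ascertainment bias, no
coalescent correlation between sites, uniform missingness only, and
phasing is free because haplotypes are emitted phased. Sweep implantation
leaves a site untouched when κ ≤ 0.5/n_hap — a perturbation below half an
allele count is unobservable, and resampling anyway would spread binomial
noise to arbitrary distances and delocalize the footprint.

Expression matrices are log-normal: log2 FPKM ~ Normal(μ_g ± effect, sd)
with per-gene baselines μ_g ~ Normal(4, 1) (FPKM ~16 typical), a planted
DE fraction per non-reference cluster with random sign, defaults
effect_log2 = 2, noise_sd = 0.5, 20 accessions per cluster. Annotation and
network tables are toy-structured (non-overlapping gene intervals on
A01…/C01… chromosomes, Poisson node memberships, G(n, p) edges) but carry
every field the overlay statistics consume.

## Recovery-experiment design and problem sizes

The shipped acceptance checks use desk-scale problem sizes chosen once:
ω recovery at 30 000 SNPs × 5 seeds; sweep localization on a 2 Mb,
10 000-SNP chromosome, σ = 0.02 M at the midpoint, 20 seeds, hit = peak
within 50 kb. Two scan-level choices apply to that experiment and are
deliberate test design, not defaults: the drift scale is estimated from the
matched neutral data, because a single 2 Mb chromosome lies entirely inside
a σ = 0.02 M footprint and estimating the "genome-wide" nuisance parameter
from the swept data itself is circular (it inflates ω̂ from 0.1 to ~0.75);
and windows are scanned without the 100-SNP cap, because the cap guards
against redundant correlated SNPs and the LD-free generator has none, while
capping at ~100 of ~1250 window SNPs discards the near-site evidence that
50 kb localization needs. On genome-scale data with sweeps covering a small
genome fraction, neither issue arises and the defaults stand.

## Known limitations

* The Morgan scale of every scan parameter inherits the user-supplied map;
  no recombination map is bundled, and the default 1 cM/Mb linear map is a
  placeholder, not an organism-specific estimate.
* The drift model has a single genome-wide ω; no per-chromosome or
  B-value-like variation.
* The scan reports no significance — percentile-based region calling is a
  screening rule, not a test.
* The Welch-on-FPKM DE caller ignores count-level dispersion and gene
  length effects; it is calibrated for matrix-level screening, not for
  single-gene inference.
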