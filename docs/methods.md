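# Methods

## Study design and scope

`isledv` analyses the relationship between island area and genome-wide
diversity when each island is represented by a single sequenced diploid
individual. The pipeline starts from genotypes (an all-sites VCF), not reads:
alignment and genotype calling are upstream of this package. Five per-island
quantities are computed — observed heterozygosity and its along-genome
variability, windowed runs of homozygosity (ROH), homozygous non-reference
ERV insertion counts, and recent / harmonic-mean Ne from rescaled MSMC2
output — and then related to log10(area) with simple regressions, a
correlation matrix and LASSO variable selection.

## Genotype filtering

Sites are dropped when site QUAL < 20 or when mean depth across non-missing
samples exceeds 30 reads; on surviving sites an individual genotype is set
missing when GQ < 20 or DP < 5. All thresholds are inclusive on the passing
side (QUAL = 20 passes). Two conventions the upstream formats leave open:

* a record with undefined QUAL ('.') passes the QUAL test (the VCFtools
  behaviour for invariant blocks), while a *called genotype* with undefined
  GQ or DP is treated as failing — conservative and reproducible;
* multiallelic records are retained and their heterozygous calls counted as
  heterozygous (a `snps_only` switch drops indel records at parse time).

Internal coordinates are 0-based half-open; VCF stays 1-based and BED output
0-based, with conversions only at I/O boundaries.

## Heterozygosity and its variability

Observed heterozygosity is Σ het sites / Σ genotyped sites over variant and
invariant positions together — the all-sites denominator is what makes the
quantity comparable across individuals with different callable fractions.
Under neutrality it estimates θ = 4·Ne·μ_g.

"Variability in heterozygosity" is not a standardised statistic; here it is
the sample SD (n−1) of per-window heterozygosity over full-width 25-kbp
windows with ≥ 80 % of sites genotyped — the same support rule the ROH
caller uses, so one windowing scheme serves both. The coefficient of
variation is emitted alongside. Partial terminal windows are excluded from
the SD (unequal support inflates it) but included in genome-wide
heterozygosity.

## ROH calling

A 25-kbp window is in a run of homozygosity when it contains no heterozygous
genotype and ≥ 80 % of its sites are genotyped (≥ 20 kbp genotyped).
Consecutive qualifying windows merge into maximal segments; a window failing
any rule terminates the run, including data-poor windows (conservative; a
`bridge_missing` option lets them be skipped instead). Partial terminal
windows never qualify.

Both ROH counts are reported: merged segment count (primary, `roh_n`) and
qualifying-window count (`roh_windows_n`). Total length equals width ×
window count identically, so length and window count are perfectly
correlated by construction. The merged segment count, by contrast,
*saturates*: when most of a genome qualifies (the smallest default islands
put ~80 % of windows in ROH), runs fuse and the count stops tracking total
length. Correlation claims between "number" and "length" of ROH therefore
hold exactly for window counts and only in the non-saturated regime for
segment counts.

## ERV insertion polymorphisms

MELT-style calls are consumed, not produced. Post-processing: (i) calls from
different ERV families whose positions chain within ±100 bp (single-linkage,
applied transitively) are collapsed to the call with the lowest consensus
divergence, with deterministic tie-breaks (divergence, then position, then
family name); (ii) calls with ASSESS ≥ 3, a non-PASS FILTER, or > 25 %
missing sample genotypes are removed (missingness is counted over sample
genotypes, not alleles); (iii) homozygous non-reference genotypes are counted
per individual as raw counts. Overlap resolution and filtering commute only
when each overlap cluster passes or fails the filters as a whole; the
pipeline fixes the order as resolve-then-filter.

## Demographic summaries

MSMC2 output has time boundaries in per-site mutation units and coalescence
rates λ in coalescent units. With μ_g = μ_year · g (defaults
μ_year = 3.16×10⁻⁹ /site/yr, g = 1 yr):

    t_years = (scaled_time / μ_g) · g        Ne = 1 / (2 · μ_g · λ)

Round-tripping is exact to machine precision and is tested to 1e-12.
`recent_ne` is the epoch containing the present (the noisy first epoch can
be skipped by flag; no exclusion is applied by default). `harmonic_mean_ne`
is the time-weighted harmonic mean over the last 200,000 years, epochs
clipped at the horizon and the final epoch treated as unbounded; a coverage
gap is an error, not a silent extrapolation. The harmonic mean is the
summary that governs long-term diversity because drift compounds as 1/Ne.

## Statistics layer

Area enters all models as log10(km²). Simple regressions are OLS with
Pearson r and two-sided p (optionally refit excluding named islands, both
fits reported); Holm-adjusted p-values are emitted alongside the raw ones.
Correlations use pairwise-complete cases; entries with a constant column or
< 3 cases are flagged undefined rather than silently NaN-propagated. LASSO
uses scikit-learn's parameterisation (1/2n)‖y−Xβ‖² + λ‖β‖₁ with predictors
standardized internally, the response centred but not scaled, and λ chosen
by leave-one-out cross-validation — with ~8–16 islands, k-fold splits are
too coarse (k-fold with a seed is available). Coefficients are reported on
the standardized-predictor scale; the selected set is the nonzero support.

## Synthetic archipelago

The generator emulates the study conditions end to end:

* **Islands**: 8 islands with log-spaced areas 10–4000 km²;
  Ne = 100·area¹ (so Ne spans 1e3–4e5). The density constant and exponent
  are configurable; exponent < 1 would emulate density compensation.
* **Genotypes**: the diploid genome (default 2 × 500 kb; 40 full 25-kbp
  windows per individual — enough to resolve the diversity/ROH gradient at
  desk scale) is partitioned into tracts with independent Exp(50 kb)
  lengths; each tract draws a pairwise TMRCA T ~ Exp(mean 2Ne) generations
  and heterozygous sites fall as Poisson with per-site probability
  min(2·μ_g·T, 1). Expected heterozygosity is exactly 4·Ne·μ_g, and
  low-TMRCA tracts create multi-window ROH. Per-site quality failures
  (missing 2 %, QUAL 2 %, GQ 3 %, low DP 2 %, high DP 1 %) are planted at
  disjoint recorded positions so the filter ledger can be checked exactly.
* **ERVs**: 500 loci per archipelago drift independently per island by
  discrete Wright–Fisher binomial sampling (genic selection s = −0.001
  against the insertion, q₀ = 0.25, 1000 generations). Populations above
  10,000 are simulated at the cap with s rescaled to conserve 2·Ne·s.
  Planted extras fail each post-filter and create multi-family overlaps.
* **Trajectories**: constant-Ne trajectories discretised into 16 log-spaced
  epochs, written in MSMC2's scaled format by the exact inverse of the
  unscaling, with log-normal λ noise (sd 0.05).

What the generator does **not** emulate: recombination-driven correlation
between adjacent tracts (tracts are independent), gene flow between islands,
linked selection, sequencing-error het inflation, or reference bias. Passing
tests therefore demonstrate the pipeline's arithmetic and filtering logic
and the direction of diversity–area relationships under drift; they do not
validate coalescent-HMM inference or MELT discovery on real data.

## Monte-Carlo error and test sizing

Under the tract model the per-island CV of estimated heterozygosity is
√(3/n_tracts) (tract length and TMRCA are both exponential), i.e. ~39 % at
1 Mbp. Tests sized accordingly:

* θ-recovery on a 20 Mbp constant-Ne genome uses the analytic SE
  √(θ/G + 3(L̄/G)θ²) and a 3-SE band;
* the slope-near-unity recovery check runs the generator's array path at
  100 Mbp per island (2000 tracts, CV ≈ 4 %), where a [0.9, 1.1] band is a
  meaningful unbiasedness test;
* the default archipelago's het ~ log-area Pearson r has a ceiling of
  ≈ 0.81 regardless of genome size, because het is proportional to area and
  hence exponential in log-area; the end-to-end check asserts r > 0.7.

Seeds: one master seed per archipelago; per-island, per-component streams
derive from it through `numpy` SeedSequence spawn keys, making builds
byte-identical under a fixed seed.

## Numerical conventions

Divergence ties in overlap resolution, window reasons (partial → support →
het) and CV fold order are all deterministic. Zero genotyped sites, empty
trajectories, coverage gaps, non-positive λ or areas, and unsorted inputs
raise errors rather than returning sentinel values.
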