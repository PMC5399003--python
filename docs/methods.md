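# Methods

## Scope and model

`sweepscan` locates candidate selective sweeps between two subgene pools of
an inbred diversity panel by scanning per-SNP differentiation and diversity
along a genetic map. Everything operates in centimorgan coordinates: the
package assumes a consensus linkage map (SNP → linkage group + cM), not a
physical assembly. All statistics work from allele observation counts under
a simple counting convention: a non-missing diploid call contributes two
observations, a heterozygous call one of each allele, a missing call none.

### Per-site statistics

Nucleotide diversity at a biallelic site is π = 1 − Σᵢ nᵢ²/n², the
probability that two allele observations drawn with replacement differ.
Its finite-sample maximum is 0.5 (balanced counts).

Differentiation uses an nⱼ²-weighted estimator robust to unequal
subpopulation sizes,

    F_ST = 1 − (Σⱼ nⱼ² πⱼ) / (π_pooled · Σⱼ nⱼ²).

Two deliberate numerical choices:

- **No clamping.** The estimator can be slightly negative when weighted
  within-pool diversity exceeds pooled diversity (e.g. allele counts (0,5)
  vs (1,12) give −0.18). Raw values are kept because clamping would bias
  window means and the bootstrap null upward.
- **Genomic-mean substitution.** Where the pooled site is monomorphic the
  ratio is undefined; such sites receive the arithmetic mean of all defined
  per-site values of the same contrast, computed once genome-wide (not per
  linkage group), and are flagged `substituted`. The π ratio is *not*
  substituted: windows with zero smoothed π₂ have an undefined ratio and are
  excluded from ranking, because a substitution rule for ratios would have
  to invent a scale.

Under a symmetric island model with divergence parameter F and
subpopulation weights wⱼ = nⱼ/n, the genome-wide mean of this estimator is
**not** F: both numerator and denominator scale with site diversity, and
the expectation of the aggregate ratio is m = F(1−s)/(1−F·s) with
s = Σ wⱼ². For two pools of 79 and 99 lines, s ≈ 0.506, so a true F = 0.25
yields a mean per-site value near 0.12–0.14. `estimate_divergence_f`
inverts this relation on the ratio-of-sums aggregate
(F̂ = m/((1−s) + m·s)), which is free of the per-site Jensen bias and
recovers the simulation parameter to well within ±0.03 at 5000 SNPs. Two
genome-wide aggregates are therefore exposed: the arithmetic mean of
per-site values (the default summary) and the ratio-of-sums, selectable in
`genomewide_summary`.

### Windows, smoothing and the bootstrap null

Windows are 0.15 cM wide and advance in 0.03 cM steps (defaults; on a
630 Mb genome with an 837.11 cM map these correspond to roughly 113 and
23 Kb). Window centres run from each linkage group's first SNP position to
at or past its last; spans are half-open [c − w/2, c + w/2). The default
kernel is uniform (the unweighted mean of member sites); a truncated
Gaussian kernel with σ = window/3 is available for users who prefer
distance-weighted smoothing. Empty windows carry no value.

Significance uses a resampling null stratified by window SNP count k: for
each k, `n_boot` replicates are drawn, each the mean of k per-site values
resampled with replacement from the genome-wide pool (for the π ratio, k
(π₁, π₂) site pairs are resampled and the ratio of means is formed).
Replicates are banked per k and shared by all windows with that k, which
makes p-values invariant to window order; the whole draw sequence is fixed
by one seed. The p-value is the add-one upper-tail estimator
p = (1 + #{replicate ≥ observed})/(1 + n_boot), so p is never zero and
p ≤ α at α = 1 for every window. The default n_boot is 10⁶; tests and the
acceptance script run 10⁴, which changes the p granularity but not the
calibration (Kolmogorov–Smirnov distance from uniformity under
exchangeability ≈ 0.02–0.04 at 500 windows). Both statistics are tested
upper-tail only: sweeps in the bottlenecked pool raise F_ST and raise
π₁/π₂; no multiple-testing correction is applied beyond the raw α = 0.05
threshold, matching standard practice for this scan family.

Significant windows that overlap or abut on a linkage group merge into
regions. A region's span is the union of member window spans clipped to the
group's SNP extent; since "region length" could equally be read as the
centre-to-centre distance of the first and last member windows, both totals
are reported (`window_extent`, `center_span`). Genome fractions divide by
an explicit total map length — never a hard-coded constant, because
different map versions disagree at the percent level.

### Trait-locus coincidence

Association hits on the same linkage group chain into LD-block clusters
when consecutive map distances are strictly below 2 cM. A qualitatively
mapped gene/QTL coincides with a region when its tagging SNP lies inside
the half-open region span; a GWAS hit coincides when the closed block
[cm − 2, cm + 2] overlaps the region, touching included. A locus tagged by
several SNPs counts as coincident if any tag falls in a region. Loci mapped
on a different map than the scan's must be lifted to scan coordinates
before input; the package does no between-map projection.

## Synthetic panel generator

The generator emulates the data regime the scan was designed for: two
diverged pools of essentially homozygous lines (79 and 99 by default),
~27 500 biallelic SNPs spread uniformly over 11 linkage groups of 76.1 cM
(≈837 cM total), ~2% residual heterozygosity, ~3% missing calls.

Frequencies follow a Balding–Nichols model: ancestral p ~ U(0.05, 0.95)
(array SNPs are ascertained away from rare variants), subpopulation
frequencies Beta-distributed with mean p and variance F·p(1−p). Pool 1
uses `background_F = 0.26` everywhere. Pool 2 models a founding
bottleneck: after its Balding–Nichols draw, frequencies are pushed toward
the nearer fixation boundary by `pop2_diversity_loss = 0.65`. These two
defaults were calibrated once, jointly, so that the realized panel shows
mean π₁ ≈ 0.27 and π₂ ≈ 0.135 (a better-than-twofold contrast with the
bottlenecked pool near 0.13, the regime of interest); the residual-het
floor (~0.015 of π) is part of that calibration. With the estimator
expectation above, the realized genome-wide mean F_ST is ≈ 0.20
(ratio-of-sums ≈ 0.30) — under this model family the divergence parameter,
the π contrast and the mean per-site F_ST cannot be dialled independently,
and the π contrast was given priority.

A planted sweep acts on pool 2 only (pool 1 keeps background divergence and
diversity — a sweep in one pool should not erase the other's variation).
Inside a sweep span, pool 2's pre-sweep frequency is drawn at `sweep_F`
(default 0.5) and then pushed toward fixation of a *swept allele* that is
the ancestrally minor allele with probability 1 − p, by the sweep's
`diversity_loss` (default 1.0, a hard sweep). Favouring the rarer
(putatively derived) variant is what makes planted sweeps strongly
divergent as well as diversity-depressed: pushing toward the *nearer*
boundary instead would co-fix the allele already common in pool 1 about
half the time and produce sweeps that are nearly invisible to F_ST. With
these defaults and the scaled-down test conditions (2000 SNPs on two 20 cM
groups — about 7.5 SNPs per 0.15 cM window — one 4 cM sweep per group,
α = 0.05, n_boot = 10⁴), the scan recovers 83–89% of planted F_ST sweep
windows and 94–99% by π ratio, with 2–6% of called F_ST region length
outside the planted spans, stably across seeds.

What the generator does **not** emulate: linkage disequilibrium between
sites (frequencies are independent given the map position, so LD-decay
curves on synthetic panels reflect only structure-driven covariance, not
physical linkage); genotyping error; ascertainment bias beyond the uniform
ancestral-frequency floor; admixed individuals (the `excluded` label is
supported but not generated); and allele-frequency correlation along
sweeps' flanks (soft sweeps, partial sweeps with haplotype structure).
Passing recovery tests therefore demonstrates the statistical machinery on
idealized panels, not performance on real LD-structured data.

At genome scale the planted sweeps occupy ~2% of the map while the α = 0.05
pooled-null threshold flags ≈5% of windows by construction, so
genome-scale false-region length is dominated by the background call rate;
the recovery figures above are meaningful at the scaled-down conditions
where sweeps occupy a fifth of the (tiny) genome and the inflated pool
suppresses background calls. This is a property of the pooled bootstrap
null itself, worth remembering when interpreting real scans.

## Problem sizes and runtime

Tests use the scaled-down generator (2000 SNPs, 2 linkage groups, n_boot
10³–10⁴); the full suite runs in a few seconds. The acceptance script runs
the full-scale default panel (27 500 SNPs, 11 groups, ~28 000 windows,
n_boot 10⁴) plus the recovery and calibration experiments in well under a
minute on one CPU. n_boot = 10⁶ (the production default) is linear extra
cost in the bootstrap stage only.

## Known limitations

- The F_ST estimator's dependence on subpopulation sizes means its genome
  mean is not comparable across panels with different n₁/n₂ without the
  model-based correction in `estimate_divergence_f`.
- Bootstrap p-values inherit the pooled null's conservatism/liberality
  when the genome-wide pool itself contains strong signal (see above).
- Region boundaries are window-resolution (±half a window), and window
  occupancy k varies with local map density; sparse map regions yield
  noisy windows with small k.
- The distance matrix and LD routines are quadratic in samples and in SNPs
  per linkage group respectively; they are meant for panel-scale data
  (hundreds of samples, tens of thousands of SNPs), not biobank scale.
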