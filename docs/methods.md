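# Methods

This note documents the models and procedures implemented in
`rohscan`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and data model

All internal coordinates are 0-based half-open `[start, end)`;
conversion to VCF/PLINK 1-based-inclusive and BED conventions happens
only in the readers and writers. Genotypes are coded 0 (hom-ref),
1 (het), 2 (hom-alt) with a distinct missing code that is never
imputed — every estimator states its own missing-data handling
instead. All computations are single-threaded and deterministic given
a seed.

## ROH detection

A run of homozygosity is a maximal interval of consecutive SNPs
satisfying, jointly: at most `max_het` heterozygous calls (default 3)
and `max_missing` missing calls (default 5); no internal adjacent-SNP
gap ≥ `max_gap_bp` (default 1 Mb); at least `min_snps` SNPs (default
50); bp length ≥ `min_length_bp` (default 500 kb, suppressing
LD-driven short runs); and density ≤ `max_density_kb_per_snp` (default
50 kb/SNP, PLINK's kb-per-SNP semantics). A segment's span runs from
its first SNP to its last SNP + 1, so the `.hom` export ends exactly
at the last SNP position.

Two modes are provided because the het/missing allowances admit two
readings. **Exact mode** (default) applies them per segment — the
literal reading — and is defined as: all intervals satisfying every
constraint whose one-SNP extensions violate some constraint, resolved
into disjoint segments greedily by earliest start, then longest. This
definition admits a brute-force oracle (enumerate all O(m²)
intervals), and the test suite asserts equality against it on hundreds
of randomized instances, including instances where the density
constraint binds non-monotonically. The implementation uses a
two-pointer scan per gap-free block; when every internal gap is ≤
1000·`max_density` bp the density constraint provably cannot bind and
the scan is linear, otherwise a per-left-endpoint vectorised
enumeration preserves exactness. **Window mode** reproduces the
scanning-window heuristic of PLINK-style callers: allowances per
window of `window_snps` SNPs, per-SNP acceptable-window fraction ≥
`window_hit_threshold` (default 0.05), gap splitting, then the final
segment filters. The two modes can legitimately differ on noisy data;
exact mode is the default because it is oracle-verifiable.

`sensitivity_grid` supports one-factor-at-a-time robustness analysis
(count, mean size, runs per individual, mean F_ROH per class as the
varied parameter moves), mirroring how detection parameters are tuned
in practice.

## Length classes

Segment lengths (kb) are fitted with a three-component
unequal-variance univariate Gaussian mixture by EM: best of `n_init` =
10 initialisations (one deterministic quantile start + 9 seeded random
restarts), tolerance 1e-6 on the relative log-likelihood change,
≤ 500 iterations, with a variance floor of (1e-6 · data sd)² against
component collapse. The observed-data log-likelihood is asserted
non-decreasing at every iteration — EM's defining property doubles as
an internal correctness check — and responsibilities are checked to
sum to 1. Components are sorted by mean; each class boundary is the
point where the posterior-most-probable component switches, obtained
as the root of the weighted-density equality (a quadratic in x)
between the two means, with a fine-grid scan fallback for the rare
no-root-in-range geometry. Fitting is on raw kb, matching how kb-scale
boundary values are conventionally reported; a `log_scale` option
exists for robustness comparisons. A length exactly equal to a
boundary is assigned to the upper class, so "short" is a strict upper
bound. Model-count selection (BIC over K) is deliberately out of
scope; K = 3 is the analysis convention the classes exist to serve.
Unequal variances are assumed since the three modes differ strongly in
spread; an equal-variance structure was not imposed.

## Genomic inbreeding

All allele frequencies are estimated from the analysis panel itself,
as the reference tools (PLINK `--het`, GCTA `--ibc`) do. This is a
deliberate, documented choice: cross-population frequency bias —
negative F_HOM or inflated F_GRM in admixed or diverged groups — is a
property of these estimators that users of the package should be able
to reproduce, not a defect to be corrected away.

* `F_ROH` = Σ segment bp / Σ autosome bp (per-class variants restrict
  the numerator). Splitting a segment into abutting pieces leaves it
  unchanged; overlapping segments within an individual are an error.
* `F_HOM` = (O_hom − E_hom)/(m − E_hom), with
  E_hom = Σᵢ (1 − 2pᵢ(1−pᵢ)·nᵢ/(nᵢ−1)) over the individual's
  non-missing sites; sites with fewer than 2 non-missing alleles are
  excluded, and m = E_hom is flagged as undefined rather than divided.
* `F_GRM` = meanᵢ[(x − 2pᵢ)²/(2pᵢ(1−pᵢ)) − 1] and
  `F_UNI` = meanᵢ[(x² − (1+2pᵢ)x + 2pᵢ²)/(2pᵢ(1−pᵢ))], over the
  individual's non-missing sites that are polymorphic in-panel
  (monomorphic sites would divide by zero; they stay in Ho, which is a
  plain proportion).
* Ho = het/non-missing calls per individual; He = mean over SNPs of
  2p̂(1−p̂) per group. Spearman correlations use ranked Pearson with
  average ranks and the t approximation (n − 2 df) for p-values —
  adequate at the sample sizes involved; exact permutation p-values
  would change nothing material.

Under Hardy-Weinberg simulation, F_GRM and F_UNI are centred near zero
(the tests allow the small negative O(1/n) finite-sample pull from
estimating p in-panel); on planted inbreeding gradients F_ROH tracks
the true autozygous fraction at rank correlation ≥ 0.95 and opposes
observed heterozygosity at ≤ −0.9.

## ROH-based structure

Segments are recoded into a binary individuals × regions matrix over
the *atomic partition*: the genome is cut at every distinct in-scope
segment start/end, and an entry is 1 iff the individual's segment
fully covers the region. Because regions are atomic, "fully covers"
equals "overlaps", so the coding is unambiguous and independent of any
arbitrary windowing — the unique such choice, and the reason it was
preferred over pooled-overlap or fixed-window codings (either of which
an upstream pipeline might have used; results can differ, which is
documented rather than hidden). Columns constant across individuals
are flagged but retained.

PCA mean-centres columns without variance scaling: entries are segment
indicators, not allele counts, so allele-frequency-based scaling has
no meaning here. Scores come from the top-k singular directions with a
deterministic sign convention (first largest-|loading| entry positive,
tie-broken by index within round-off). `export_structure_inputs`
writes a transposed 0/1 pseudo-genotype coding plus a region map so
external clustering/admixture tools can be applied downstream.

## Hotspot permutation test

The scan statistic is the SNP-wise ROH frequency within a group:
carriers at each SNP position divided by the full group size (not just
ROH carriers — the flagged alternative denominator exists but makes
frequencies incomparable across groups with different ROH prevalence).
Coverage is evaluated at SNP positions, not per-bp, because SNP-wise
frequency is the unit the downstream merge rule ("adjacent significant
SNPs") operates on.

The null hypothesis is uniform random placement of each individual's
runs along their chromosomes. Each of `n_perm` permutations (default
10,000) independently re-draws every segment's start uniformly on
[0, chrom_len − length] — same individual, same chromosome, same
length, so per-individual counts and lengths are conserved exactly —
and records the genome-wide maximum frequency. Displaced segments of
one individual may overlap; the individual still counts once per SNP.
Independent displacement (rather than sequential non-overlapping
packing) was chosen because it is the minimal model consistent with
"redistribute preserving lengths and counts", and it matches the
generative model used in the calibration studies; a non-overlapping
variant would be slightly more conservative.

The genome-wide threshold is the order statistic at rank
⌈(1 − α)·n_perm⌉ of the null maxima (α default 0.01 → the 99th
percentile). A SNP is significant iff its observed frequency
*strictly* exceeds the threshold — conservative under the heavy ties
that small groups produce, where frequencies live on a grid of
multiples of 1/n. Per-SNP FWER-adjusted empirical P uses the standard
(1 + #{null ≥ obs})/(n_perm + 1) estimator, never zero. Consecutive
significant SNPs merge into hotspots; an optional `merge_gap_bp`
bridges sub-threshold gaps, off by default since "adjacent" is taken
literally.

Implementation note: permutations are processed in batches with a
composite-key trick (offset intervals by owner × (m+1)) so per-
individual interval union, coverage and maxima for a whole batch
reduce to one sort plus cumulative operations; the test suite checks
this machinery against a direct per-SNP set-counting reference and
against exhaustive enumeration on a toy genome.

## Windowed selection statistics and overlap

Sliding windows default to 50 kb with 20 kb steps, truncated at
chromosome ends. Aggregations: proportion of |iHS| ≥ 2 (windows with
< 10 SNPs dropped — the SNP floor applies to this statistic only),
max CLR, mean XP-EHH/F_ST. π is computed natively:
π_site = n/(n−1)·2p̂(1−p̂) (the unbiased average pairwise difference),
summed per window and divided by the window's (possibly truncated) bp
length; the tests verify exact agreement with an explicit
pairwise-allele-difference enumeration. Windows are z-standardised per
statistic and retained when the one-sided normal tail probability
falls below α = 0.01 — upper tail for iHS/CLR/XP-EHH/F_ST, lower for
π (sweeps deplete diversity); the tail is configurable because the
z-test formulation admits either convention. Retained windows merge
into maximal intervals. A hotspot is "supported" by a method iff some
retained interval intersects it (half-open: touching ≠ overlap), and
the summary reports the percentage of hotspot SNPs inside ≥ 1 / ≥ 2
methods' interval unions.

## Synthetic panels

`simulate_panel` emulates the statistical structure the analyses
assume: exponential (Poisson-process) inter-SNP spacing around a mean
(default 10 kb); per-site allele frequencies uniform on [0.05, 0.5]
(post-MAF-filter panel); HWE background genotypes; per-individual
Poisson tract counts with log-normal lengths per class (default
medians 600/1,200/3,000 kb — the three-modal structure the mixture
model is meant to recover — with log-sds 0.10/0.125/0.20); genotypes
inside tracts forced homozygous with the allele drawn by site
frequency, then flipped to het at `het_error_rate` (default 1e-3, a
WGS-call-error scale that keeps expected hets per 100-SNP tract well
under the detection allowance); genome-wide missingness (default
1e-3); hotspot islands as fully covering tracts in a carrier fraction
of a group or of the panel; optional per-individual target autozygous
fractions (topped up with medium tracts until the union reaches the
target); and optional logistic covariate→allele-frequency links for
frequency-climate analyses. Ground truth (tracts, islands with
realized carriers, per-individual realized autozygous fractions,
planted frequencies) is recorded exactly. Tract placement is uniform
and tracts of an individual may overlap (unions are used for
fractions) — deliberately the same placement model as the permutation
null, so calibration tests are internally coherent.
`simulate_null_segments` generates segment-level datasets directly
from that placement model for calibration and power studies.

What the generator does **not** model: linkage disequilibrium,
recombination maps, mutation, pedigree structure, or selection
dynamics. Short-ROH-from-LD phenomena are emulated only through
planted short tracts. Consequently, passing tests demonstrate
correctness of the algorithms under their stated null/alternative
models — FWER control when placement is genuinely uniform, recovery
when tracts are genuinely planted — not robustness to the spatially
heterogeneous ROH backgrounds real genomes produce (centromeric
deserts, recombination coldspots), where the uniform-placement null is
known to be approximate.

## Calibration and problem sizes

The acceptance study (`scripts/acceptance.py`) estimates the hotspot
caller's family-wise error rate on 500 null datasets of 25 individuals
× 5,000 evenly spaced SNPs on one 50 Mb chromosome, 20 log-normal runs
(median 800 kb, log-sd 0.5) per individual, thresholds from 1,000
permutations at α = 0.01 — sizes chosen so the full study runs in
minutes on one CPU while keeping ≥ 100 SNPs per typical run. The
estimate is expected at or below the nominal 0.01; the discreteness of
frequencies (multiples of 1/25) plus strict-inequality calling makes
the procedure conservative, often strongly so. The test suite runs the
same study, plus power/localisation (a 90%-carried island over random
background, 100 replicates) and the qualitative threshold-vs-sample-
size relationship (thresholds fall as group size grows at equal
per-individual burden).

## Known limitations

* The uniform within-chromosome placement null ignores SNP-density and
  recombination heterogeneity; on real data the threshold is best
  interpreted per group and genome build.
* Exact-mode and window-mode detection differ by design on data with
  interior het/missing clusters; cross-tool comparisons should state
  the mode.
* F estimators inherit in-panel frequency bias by construction (see
  above).
* The binary-matrix recoding is one of several defensible conventions
  (atomic partition vs pooled overlaps vs fixed windows); PCA patterns
  are comparable only within a convention.
* BCF/indexed VCF, phased haplotypes, sex chromosomes, and imputation
  are out of scope.
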