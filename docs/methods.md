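# Methods

`popsweep` implements a frequency- and haplotype-based scan pipeline for
detecting population-specific selection and cross-population introgression
in multi-sample SNV data, together with the population-structure layer
(distances, trees, PCA) needed to interpret it. This note documents the
statistical model behind each stage, the defaults and why they were chosen,
the synthetic-data generator's assumptions, and known limitations.

## Selection scan: pairwise Fst and the d_i statistic

Population differentiation at a single biallelic SNV is measured with
Hudson's Fst estimator in ratio form,

    Fst = [ (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1) ]
          / [ p1(1−p2) + p2(1−p1) ],

where p_k is the alternate-allele frequency and n_k the number of called
allele copies in population k. Hudson's estimator was chosen as the default
because it is stable per SNV and does not weight by within-population
sample sizes; a Weir–Cockerham variant (allele-frequency form, no
within-individual component) is exposed via `estimator="wc"` for
sensitivity analysis. Negative per-SNV values are retained — clamping at
zero would bias the genome-wide moments used next. Sites where either
population has ≤ 1 called allele copy, or where both populations are
monomorphic for the same allele (zero denominator), are undefined and
propagate as NaN.

Lineage-specific differentiation in a focal population i is summarized by

    d_i = Σ_{j≠i} ( Fst^ij − E[Fst^ij] ) / sd[Fst^ij],

the sum over comparison populations j of the z-standardized pairwise Fst.
The moments E and sd are computed over all SNVs with defined Fst on the
chromosomes listed in the `GenomeLayout`; restricting the layout to
autosomes therefore excludes sex chromosomes by construction. The sd uses
the population (ddof = 0) convention, so genome-wide z-scores have mean 0
and sd 1 exactly.

Per-SNV d_i is averaged in non-overlapping 100-kb windows tiling each
chromosome from coordinate 0; the trailing partial window is retained.
Windows with fewer than `min_snvs` (default 10) defined values are masked —
a mean over very few SNVs is dominated by single-site noise. Candidate
sweep regions are the windows strictly above the empirical (1 − tail)
quantile of unmasked window values (tail = 0.01 by default); adjacent
selected windows merge into regions scored by their maximum window value.
Strict inequality means ties at the threshold are excluded, matching the
convention of reporting regions *above* a printed cutoff.

## ΔCLR

SweepFinder2 composite-likelihood grids are ingested (not recomputed: the
CLR likelihood model is that tool's own contribution), averaged per window
— grids need not align with window boundaries — and combined as

    ΔCLR = CLR_focal − (CLR_other1 + CLR_other2) / 2.

A window lacking grid points in any of the three tracks is masked. No CLR
significance cutoff is imposed; it is left as a user parameter.

## ΔAF, breed-specific SNVs, enrichment

Per-population alternate-allele frequencies count called allele copies
only; missing genotypes are excluded, never imputed, and a population with
zero called copies at a site is undefined there. The differentiation
statistic is

    ΔAF = | AltAF_focal − (AltAF_other1 + AltAF_other2)/2 |  ∈ [0, 1].

Fixed breed-specific SNVs are sites with AltAF_focal > 0.95 and AltAF
< 0.05 in *each* comparison population (strict inequalities as printed
thresholds; a pooled-frequency mode is available behind a flag). Sites
passing with frequencies exactly (1, 0, 0) have ΔAF = 1 identically.

ΔAF values are binned in steps of 0.05 — bin b covers [0.05·b, 0.05·(b+1)),
with the last bin closed at 1.0 so the bins partition [0, 1]. Enrichment of
a functional class within a ΔAF range uses a 2×2 table {in class, not in
class} × {ΔAF in range, outside} and a Pearson χ² with 1 df without
continuity correction; direction is reported as the odds ratio. The 2×2
class-vs-genome construction is one defensible reading of "χ² enrichment of
bins within classes"; a comparison against a uniform bin expectation would
be the alternative. A table with a zero margin is skipped with a flag
rather than tested. Bonferroni adjustment over the tested classes is
available behind a flag; no multiple-testing procedure is applied by
default.

## Introgression: IBD segments and nIBD

For populations A and B with n_A and n_B diploid samples, every
cross-population haplotype pair is a potential sharing event:
tIBD = (2n_A)(2n_B). Haplotype pairs (not individual pairs) are the default
unit because the statistic counts *haplotypes* IBD; an individual-pair mode
is exposed for sensitivity. In fixed 10-kb bins,

    nIBD = cIBD / tIBD,

where cIBD counts pairs having an IBD segment overlapping the bin by at
least 1 bp (a pair counts once per bin regardless of how many of its
segments touch it). The ≥1-bp rule matches the binary shared-haplotype
framing; midpoint or proportional-overlap rules are alternatives the data
model would also support. Introgressed regions are bins strictly above the
empirical 95% quantile (or above a user-supplied fixed cutoff, mirroring
published fixed thresholds), merged when adjacent, scored by mean nIBD.

The built-in segment caller is a deterministic run-based substitute for
LD-aware HMM callers: for each cross-population haplotype pair it emits
maximal runs of consecutive identical alleles (allowing `max_mismatch`
mismatches per run, default 0) spanning at least `min_length` bp (default
150,000), bounded by the first and last matching SNV. The default
`min_length` is set analytically: with ~1 SNV/kb and a per-site background
match probability around 0.65 between unrelated haplotypes, a run of ~150
consecutive matches has probability ≈ 10⁻²⁸ per start position, so the
expected number of background segments genome-wide is negligible while
copied tracts of 200 kb (identical by construction) always qualify. The
caller requires phased input; precomputed segments from an external caller
can be supplied as TSV instead.

## Population structure

* **IBS distance**: d(a, b) = mean over jointly called sites of
  |g_a − g_b| / 2; a pair with no jointly called site is an error rather
  than a silent 0. Population-level distances are means of cross-population
  individual distances.
* **Neighbor joining**: standard Saitou–Nei agglomeration (Q-matrix
  minimization, canonical branch-length formulas, trifurcating root at
  three nodes). Ties in Q are broken on the lexicographically smallest pair
  of node keys (a node's key is its smallest leaf label), making the result
  deterministic and input-order invariant. Negative branch lengths are kept
  internally and clamped to 0 only at Newick serialization, with the raw
  value logged.
* **GRM / PCA**: VanRaden's first method, G = ZZᵀ/m with
  z = (g − 2p)/√(2p(1−p)) and p the overall sample frequency; monomorphic
  or incompletely called sites are excluded. PCA takes the top-k eigenpairs
  of G; coordinates are eigenvector·√eigenvalue. Eigenvector sign is
  arbitrary, so tests compare up to sign.
* **Distance correlation**: Pearson correlation over the upper triangles
  of two distance matrices with a Mantel-style two-sided permutation
  p-value, p = (#{|r_perm| ≥ |r_obs|} + 1)/(B + 1), seeded. A parametric
  t-test option exists but is labeled naive: distance pairs are not
  independent.

## Synthetic data generator

The generator emulates the statistical structure the scan statistics
consume, not a full evolutionary history. Background differentiation
follows the Balding–Nichols model: ancestral frequency
p ~ Uniform(0.05, 0.95) per SNV (bounded away from 0/1 so monomorphic
sites do not dominate), population frequency
~ Beta(p(1−F)/F, (1−p)(1−F)/F) independently per population, haplotype
alleles ~ Bernoulli(population frequency) independently across sites.
Sweep regions overwrite in-region frequencies with configured focal /
non-focal targets — the differentiation end-state, not a selection
trajectory, is what the frequency statistics detect. Introgressed tracts
copy a randomly chosen donor haplotype into a seeded carrier subset of
recipient haplotypes. Functional classes are drawn from configured
proportions (defaults approximate a mammalian SNV composition: ~54%
intergenic, 30% intronic, ~8% exonic); an optional odds tilt concentrates
one class inside a ΔAF range.

Study conditions (scenario presets, fixed once):

* **sweep** (default `SimConfig`): one 10-Mb chromosome, 2,000 SNVs
  (100 windows of 100 kb), three populations ("MS" focal, "DU", "TB") of
  30 samples each, F = 0.1, one planted fixed-difference region at
  4.5–4.6 Mb with targets (1, 0).
* **introgression**: 10,000 SNVs on the same chromosome (the run-based IBD
  caller needs marker density that frequency scans do not), no sweeps, two
  200-kb MS→DU tracts (1.5–1.7 Mb, 7.0–7.2 Mb) at carrier fraction 0.5.
* **enrichment**: F = 0.2 and eight planted near-fixed sweep windows so
  the high-ΔAF range is populated (high-ΔAF SNVs concentrate in sweep
  regions in real data too), with a default odds-3 tilt of the intronic
  class inside ΔAF ∈ [0.8, 1].

All randomness flows from a single seeded generator in a fixed order, so a
fixed seed yields byte-identical VCF/manifest output.

What the generator does **not** model, and the corresponding limits on
what passing tests show: no linkage disequilibrium outside copied tracts
(so the IBD caller is exercised only by planted tracts, and LD-based
methods could not be validated here); no recombination map, mutation-rate
heterogeneity, demographic bottlenecks, or sequencing error; unphased and
missing-data paths are exercised by hand-written fixtures rather than the
generator.

## Numerical and degenerate-input conventions

* Empirical quantiles use linear interpolation (numpy default); with the
  strict ">" selection rule this selects ⌈tail·W⌉ windows on distinct
  values, fewer under ties at the threshold.
* NaN marks "undefined" throughout (Fst, ΔAF, masked windows); every
  consumer either propagates or explicitly excludes NaN, never treats it
  as 0.
* Zero sd of a pairwise Fst panel, all-masked window tracks, empty
  populations, asymmetric distance matrices and constant distance vectors
  raise errors naming the degeneracy instead of producing numbers.
* Interval coordinates are 0-based half-open internally; VCF (1-based
  points) and GFF3 (1-based inclusive) are converted at the I/O boundary.
  SweepFinder2 fractional grid locations are floored to integer base
  positions.

## Problem sizes

Tests and the acceptance script run on the scenario sizes above: 20-seed
replicate loops for recovery rates, 200 seeds at n = 400 SNVs for the
enrichment null calibration, 5,000 SNVs for the standardization check, and
8-taxon trees for neighbor joining. These sizes are large enough that every
recovery criterion is met with margin while the full suite runs in well
under a minute on one core.

## Known limitations

* The run-based IBD caller is not a replacement for HMM callers on real
  data, where genotyping error and low marker density break exact runs; it
  exists so the nIBD pipeline runs end-to-end and is labeled as a
  substitute in outputs. Use externally called segments when available.
* Per-SNV Fst with small samples is noisy; d_i inherits this and relies on
  window averaging. Window size and `min_snvs` should be scaled to marker
  density.
* The enrichment χ² treats SNVs as independent observations; LD between
  nearby SNVs inflates significance on real data. P-values should be read
  comparatively, not literally, in dense panels.
* `pca` eigendecomposes the full GRM (O(n³)); fine for hundreds of
  samples, not for biobank scale.
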