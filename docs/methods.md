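# Methods

`rsta` re-implements restriction-site tiling genotyping as a desk-scale,
fully synthetic pipeline: array tile design from a genome, simulation of
two-channel hybridizations for diploid individuals, polymorphism
identification and genotype calling from log ratios, and
population-genetic analysis of the resulting genotype matrices.  This
note records the models, the calibrations behind the defaults, and the
limits of what the synthetic data can show.

## The measurement model

A tile is a 50-bp probe centered on a 4-bp restriction recognition site
(TaqαI, `TCGA`).  Each individual's DNA is split into a digested fraction
(labeled Cy3) and an undigested control fraction (Cy5) and co-hybridized.
An allele matching the recognition site is cut, so it contributes weakly
to Cy3; an allele with a point mutation in the site escapes digestion and
contributes to both channels with a single-mismatch binding penalty; a
deleted allele contributes to neither.  The per-tile statistic is the
replicate-averaged log ratio `log2(cy5/cy3)`:

* homozygous cut — high log ratio;
* heterozygous — intermediate;
* homozygous uncut — low.

Polymorphic loci are identified across individuals by requiring a
log-ratio range above 0.7 together with more than one cluster in a
univariate Gaussian mixture (BIC-selected over 1–4 components); genotypes
at polymorphic loci are then assigned by fixed thresholds: below −0.6
homozygous uncut, −0.6 to −0.1 (closed interval; the boundary choice is
measure-zero) heterozygous, above −0.1 homozygous cut.  Indel loci are
detected separately from raw Cy5 intensities: 2–3 clusters with one
cluster mean below 50 (background-like) and one above 150.

## Hybridization simulator

The simulator (`rsta.hybsim`) is the package's synthetic-data generator
and defines the study conditions used throughout the tests: 2 populations
× 10 individuals, 2,000 cut-site loci by default, 24% polymorphic, 3% of
polymorphic loci carrying deletions, triplicate tiles, and multiplicative
log-normal intensity noise with CV 0.08 per channel and replicate — the
replicate consistency level reported for the platform.

Signal model per tile and allele (intensities in arbitrary fluorescence
units):

* full-match intensity `I0` drawn once per tile, uniform on [400, 700];
* additive background `b = 30`;
* mismatch binding decay `exp(-λ·m)` with `λ = ln(5)/4`, anchored so that
  four mismatches in a 50-mer cause an 80% intensity loss (and hence 8%
  sequence difference ≈ near-total loss);
* digested (cut) alleles retain `cut_binding = 0.30` of full binding in
  the Cy3 channel: sonication-then-digestion leaves fragment halves that
  still overlap the probe;
* deleted alleles bind with `deletion_efficiency = 0` in both channels;
* heterozygotes are additive half-doses of their two alleles.

Scanner gain normalization is modeled as a single per-array scalar on the
Cy3 channel making the slide-wide channel sums equal ("overall slide
count ratio equal to one"); Cy5 is untouched so the absolute indel
cutoffs (<50, >150) keep their scale.  All log ratios therefore shift by
one array-wide constant, whose size is set by the array composition: the
cut-site tiles (depressed Cy3) push the rescaling up, the equal-channel
control mass (non-cut, negative, positive tiles) pulls it down.

### Calibration of the defaults

`cut_binding`, the `I0` range and the default control fractions (non-cut
14%, negative 2%, positive 0.2% of the cut-site tile count at 10× gain)
were calibrated jointly — once, against the printed anchors of the
measurement model, not against test outcomes — so that the noise-free
post-normalization genotype clusters sit at approximately +0.55
(homozygous cut), −0.35 (heterozygous) and −1.0 (homozygous uncut):
inside the fixed calling bins, with the heterozygote centered in its
window.  Two constraints force this structure:

* a 4-bp-site mutation changes binding by the single-mismatch factor
  `exp(-λ) ≈ 0.67` in both channels, which fixes the heterozygote-to-
  uncut-homozygote distance at `log2((1+0.67)/(cut_binding+0.67))`;
* the additive background makes cluster positions drift with `I0`; the
  `I0` range is kept within ~1.75× so the drift stays below 0.1 log2
  units and the fixed thresholds apply to every tile.

With these defaults the simulated distances between adjacent cluster
centers are ≈ 0.65–0.9 log2 units and the replicate-averaged log-ratio
noise is ≈ 0.06–0.09 sd, giving the observed ≥ 99% genotype concordance
and ≥ 95% (typically ≈ 99%) polymorphic-locus sensitivity at default
noise, and exact calls at zero noise.

### Population model

Per-population allele frequencies follow the Balding–Nichols Beta model
around a uniform [0.05, 0.95] ancestral frequency.  The dispersion
parameter is calibrated as `θ = k·F/(k−1+F)` so that the target `fst_sim`
equals the expected equal-weight, k-deme multilocus G_ST of the true
frequencies (with k demes, G_ST = θ(1−1/k)/(1−θ/k), not θ itself).
Genotypes are binomial (Hardy–Weinberg) draws within populations.

## Signal processing

Replicates are averaged per channel before the ratio (robust to single
replicate dropouts); the replicate CV is computed on per-replicate
intensities (averaged over the two channels), matching how replicate-tile
consistency is quoted for the platform — a CV on the per-replicate log
ratios would be ill-scaled because the mean log ratio can be ~0.  Loci
whose across-individual mean Cy5 does not exceed the 95th percentile of
the negative-control Cy5 are masked as poor-binding (the cutoff is a
package choice; which channel the original analysis used is not
documented).

## Mixture model and calling

`fit_gmm_1d` is a hand-written, vectorized EM for univariate Gaussian
mixtures with component-specific variances: k-means++-style seeded
initialization, 10 restarts per component count, convergence tolerance
1e-8 on the log-likelihood, at most 500 iterations, and BIC
(−2·loglik + (3k−1)·ln n) selection over k = 1..k_max (default 4: three
genotype clusters are assigned more reliably when a fourth is allowed).
Component variances are floored at (0.2 × data sd)²; without a floor, EM
collapses components onto near-coincident points and the likelihood
spikes make BIC prefer spurious clusters (reference 1-D implementations
without such regularization select k = 1 on pure Gaussian samples only
~91–93% of the time in our trials; the floored fit reaches ≥ 95%).
`sklearn`'s `GaussianMixture` serves as an independent cross-check in the
test suite, not as the implementation.

Indel dosage is assigned from Cy5 cluster membership (low → 2 deletions,
intermediate → 1, high → 0).  Known identifiability limit: with only two
Cy5 clusters the high cluster cannot be distinguished between "one
deletion" and "no deletion" because the full-binding intensity is
tile-specific; homozygous deletions (< 50, background-like) are always
identified.  Loci with a deletion allele are also excluded from
log-ratio genotype accuracy accounting: a cut/deleted heterozygote is
physically indistinguishable from a cut/cut homozygote in the log-ratio
channel, which is precisely why indels are scored from Cy5.

## Population genetics

Per-locus F_ST is the allele-frequency form (H_T − H_S)/H_T with equal
population weights (H_i = 2p_i(1−p_i), H_S their mean, H_T at the pooled
mean frequency).  This plug-in estimator carries an upward sampling bias
of order 1/(2n) (~0.025 at 10 diploids per population); it is kept as the
default because it is the form the measurement model defines, and because
the bias cancels exactly in the permutation test (observed and permuted
values share the sampling design).  For parameter recovery against
simulations, `fst_table(..., corrected=True)` applies the Nei–Chesser
small-sample correction and `mean_fst(..., weighted=True)` the
H_T-weighted multilocus ratio; together they recover `fst_sim` within
±0.01 across {0, 0.003, 0.05, 0.2} at 20 individuals.

The panmixia test shuffles the 2n called allele copies per locus and
permutation and re-deals them into the populations; this is implemented
exactly as the hypergeometric draw of the first population's mutant
allele count, which vectorizes over permutations.  An individual-level
permutation mode is available as a sensitivity analysis.  The test is
calibrated: under panmixia the rank of the observed mean among permuted
means is uniform.

Hardy–Weinberg tests are 1-df chi-square against expected counts from the
sample allele frequency, Benjamini–Hochberg adjusted; tests with a
minimum expected count below 1 are flagged low-power.  The linkage screen
is a permutation chi-square on 3×3 genotype contingency tables — an
explicit simplification of an exact haplotypic linkage test, adequate for
screening but not a likelihood-based LD estimate.  PCA centers loci and
projects individuals (full SVD, deterministic up to sign); the
"top-F_ST" subset rule is mean + 2 sd of the genome-wide distribution.

## Tile design details

Coordinates are 0-based, half-open.  A 50-bp tile places 23 bp on each
flank of the 4-bp site; overlapping tiles are dropped symmetrically (both
members of a pair) so retention is order-independent; windows containing
N are never sites or tiles.  The uniqueness screen replaces an external
BLASTN step with an exact-seed, ungapped-extension alignment over both
strands: the seed length is `floor(L/(m+1))` where m is the maximum
number of mismatches a hit above the identity threshold can carry (k = 10
for 50-bp tiles at 90%), which guarantees by pigeonhole that the screen
finds every qualifying window — it is exactly equivalent to brute-force
sliding-window alignment, and is tested against one.  Non-palindromic
recognition motifs are supported by scanning both strands and
deduplicating positions.

## Problem sizes

Defaults used by the test suite and the acceptance script: 2,000-locus
arrays for concordance/sensitivity (≈ 48,000 genotype calls), 5,000 loci
per F_ST recovery point, 200 replicate null datasets × 500 permutations
for permutation-test calibration, 60 seeded trials per component count
for BIC selection, and 1 Mb of random sequence for the site-density
check.  These sizes put Monte-Carlo error well inside the asserted
tolerances while keeping a full run in minutes on one core.

## What the synthetic data do not show

The simulator reproduces the signal logic, noise level and composition
of a cut-site tiling array, but not: dye-specific bias, spatial artifacts
or scanner saturation; cross-hybridization between near-duplicate genomic
families; linkage between loci (loci are simulated independently, so the
linkage screen's null behavior is exercised but a positive LD signal is
not); or ascertainment structure in allele frequencies beyond the
Balding–Nichols model.  Passing tests therefore validate the estimators
and the calling logic under the platform's stated noise model, not the
wet-lab performance of the assay.
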