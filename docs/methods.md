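# Methods

`bgcscan` tests resequenced genomic regions for a fixation process that
favors strong (G/C) over weak (A/T) alleles — the population-genetic
signature of GC-biased gene conversion (BGC) — and scans the same regions
for completed selective sweeps.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Mutation classes and spectra

Every polarized change is classified by `classify_mutation`: weak-to-strong
(W2S: A/T ancestral, G/C derived), strong-to-weak (S2W), or OTHER
(weak-to-weak, strong-to-strong).  Classification needs an ancestral
allele; low-confidence (lowercase) ancestral calls are accepted and flagged
rather than dropped, while undetermined calls exclude the site.

The unfolded site frequency spectrum stores real-valued counts over derived
counts 1..n−1.  Reducing a spectrum from n to m chromosomes uses the
hypergeometric projection: class i of n contributes to class j of m with
weight C(i,j)·C(n−i,m−j)/C(n,m).  Mass landing on the monomorphic classes
j = 0 and j = m is discarded (a subsampled monomorphic site is not
observed), and the result is optionally renormalized to total one.  Two
aggregation conventions exist and both are exposed: per-site
renormalization (each input site contributes one unit; the default in
`build_spectrum`) and raw weights (each site contributes its probability of
remaining polymorphic; used for background spectra, because it commutes
exactly with projection).

Summary statistics follow the classical definitions: Watterson's
θ_W = S/a₁, π = Σ 2k(n−k)/(n(n−1)), θ_H = Σ 2k²/(n(n−1)), Tajima's D with
its published variance normalization, and the unnormalized Fay & Wu
H = π − θ_H.  With S = 0 both D and H are reported as missing, never as 0.
At n = 2 the variance constants vanish together with π − θ_W and D is 0 by
the closed form.

## The two fixation-bias tests

**MWU spectrum test** (`mwu_test`): a two-sided Mann-Whitney/Wilcoxon
rank-sum comparison of W2S versus S2W derived-allele frequencies (k/n per
site).  The reported offset is the Hodges-Lehmann shift (median of pairwise
frequency differences, W2S minus S2W) scaled to 22 chromosomes; positive
values mean W2S sites segregate at higher frequencies — an *ongoing*
fixation bias.  Method selection mirrors R's `wilcox.test`: exact null
distribution when there are no ties and the combined size is below 50,
otherwise the normal approximation with midranks, tie correction and
continuity correction.  A full midrank permutation mode (`method="exact"`)
exists for small samples with ties; its two-sided p is
min(1, 2·min(P(RS ≤ obs), P(RS ≥ obs))) over all C(m+n, m) assignments.

**MK-like test** (`mk_test`): Fisher's exact test (two-sided, by summation
of point probabilities no larger than the observed table's) on
{fixed differences, segregating sites} × {W2S, S2W}; OTHER is excluded but
reported.  The direction labels whichever class is enriched among fixed
differences (cross-products, so zero cells need no special-casing).  A W2S
direction indicates *historical* fixation bias.  Either test returns an
absent result (not p = 1) when a required stratum is empty.

**Cleaning filters**: segregating sites need ≥ 8 genotyped chromosomes, at
most two distinct alleles among reference/ancestral/sample alleles, and a
determined ancestral allele.  Candidate fixed differences must fall at
callable positions, carry a determined ancestral allele, and be absent from
the observed segregating sites and from a SNP catalog; the removed fraction
is reported.

**Masking scans**: a central mask of width w removes all data within w/2 of
the region center (widths 500/1000/5000/10000 bp by default); sliding masks
are 5 kb windows centered every 2.5 kb from the region start, giving
fifteen windows in a 40 kb region; `sliding_max` is the largest (least
significant) resulting p over non-missing masks.  Masks that empty a
stratum propagate a missing value.

**Association statistics** across regions: Fisher's exact p on
{MWU, notMWU} × {MK, notMK}; binomial and Poisson upper tails for the
count of regions significant on both tests at a supplied reference rate.
One reference value (a binomial p of 0.003 for 11/49 at rate
51/499) does not reproduce with a standard exact upper tail (which gives
0.0094); the standard tail is implemented.

Auxiliary tests: an exact conditional Hardy-Weinberg test (probabilities of
heterozygote counts given allele counts; p sums outcomes no more probable
than observed), a Poisson substitution-acceleration upper tail, and the
detectable-sweeps estimate (human-minus-chimp substitution excess times the
detectable fraction of the divergence time; with 206 human and 16 chimp
substitutions, 5 Myr divergence and a 200 kyr detection window this gives
at most 190 adaptive events and 7.6 detectable sweeps).

## Neutral calibration simulators

`simulate_neutral_region` draws a standard-coalescent genealogy (msprime;
haploid samples, recombination optional) and places mutations on branches
with probability proportional to branch length × covered genomic span —
conditioning on an exact S reproduces the classic fixed-segregating-sites
simulation behavior; θ-mode draws S ~ Poisson(θ/2 × total weighted length),
so E[S] = θ·a₁·L on a fully covered region.  Site positions land only in
covered intervals, reproducing partial probe coverage.  Classes are then
assigned by Bernoulli draws (`label_mutation_classes`), default fraction
2057/(2057+2114), the study-wide W2S:S2W composition.

`simulate_fixed_differences` evolves alignment columns on a three-taxon
star tree (human, chimp, outgroup from their common ancestor) under an HKY
model with configurable equilibrium GC content (default 0.41, a genome-wide
average) and transition/transversion ratio 2.  Default branch lengths:
0.005 substitutions/site for each ingroup terminal and 4× that to the
outgroup — round numbers of the right order for human-chimp-macaque; they
are configurable and only ratios matter for class composition.  Columns
are kept when human ≠ chimp and the outgroup matches exactly one of them
(unambiguous polarization), until the requested count (default 335).

`calibrate_test` wires these into the tests: MWU mode pairs 22-chromosome,
85-site coalescent replicates with Bernoulli labels; MK mode pairs 335
simulated fixed differences with 101 Bernoulli-labeled segregating sites
whose class probabilities equal the pooled fixed-difference ratios across
all replicates, so the null of equal ratios holds exactly.  Output: per
significance level, the fraction of replicates below it and the subset with
W2S direction.  Fisher's exact test is conservative on discrete tables, so
the MK fractions sit at or slightly below the nominal level.

## Forward Wright-Fisher BGC simulation

BGC is modeled as selection: each W2S mutation adds, and each S2W mutation
subtracts, |Normal(0, σ)| on the log-fitness of the haplotype where it
arises, with σ set so the mean population-scaled effect is 4NB (default
1.3).  Reproduction is haploid Wright-Fisher with multiplicative (genic)
selection and no recombination within the locus.  Mutations are
infinite-sites with independent Bernoulli class labels (default half W2S).
This independence is a substantive modeling choice: if classes were instead
read off a finite site's current weak/strong state, the stationary base
composition would equalize the W2S and S2W fixation fluxes *by definition*
and no divergence-based contrast could ever detect the bias.  With
independent labels, W2S mutations fix at ≈ e^{4NB} times the S2W rate,
which is the signal the MK test measures.

Mutation supply: the locus-wide scaled rate θ_locus =
L × scaled_bgc / bgc_mut_ratio (default L = 2000, ratio = 260, θ_locus =
10) was sized so a 50-chromosome sample yields segregating-site and
fixed-difference counts of the same order as a resequenced 40 kb region
(≈ 50 and ≈ 110 after shared substitutions are removed), and so the two
tests have the moderate per-replicate power regime in which the MK test is
significant in roughly a quarter of biased replicates and the MWU test in
roughly a tenth — with 4NB = 0 both collapse to their nominal 5% rate.
A neutral run keeps the mutation supply of the default biased run so the
two conditions are comparable.

Each replicate: burn-in 40·N generations from a mutation-free locus, an
instantaneous split, 6.5·4N further generations per descendant population,
then sampling (50 "human" chromosomes, 1 "chimp").  Observation is purely
sample-based: a mutation on 1..49 human samples is a segregating site; one
on all 50 but not the chimp chromosome — or on the chimp but on no human —
is a fixed difference; one on all 50 and the chimp is a shared substitution
and invisible.  Fixed differences are classified by their own labels, the
analogue of reliable outgroup polarization.

Implementation: with no recombination and no back-mutation the population's
history is a persistent mutation tree; a haplotype is a pointer to its most
recent mutation, reproduction copies pointers, and sampled-carrier counts
come from one bottom-up pass.  A generation costs O(2N) independent of
diversity.  The compiled loop keeps fitness weights incrementally (only
mutations change them), samples parents by rejection against the maximum
weight (exact multinomial; effects are ~10⁻³, so acceptance ≈ 1), and uses
an inline xorshift128+ generator seeded via splitmix64 — all fully
deterministic under the replicate seed.

The single-mutant check simulates allele-count trajectories with relative
fitness 1+s and compares the fixation fraction with the diffusion result
(1−e^{−2s})/(1−e^{−4Ns}).

## CLR sweep scan

The scan follows the star-genealogy composite-likelihood formulation for a
completed sweep against an arbitrary background spectrum.  At distance d
from the sweep point each of the n lineages escapes independently with
p_e = 1 − exp(−α·d); the α parameter absorbs recombination rate and sweep
strength/duration, and d is physical distance in bp.  With b escaped
lineages the site's ancestry is b+1 draws against the background (the swept
class contributes one lineage, later expanded to n−b sample copies); the
count distribution is assembled from the background's hypergeometric
projections, mixed over b ~ Binomial(n, p_e), and conditioned on a
polymorphic outcome.  CLR(x) = 2[max_α log CL(x, α) − log CL_background]
with the α → ∞ limit (= background) always included, so CLR ≥ 0.

Numerics: the per-b count distributions are precomputed once per region
(they do not depend on α or d); per grid point, α is maximized over a
16-point log grid from 10⁻²/L to 10³/L (L = region length) with bounded
scalar refinement between the best grid point's neighbors (refinement can
be disabled for bulk null scans — the p-value remains valid because
observed and null replicates are scanned identically).  The grid has 1000
evenly spaced points including both endpoints by default; argmax ties break
to the leftmost point.  Probabilities are floored at the smallest positive
double before logs; a site on a background class with zero empirical mass
contributes the floor (this only arises for simulated nulls and is
conservative).

P-values: neutral coalescent replicates conditioned on the observed S, the
region's coverage mask, and its ρ are rescanned with the same background;
p = fraction of replicate maxima ≥ the observed maximum.  Default 1000
replicates, and an effective population size of 10,000 where one is needed
to convert per-generation rates — both configurable.

Backgrounds are estimated by aggregating filtered derived-allele counts
across regions, projecting sites at larger n down hypergeometrically (raw
weights, see above) and normalizing; sites below the target n are excluded
with a warning.

## Synthetic study generator

`generate_study` emulates the data shapes of a targeted resequencing study:
49 target + 13 control regions of 40 kb, coverage masks of alternating
geometric covered/uncovered runs (mean covered run 2 kb) with per-region
coverage fractions drawn on (0.65, 0.98) with median near 0.88; per-region
segregating-site counts Poisson around 101 with W2S:S2W:OTHER labels at the
study-wide composition (classifiable fraction 85/101); fixed differences
Poisson around 335 from the phylogenetic simulator, scattered over covered
bases.  Optional per-region bias: `inject_w2s_shift` moves W2S derived
counts up by a binomial number of steps calibrated so the expected
frequency increase equals the requested shift (an MWU positive control),
and S2W fixed differences can be relabeled W2S with a given probability (an
MK positive control).  Everything is seed-deterministic; files round-trip
bit-exactly through the package readers.

What the synthetic data do *not* emulate: linkage disequilibrium between
segregating sites within a region (sites are exchangeable draws given the
genealogy only in the coalescent engine's output), real recombination-rate
or telomere-distance structure, sequencing or genotyping error, and
chromosomal placement.  Passing tests on these fixtures demonstrates the
statistical machinery, not properties of any real dataset.

## Scale choices

Simulation-heavy checks run at reduced scale chosen to keep the full suite
practical while leaving Monte Carlo error well below the asserted margins:
neutral calibrations use 2,000 replicates; the forward BGC experiments use
N = 500 (diploid) with 300 replicates per condition; null sweep-scan
calibration uses 500 regions at a 40-point grid without α refinement; the
fixation-probability check uses N = 100 with 20,000 trials.

## Known limitations

- The MWU asymptotic branch relies on the normal approximation below ~8
  sites per class when ties are present; per-region results with very few
  classified sites should be read alongside the pooled test.
- The forward simulator's fitness is per-haplotype multiplicative; diploid
  dominance, gene-conversion tract mechanics, hotspots, and demography
  beyond a single clean split are out of scope.
- The sweep model is the star-genealogy approximation; its p-values inherit
  the conservativeness of the standard neutral null.
- Association binomial/Poisson tails treat regions as independent.
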