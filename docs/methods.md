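# Methods

This note documents the models, estimators, numerical choices and
limitations behind `salmix`.  It is written for a reader who wants to
know exactly what each number the package produces means, and what
passing the test suite does and does not demonstrate about real data.

## Data model

Genotypes are unordered diploid allele pairs at a shared panel of
codominant microsatellite loci; allele labels are PCR fragment sizes in
base pairs.  Missingness is whole-locus: a half-called genotype (one
allele scored, one zero) is coerced to missing with a warning, since a
single scored allele at a codominant locus is not usable by any estimator
here.  A `BaselineRegistry` couples the locus panel, the collections
(one per sample site × year) and a `HierarchyMap` of
site → catchment → reporting region.  Reporting regions are inputs, not
outputs: they encode an expert grouping of collections into units within
which stocks are not reliably separable, informed by the tree and
ordination evidence this package computes, but decided by a curator.
Allele binning and cross-laboratory standardisation are assumed done
upstream.

## Synthetic baseline generator

No genotype data accompany the study design this package targets, so the
generator is first-class code: it defines the conditions under which
every downstream claim is tested.

**Drift model.** Allele frequencies follow a nested Dirichlet
(Balding–Nichols-style) cascade.  Ancestral frequencies per locus are
symmetric-Dirichlet(1); each child level draws
`Dirichlet(parent · (1−F)/F)` with its own drift coefficient, so the
expected fixation index contributed per level is ≈ F and levels compound
approximately as `1 − Π(1−F_level)`.  This was chosen because the
workflow's own summaries of structure are nested variance components; a
coalescent model would add realism (shared drift topology within levels,
linkage) the analysis never exploits.

**Defaults and calibration.** The default geometry is 8 reporting
regions × 3 catchments × 2 sites, 12 loci with allele counts drawn
uniformly from 8–40, and 20–50 diploids per site — the shape of a
realistic national microsatellite baseline.  The drift coefficients
(`F_region = 0.023`, `F_catchment = 0.014`, `F_site = 0.009`) were
calibrated once so that the *realised* Weir–Cockerham global θ on
generated baselines averages ≈ 0.04, the canonical among-site
differentiation of such baselines; the raw coefficients sit above the
naive 0.02/0.012/0.008 split because genotyping error and finite panels
attenuate realised θ relative to the drift model's nominal F.
`study_baseline()` produces the full-scale version: a 112-site grid
truncated to 108 collections (so group sizes are slightly uneven, as in
any real programme).

**Error model.**  Per locus and gene copy, independently:

- *null alleles* — a hidden allele of frequency `q` (default: two of the
  twelve loci with `q` drawn in 0.05–0.15) makes visible/null
  heterozygotes score as homozygotes for the visible allele and null
  homozygotes score missing.  This is the standard microsatellite null
  model; the magnitude is a design choice (the phenomenon, not its rate,
  is documented for real panels).
- *allelic mis-scoring* — each scored allele is replaced by a uniformly
  chosen different allele with probability 0.022, the re-genotyping
  error rate reported for the real dataset.
- *missingness* — each locus genotype drops with probability 0.01.

**Seeding.** All generators are pure functions of (spec, seed).
Substreams are derived by hashing `(master seed, purpose, unit id)`
(`salmix.util.substream_seed`), so adding a unit or experiment never
shifts another stream's draws.

**What the generator does not emulate.** Family sampling (sibship
clusters in parr collections), temporal drift between years at a site,
linkage between loci, allele-size homoplasy and binning artefacts, and
population-specific error rates.  Tests passing on this generator
therefore demonstrate correctness of the estimators under their own
assumptions and realistic noise — not robustness to pedigree structure
or inter-laboratory artefacts.

## Quality control

*Heterozygosities*: H_O is the fraction of typed individuals
heterozygous; H_E is Nei's unbiased `(2n/(2n−1))(1 − Σp²)`.

*Hardy–Weinberg test*: exact conditional test on the genotype table given
allele counts (Levene's distribution).  The p-value is the total
probability of tables no more probable than the observed one.  Tables
are enumerated recursively when the search visits ≤ 100,000 nodes (the
cap bounds work, not just output size); otherwise the same distribution
is sampled by shuffling the 2n gene copies and pairing them
(vectorised, default 100,000 replicates), with the add-one p estimate
`(hits+1)/(reps+1)`.  Probability comparisons use a 1e-9 relative slack
so enumeration and Monte Carlo agree on ties.

*Null-allele screen*: one-sided test of heterozygote deficiency (the
count of heterozygotes under the same conditional distribution) plus the
Brookfield-1 estimator `r = (H_E − H_O)/(1 + H_E)` floored at zero.
Size-class-specific diagnostics (large-allele dropout, stutter) are out
of scope.

*Multiple testing*: "sequential Bonferroni" is implemented as Holm's
step-down procedure, the standard reading of that phrase.  Flagged HWE
departures are reported, never acted on automatically; excluding
collections is a caller decision.

*Temporal stability*: per-locus exact tests on the alleles × 2-samples
count table (Fisher's exact for 2 alleles, multivariate-hypergeometric
enumeration or permutation Monte Carlo otherwise).

*Duplicate-run error rate*: allelic mismatch proportion between two
genotyping runs of the same individuals, genotypes compared as unordered
multisets, loci missing in either run excluded.

## Differentiation and structure

*θ (F_ST)*: Weir & Cockerham (1984) variance components per allele and
locus, combined as Σa / Σ(a+b+c); negative per-locus values are retained
in the sums.  Missing genotypes are dropped per locus (pairwise
deletion).  Pairwise θ over many collections uses the fact that the
two-population estimator depends only on per-collection sufficient
statistics (typed counts, allele frequencies, per-allele heterozygote
proportions), so all pairs are computed by broadcasting; permutation
p-values shuffle individuals between the pair with sizes preserved and
use the add-one estimate.

*Variance components*: three-level AMOVA on allele-identity (0/1)
distances between gene copies — the unordered-allele default — with the
standard sums-of-squares decomposition and coefficient corrections for
unequal sizes; components are estimated per locus and summed.  With one
collection per group the middle level is structurally zero; with a
single group the analysis collapses to two levels and F_CT is unset.

*D_A*: `1 − (1/L) Σ_ℓ Σ_a √(x_a y_a)` on plain count frequencies, loci
untyped in either member of a pair dropped (L reduced).

*Neighbour joining*: Saitou–Nei with the standard Q criterion; ties are
broken by the lexicographically smallest pair of node representative
labels, making topologies deterministic; negative branch lengths are
clamped to zero with the clamped total recorded.  Locus-bootstrap
support resamples loci with replacement, recomputes D_A and the tree,
and reports the percentage of replicates containing each bipartition of
the full-data tree; the majority-rule (50%) consensus is built with
dendropy.

*Ordination*: classical PCoA (double-centred −D²/2, eigendecomposition,
top-k non-negative eigenpairs, first non-zero loading positive per
axis).  The original workflow used non-metric MDS; PCoA was substituted
for determinism and testability, so coordinates are comparable only in
cluster membership, not in layout.

## Stock identification

*Frequencies*: posterior means with 1/K pseudo-counts
(`(count + 1/K)/(2n + 1)`); mixture alleles unseen in the entire
baseline are appended to the registry with prior-only mass.  This keeps
every genotype possible in every unit — mandatory, since a zero-probability
allele would veto a unit regardless of the other loci.

*Likelihoods*: per locus `2 p_a p_b` / `p_a²`, summed in log space over
typed loci, floored at −700 per matrix entry against underflow.
Individuals typed at zero loci carry a zero row and are flagged.
Leave-one-out removes an individual's own alleles from its unit's counts
(and 2 from the denominator) before computing that entry, eliminating
self-inflation in baseline self-tests; for a singleton unit this reduces
to the prior alone.

*EM*: uniform start; responsibilities and proportion means until the
largest proportion change is below 1e-7 (20,000 iteration cap, warning
on non-convergence).  The observed-data log-likelihood is asserted
non-decreasing every iteration.  Uncertainty: nonparametric bootstrap
over mixture individuals (default 100 replicates), reported as SD and
2.5–97.5 percentile interval.

*Gibbs sampler*: conditional on baseline frequencies fixed at posterior
means, with prior Dirichlet(1/B).  Eight chains; chain c starts with
0.90 of the mass on the c-th largest unit of a preliminary EM fit (ties
by label), remainder uniform.  Each sweep resamples origins then
proportions.  The last 1,000 draws per chain are pooled for the
posterior mean and SD; the per-unit Gelman–Rubin shrink factor
√(((n−1)/n·W + B/n)/W) is computed on those retained segments, reported
unclamped (it can fall below 1), and convergence requires every factor
< 1.2.  A flag enables the full variant that also resamples baseline
allele frequencies each sweep from Dirichlet(counts + 1/K + assigned
mixture alleles); it is markedly slower and off by default, since with
baselines of tens of individuals the conditional approximation is the
conventional choice and the two variants differ little away from tiny
units.

Indistinguishable baseline units are the sampler's designed failure
mode: the split of mass between two statistically identical columns has
a flat likelihood, so it performs a diffusive random walk whose
relaxation time grows with the mixture's information content.  With a
mixture of a few hundred fish the last-1,000 windows of different chains
sit at different split values and the shrink factor exceeds 1.2 — the
correct diagnostic outcome, mirroring the behaviour of Bayesian MSA on
real baselines containing near-duplicate collections.

*Assignment*: posterior over units with a uniform prior; individuals
typed at fewer than 9 loci are excluded (the standard panel-quality
filter); exact posterior ties are flagged and broken by unit order.

*Aggregation*: allocate-and-sum adds unit proportions within a catchment
or region (mass conserved exactly); pool-and-allocate merges genotypes
within catchments first and re-estimates.  Pooling trades unit
resolution for per-unit sample size, which helps when collections are
small and similar.

## Evaluation experiments

Single-origin (100% from one unit) and multi-origin designs (equal
12.5% × 8 and an unequal 5–30% design) draw `n_mix = 100` fish per
replicate and run 100 replicates by default.  Simulated mixture fish are
always *fresh parametric draws* — never copies of baseline individuals —
from either (a) the unit's smoothed baseline frequencies (the only
option with real data, and optimistic at the unit level because the
mixture then matches the baseline's sampling noise) or (b) the
generator's true population frequencies (`source=truth`), which emulates
genuinely new fish against an imperfect finite baseline.  Option (b) is
what the headline recovery experiment uses, and it reproduces the
characteristic pattern: unit-level estimates biased low (similar
neighbouring units absorb proportion) while region-level sums are
accurate — the reason reporting regions exist.

The published evaluation summaries of the original study (per-sample
point estimates of apportionment back to sample, catchment and region)
ship as transcribed CSVs under `salmix/data/`; only their column
arithmetic (means/ranges) is used, via `summarize_table`.  One published
column (the Bayesian per-river allocation) is internally inconsistent —
its printed mean (34.00) does not equal the mean of its printed rows
(≈ 62.7), apparently reflecting an exclusion of non-converged chains
that the source does not specify — so no check targets it.

## Problem sizes and determinism

The test suite and acceptance script run everything at the study's
design scale where the quantity is scale-defined (108 collections for
the pair count; 8 × 20,000-iteration chains for the MCMC protocol;
100 × 100 replicate mixtures for recovery) and at reduced scale where
only correctness is at stake (QC Monte Carlo replicates, bootstrap
counts in unit tests).  Every random quantity is a pure function of the
documented seed; reruns are byte-identical.

## Known limitations

- AMOVA significance is not permutation-tested (components and F-ratios
  only); the workflow's inference rests on the pairwise permutation
  tests.
- The Gibbs sampler reports unconverged estimates rather than refusing
  them; callers must check `converged`/`shrink_factors`.
- The null-allele screen is the general homozygote-excess test only; it
  will flag any heterozygote-deficit cause (inbreeding, Wahlund,
  dropout) as "null-like".
- GENEPOP parsing covers the 2- and 3-digit diploid dialect with comma
  labels; haploid data and extended dialects are rejected.
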