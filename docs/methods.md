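# Methods

## The observation model

The unit of observation is a genotyped trio (sire, dam, offspring) at a
biallelic locus, coded as the count of allele B.  Only matings with at least
one heterozygous parent are informative; ordered sire × dam they are
AB × AA, AB × BB, AA × AB, BB × AB and AB × AB, giving eleven possible
offspring-genotype cells.  A locus's data are the multinomial counts in
those cells (the multinomial coefficient is dropped everywhere; it is
constant across models, so Bayes factors and DIC differences are unchanged).
Trios with a missing genotype are dropped, and trios incompatible with any
pair of parental gametes (Mendelian errors, a genotyping-error signature)
are excluded and tallied per locus rather than repaired.  Heterozygous-sire
and heterozygous-dam counts are over distinct parents, not trios, because
they measure how many independent meioses inform the locus.

## TRD parameterizations

**Allelic.**  A heterozygous parent transmits allele A with probability
0.5 + α (overall) or 0.5 + α_s / 0.5 + α_d (parent-specific), each with a
flat prior on [−0.5, 0.5].  AB × AB offspring probabilities are products of
the two transmission probabilities; the AB cell sums both transmission
routes, so no latent "which parent sent which allele" variable is needed.

**Genotypic.**  Offspring genotype frequencies are distorted directly:
relative viabilities (1 + α_g − δ_g, 1 + δ_g, 1 − α_g − δ_g) for AA/AB/BB.
From AB × AB these divide by 4/2/4; in heterozygous × homozygous matings the
unreachable homozygote is absent and the two remaining cells renormalize by
2(1 ± α_g/2) — a correction for the overall loss of individuals.  The
admissible space is taken to be exactly the set where every offspring
probability lies in [0, 1]: α_g ∈ [−1, 1], δ_g ∈ [−1, 1 − |α_g|], with the
flat prior normalized numerically over that region (area 3).  This is a
deliberate design choice: it is the minimal space in which every published
fit of this model family (including heterosis-excess estimates such as
α_g = 0.05, δ_g = 0.25) is admissible, whereas narrower textbook supports
exclude some of them and do not carry unit prior mass.  Users comparing
against other software should check which support that software uses.

A complete recessive lethal is the boundary point (α_g, δ_g) =
(−2/3, +1/3) (or its mirror image for the other homozygote): the
disadvantaged homozygote has probability exactly zero in every mating and
carrier × non-carrier matings segregate 1:1 — which is why het × het
matings are indispensable for distinguishing recessive from allelic TRD.
Viability factors within 10⁻¹² of zero are snapped to exact zero so that
lethality boundaries behave as structural zeros rather than rounding dust.

## Inference

All models are 1- or 2-dimensional with bounded flat priors, so the
**reference engine is grid quadrature**: trapezoid weights per dimension
(default 201 points per axis, odd so the Mendelian null is on the grid),
masked to the admissible region for the genotypic model.  It yields the
marginal likelihood, posterior moments, equal-tail credible intervals and
DIC deterministically, with no Monte-Carlo error, and the parameter grids
and their cell-probability matrices are cached across loci, which is what
makes genome scans cheap.

An **adaptive random-walk Metropolis** chain (default 110,000 iterations,
10,000 burn-in, proposal scale adapted toward ~30 % acceptance during
burn-in only) is provided as the sampling-based engine.  Proposals reflect
at the rectangular bounds of each parameter; for the genotypic model a
reflected proposal that still violates the interior simplex constraints is
rejected outright — the prior is zero there, so detailed balance holds
without a bespoke reflection across the diagonal boundaries.  Effective
sample sizes use the initial-positive-sequence autocorrelation estimator,
and acceptance rates outside [0.05, 0.95] are logged as warnings.

**Bayes factor.**  BF = marginal likelihood of the TRD model / likelihood at
the Mendelian point null (the null has no free parameters).  Under flat
priors this equals the Savage–Dickey density ratio, and both routes are
implemented: on the grid the posterior density at the null is read off the
quadrature cell at the origin, for chains it is a Gaussian KDE at the
origin.  The identity is used as an internal cross-check; the grid
marginal-likelihood route is authoritative.  BF ≥ 100 ("decisive") is the
significance call.  For a significance/ranking BF the scan takes the
maximum across the three TRD models, since a region distorted under any
parameterization is a candidate; parameter estimates, CV and the pattern
label always come from the DIC-selected model.

**DIC.**  DIC = D̄ + pD with D = −2 log p(y|θ), D̄ the posterior mean
deviance and the point estimate at the posterior mean (the standard
Spiegelhalter form).  Models within 3 DIC units resolve toward fewer
parameters.  The null model participates as a reference (pD = 0) but model
selection for labeling is among the three TRD models.

**Pattern labels.**  Parent-specific fits are labeled sire-TRD / dam-TRD /
sire+dam-TRD by which 95 % credible intervals exclude zero (neither
excluding zero falls back to overall-TRD).  Genotypic fits are labeled from
the point estimate: *recessive* when δ_g > 0 and the disadvantaged
homozygote retains less than half its Mendelian viability
(1 − |α_g| − δ_g < 0.5); otherwise δ_g ≥ 0.10 → heterosis excess,
0 < δ_g < 0.10 → homozygote disadvantage, δ_g ≤ −0.10 → heterosis
deficiency, −0.10 < δ_g ≤ 0 → homozygote advantage.  The 0.5 lethality
margin and the 0.10 dominance split are configuration values; the defaults
reproduce the published example labels for all five genotypic patterns.

## Haplotype windows

Sliding windows of 2/4/7/10/20 consecutive SNPs (step 1 marker, never
spanning chromosomes) define haplotype alleles as the distinct phased
strings among parental haplotypes.  Each allele H_j is recoded against the
pooled remainder H_−j as a biallelic pseudo-marker (pseudo-genotype = count
of H_j copies), and the full SNP machinery applies unchanged; a one-marker
window recode reproduces the SNP fit exactly, which the tests use as a
consistency bridge.  Individuals with any missing or unphased entry in a
window are excluded from it; unphased input disables window mode with an
explicit error rather than attempting on-the-fly phasing.  Orientation
(which allele of a SNP, or H_j vs H_−j) only flips parameter signs.

## Filtering ledger

Four independent flags per candidate record; the verdict is their
conjunction:

1. **informative parents** — ≥ 20 distinct heterozygous sires and/or ≥ 100
   heterozygous dams;
2. **sire robustness** — among heterozygous-sire families whose unambiguous
   transmissions are all the same allele ("fully skewed", the classic
   signature of a genotyping artifact in one family), the k = 2 largest are
   removed one at a time and the record's Bayes factor must stay decisive
   each time; records that are not decisive to begin with pass vacuously;
3. **empirical null** — the selected model's parameter estimate must exceed
   the two-sided Mendelian-sampling threshold for the record's
   informative-offspring bin at tail probability p = 10⁻⁵ (any of the
   selected model's parameters exceeding its threshold passes, so a pure
   sire effect is not penalized for its null dam component);
4. **stability** — posterior CV (sd/|mean|) of the selected model's
   largest-magnitude parameter ≤ 20 %.

The null table is built by Monte Carlo (default 2 × 10⁶ replicates per
offspring bin, seeded): offspring are allocated to matings by a configurable
mix, drawn at Mendelian ratios, and fast method-of-moments statistics stand
in for the posterior means — the pooled transmission fraction for α, α_s,
α_d (het × het matings contribute only their unambiguous AA/BB offspring to
the parent-specific statistics) and the het × het genotype moments
α̂_g = 2(p̂_AA − p̂_BB), δ̂_g = 2p̂_AB − 1.  At the sample sizes where this
filter matters, flat-prior posterior means and these statistics coincide to
first order, and a million-replicate refit per bin would be infeasible.
Thresholds are the smallest observed magnitude whose empirical exceedance
probability is ≤ p, +∞ when no magnitude is that rare (small bins), and are
forced non-increasing in offspring count.

## Integration

Overlapping significant records on a chromosome are clustered transitively
and only the highest-BF record per cluster is kept (ties: smaller interval,
then leftmost) — overlapping windows of different sizes all shadow the same
underlying signal.  The retained records' BFs are then smoothed along the
genome with a Gaussian kernel, ŷ(κ_i) = Σ_j (2πσ²)^{−1/2}
exp(−(κ_i−κ_j)²/2σ²)·BF_j, anchored at interval midpoints and rescaled by
√(2πσ²) so an isolated record's peak equals its own BF (a max-normalized
track is available by flag).  Default bandwidth σ = 500 kbp with 2 Mbp and
5 Mbp alternatives.  Core regions are separated local maxima above the
decisive threshold — two adjacent peaks count as separate only if the track
dips below half the smaller peak between them — each with a significance
span of ±zσ, where z is the two-sided normal quantile rounded to two
decimals (1.96/2.58/3.29 → ±980,000/±1,290,000/±1,645,000 bp at σ =
500 kbp).  Infinite BFs (likelihood-ratio overflow at extreme loci) are
clipped to the largest finite BF for smoothing only; the track is a mapping
aid, not an inference.

For a candidate lethal, the expected count of missing offspring is
n_informative × 2 × |α| from the overall allelic fit, and genotypic records
additionally report round(n_{AB×AB}/4) minus the observed count of the
disadvantaged homozygote from het × het matings.

## Synthetic data

The gene-drop simulator emulates the family structure of large dairy-cattle
genotyping programs: paternal half-sib families (a fixed or uniformly
sampled offspring count per sire, supporting the tens-to-thousands range),
one offspring per dam, one generation of depth, biallelic SNPs at constant
spacing (default 50 kbp, matching typical medium-density array spacing) and
recombination at 1 cM/Mbp via per-interval Haldane fractions.  Founder
haplotypes are drawn site-independently from per-SNP allele frequencies
(Uniform(0.1, 0.9) unless specified) or from an explicit per-chromosome
haplotype pool with given frequencies — the pool route creates genuine
multi-SNP haplotype alleles for window-mode tests, and a planted locus's
carrier frequency is checked against the pool (error if unattainable).

Allelic distortion conditions the meiosis strand process at the focal locus
(the crossover chain is symmetric under a global strand flip, so flipping
whole paths implements P(transmit A) = 0.5 + α exactly while preserving the
recombination law for linked markers); one allelic locus per chromosome is
supported.  Genotypic distortion is zygote-viability rejection with weights
(1 + α_g − δ_g, 1 + δ_g, 1 − α_g − δ_g)/max — exactly the likelihood being
fit, in every mating type.  Matings that cannot produce any viable genotype
(e.g. two lethal-homozygote parents) produce no offspring: those pedigree
rows and genotype columns are removed, as they would never be observed.
Rejections and removals are counted per locus in the truth record.
Genotyping error flips an entry to one of the two other codes (phase
redrawn consistently); missingness masks entries independently.

What the generator does **not** emulate: multi-generation pedigrees,
realistic linkage disequilibrium from population history (founder sites are
independent unless a pool is given), array-specific missingness patterns,
age-at-genotyping ascertainment, or selection on phenotypes.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated sampling model, not robustness to every artifact of industry data.

## Problem sizes and numerical choices

The test suite and the acceptance script run deliberately scaled-down
designs chosen to keep every check sharp: 1,000-SNP genomes with 15,000
offspring for the planted-signal scans, 50,000 offspring for the
single-locus recessive-lethal recovery (carrier frequency 3 % needs that
many matings to yield ≥100 het × het trios), 1,000 null loci × 1,000
informative offspring for BF calibration, and 2 × 10⁶ replicates per bin
for the null table (10/p at p = 10⁻⁵ is the recommended floor, 2×10⁶ the
default).  Grid resolution is 201 points per axis in scans and 401–1001
where quadrature accuracy itself is under test (trapezoid error at 1001
points is ~10⁻⁴ relative on the hardest oracle integrals).  Posterior-mass
normalization is exact by construction; quantiles are weighted empirical
quantiles on the grid marginals.  Degenerate inputs are defined behavior:
empty pedigrees give empty trio sets, all-zero count tables give BF = 1 and
posterior = prior, a locus below 10 trios produces no record, and a zero
posterior mean stores an infinite CV.

## Known limitations

* The MCMC Savage–Dickey BF uses a KDE at the origin and is noticeably
  noisier than the grid marginal-likelihood BF for strongly non-null data;
  grid BFs are used for calling.
* The empirical-null estimators are moment statistics, not refitted
  posteriors; at very small bins (≤50 offspring) their discreteness makes
  thresholds coarse (often +∞, i.e. the filter cannot pass there).
* Window mode fits every observed haplotype allele of every window;
  runtime grows with haplotype diversity, and no LD pruning is attempted.
* X-chromosome matings, mixture/per-family random-TRD models and genotype
  imputation/phasing are out of scope; window mode expects phased input.
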