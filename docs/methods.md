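# Methods

`pedgrm` estimates the additive genetic variance (Va) and narrow-sense
heritability (h²) of a repeatedly measured quantitative trait with a
Bayesian animal model, under two alternative descriptions of relatedness
among individuals: the expected (numerator) relationship matrix **A**
derived from a field-observed social pedigree, and a realized genomic
relatedness matrix **G** derived from SNP dosages.  Its purpose is to make
the bias mechanism of erroneous social pedigrees — extra-pair paternity
(EPP) turning putative full sibs into half sibs — measurable on synthetic
data with known truth.

## The model

For measurement *j* of individual *i*,

    y_ij = mu + x_ij' b + a_i + p_i + e_ij

with `a ~ N(0, sigma2_a K)`, `p ~ N(0, sigma2_pe I)`,
`e ~ N(0, sigma2_e I)`, and optionally a year random effect
`u ~ N(0, sigma2_year I)`.  K is either A (pedigree) or G (genomic).  The
fixed effects default to an intercept plus measurer contrasts in
first-level reference coding; sex and (minimum) age can be added.  Repeated
measurements are what separate the permanent-environment variance from the
residual; with a single record per individual only `sigma2_a + sigma2_pe`
(under K = I, only the total) is identified, and the fit warns accordingly.

Heritability is summarised per draw as
`h2 = sigma2_a / (sigma2_a + sigma2_pe + sigma2_e [+ sigma2_year])`
(mean of ratios; the ratio of posterior means is also reported).  The
year component enters the denominator exactly when it is fitted; it is off
by default because among-year variance is negligible in the data structure
the generator emulates.  The additive genetic coefficient is the per-draw
`sigma2_a / trait mean`, an evolvability-style quantity that requires the
mean on the same measurement scale as the variance components — for a
tarsus-like trait recorded in 0.1 mm units, a 17.48 mm mean enters as
174.8.  The internal consistency of heritability and coefficient summaries
computed from the same components is what pins that scale.

## Sampler

All full conditionals are available in closed form, so the model is fitted
by a blocked Gibbs sampler rather than generic HMC:

* fixed effects from their Gaussian conditional (flat prior);
* the individual-effect block (a, p) jointly: a is drawn with p
  analytically marginalised — its conditional precision is
  `K^{-1}/sigma2_a + diag(w)` with `w_i = n_i/(sigma2_e + n_i sigma2_pe)`
  — followed by p given a.  Sampling this strongly anti-correlated block
  jointly is what keeps the Va/Vpe split mixing well, which matters because
  the deflation phenomenon *is* a Va↔Vpe reallocation;
* each variance component from its scaled-inverse-chi-square conditional.

The default prior on each random-effect standard deviation is
half-t(3, sd(y)), the standard weakly-informative choice for variance
components in hierarchical models.  It is implemented *exactly* inside the
conjugate Gibbs framework by parameter expansion: the component is written
`a = alpha * eta` with `alpha ~ N(0, A^2)` and
`eta ~ N(0, vtilde K)`, `vtilde ~ scaled-inv-chi2(nu, 1)`, so that
`sigma_a = |alpha| sqrt(vtilde) ~ A * |t_nu|` while every full conditional
(eta block, scalar alpha, vtilde) stays Gaussian or
scaled-inverse-chi-square.  The expansion doubles as a mixing device: the
alpha moves rescale an entire component in one draw, cutting the Va
autocorrelation time from ~200 to ~14 in the weakly-identified repeated-
measures setting.  This choice is deliberate: a near-Jeffreys
scaled-inverse-chi-square prior (df ~1e-3) looks innocuous but diverges at
zero, and on the flat Va/Vpe ridge produced by 1–3 records per individual
it drags one component to zero — parameter recovery fails no matter how
long the chain.  The plain conjugate prior remains available
(`ModelSpec(prior="inv_chisq")`) for sensitivity checks; the residual
variance, which is always strongly identified, keeps a
scaled-inverse-chi-square prior with tiny df.  Defaults are 20,000
iterations, 4,000 burn-in, 4 chains, thin 1; the per-chain stream is
`default_rng([seed, 100 + chain])`.  Convergence is monitored with the
split potential scale reduction factor (two half-chains per chain;
`sqrt(((n-1)/n W + B/n)/W)`).

Numerics: K is symmetrised, and repaired to positive definite by adding
`eps * trace(K)/n` to the diagonal with eps escalating
1e-8 → 1e-4 (×10 steps); the accepted eps must leave the smallest
eigenvalue clearly positive, because a centred GRM is numerically singular
along the all-ones direction and a merely-passing Cholesky produces an
unusable K⁻¹.  A matrix still indefinite at 1e-4 is an error.  Phenotype
rows are canonically sorted before fitting, so row order cannot change
results at a fixed seed.  Per iteration the dominant cost is one n×n
Cholesky (n = phenotyped individuals); a 500-individual, 4-chain,
5,000-iteration double fit completes in a few minutes on one core.

## Relatedness constructions

**A** is filled by the tabular method in topological order
(`A_ii = 1 + 0.5 A(sire,dam)`, `A_ij = 0.5 (A(j,sire_i) + A(j,dam_i))`,
missing parents contributing zero); it is exact and O(n²).  Clutches with
an unobserved parent receive one shared dummy founder per missing slot
("common dummy parents"), so full-sib covariance within the clutch is
retained; dummies are flagged and excluded from phenotype joins and from
maternity/paternity/depth counts, but participate in the recursion.  Rows
with no parents and no clutch key are founders and never receive dummies.
Trimming a pedigree to the genotyped subset keeps the ancestor closure, so
relatedness transmitted through removed intermediates survives projection
of A onto the subset.

**G** comes in two constructions.  `build_grm_ibs` is the classic mean
identity-by-state allele sharing over pairwise-complete loci,
`mean((2 - |g_i - g_j|)/2)`; its entries live in [0, 1] with unrelated
pairs near 0.7 at intermediate allele frequencies.  `build_grm_vanraden`
is the allele-frequency-centred matrix `W W'/(2 Σ p(1-p))`, whose
expectation is A.  The pipeline fits models and classifies paternity on
the centred construction by default: the Va(P)-vs-Va(G) contrast is only
meaningful when both matrices are on the additive-relationship scale, and
the paternity thresholds below presuppose unrelated ≈ 0 and
parent–offspring ≈ 0.5 — on the raw IBS scale every pair clears them.
The raw IBS matrix remains available (`grm_method: ibs`) for
scale-sensitivity checks.  The G diagonal is not rescaled (a
standardisation knob exists in the form of choosing the construction).

A caveat the tests document: centring on *sample* allele frequencies
shifts all entries downward in small, deeply related populations (parent–
offspring pairs can sit near 0.3 rather than 0.5).  The classification
thresholds therefore assume a mostly unrelated sample, which matches the
field situation the package emulates (mean pairwise relatedness of order
1e-3) but not a small closed population after several generations.

Paternity classification labels a social father–offspring pair
`within_pair` above similarity 0.3, `epp` below 0.1, `unresolved`
between; unresolved pairs are counted and kept in the rate denominator by
default (on well-separated data the choice is inert).  The EPP rate is
reported as a percentage with its raw counts.

The Mantel comparison correlates the strictly-lower-triangle entries of
the two matrices; the one-sided p-value uses simultaneous row/column
permutations (9,999 by default; add-one correction), and the confidence
interval is a percentile bootstrap over individuals in which pairs formed
by two copies of the same resampled individual are excluded (a bootstrap
over pairs would break the matrix structure).  The pipeline's desk-scale
default lowers the permutation count to 999.

## Marker QC

The cascade runs in a fixed, logged order: excluded (sex) chromosomes →
per-SNP missingness → per-individual missingness → recompute per-locus
statistics → MAF → Hardy–Weinberg exact test.  Missing-rate bounds are
inclusive ("no more than"), MAF and HWE cuts are strict, with defaults
MAF < 0.05, per-SNP missing > 0.1, per-individual missing > 0.05, HWE
p < 0.001.  The HWE test is the two-sided exact conditional test computed
in log space (chi-square is deliberately not used; the exact test is the
standard for SNP QC and is conservative, which the tests verify
empirically).  Whether individual filtering should precede the HWE test is
genuinely ambiguous in field practice; the chosen order recomputes locus
statistics after individual removal and is documented rather than inferred.

## Synthetic data

The generator emulates a nest-box passerine study: discrete non-
overlapping generations, strictly monogamous social pairs formed by random
male–female matching, a fixed number of offspring per pair, and per-
offspring independent EPP — with probability `epp_rate` the genetic sire
is a uniformly drawn different male of the parental generation (dams are
never misassigned).  Defaults: 50 founders, 4 generations, 4 offspring per
pair (~750 individuals), EPP 20%, 8,000 unlinked SNPs with founder minor-
allele frequencies uniform in [0.05, 0.5] (the panel size is a
requirement of the P-vs-G contrast, not an ornament — see the experiments
section), trait mean 174.8 with
Va = 13.5, Vpe = 8.22, Vres = 3.89 (total ≈ 25.6 on the 0.1 mm scale),
five measurers with offsets (0, 0.5, 3.9, 0.2, 0), and 1–3 measurements
per individual (the repeat distribution is a modelling choice: field data
of this type average ~1.7 measurements per bird, but the within-population
distribution is not knowable from summaries).

Genotypes are gene-dropped through the *genetic* links so marker
similarity reflects realized relatedness.  Breeding values follow the
additive infinitesimal model with Mendelian-sampling variance Va/2
(non-inbred approximation — adequate for pedigrees of ≤8 generations with
unrelated founders, and deliberately simpler than an inbreeding-corrected
term).  Not emulated: overlapping generations, immigration, selection or
assortative mating, linkage/LD among loci, dominance, sex linkage,
clutch-correlated EPP, maternal or common-environment effects.  Passing
tests therefore demonstrate the EPP mechanism in isolation; on real data
the same contrast also absorbs unmodelled common-environment similarity
and LD structure, which this package does not claim to quantify.

All randomness derives from one seed via fixed stream keys
(`default_rng([seed, stage])`), so identical configurations are
byte-identical, and the pipeline derives its stage seeds (simulation,
Mantel, P fit, G fit) from the single run seed by fixed offsets.

## Replicate experiments and chosen problem sizes

Two designed experiments quantify the headline claims
(`pedgrm.experiments`):

* **Deflation**: 20 replicates of a 402-individual population
  (134 founders, one generation of four-chick broods, 8,000 SNPs) with
  true h² = 0.5 (Va 12.5, Vpe 8.5, Vres 4.0) at 20% EPP, each fitted with
  the social-pedigree A and with the genomic G.  The expectation is mean
  Va(social) strictly below mean Va(genomic) with Vpe moving oppositely.
  The same function at 0% EPP is the null calibration: the two h² credible
  intervals should overlap in ≥18/20 replicates.
* **Coverage**: 100 replicates fitted with the true (genetic-pedigree) A;
  the 95% CrI for h² should cover 0.5 in ≥85/100.

Two design constraints of these experiments are worth spelling out.
First, the wide founder base: the model's credible interval is conditional
on the pedigree, so coverage of the *generating* h² requires the realized
genetic variance of each replicate to sit close to that value — with few
founders and several generations, founder-sampling noise alone pushes
coverage well below nominal for any chain length.  Second, the SNP panel:
per-pair marker noise of order 1/sqrt(n_loci) attenuates the G-fitted Va
like measurement error in a regressor, and at 1,000 loci that attenuation
(~30% here) would swamp the ~13% pedigree-error attenuation the experiment
is about; 8,000 unlinked loci push it well below.  Replicate fits use
deliberately short single chains (1,200 iterations, 300 burn-in): the
coverage target leaves headroom for the extra Monte-Carlo noise in the
interval endpoints, and these sizes keep a full replicate batch
desk-sized.  `scripts/acceptance.py` re-runs the complete
pipeline at the generator defaults (2,500 iterations × 2 chains per fit)
plus reduced replicate batches (8 deflation, 20 coverage) and writes every
computed quantity to JSON.

## Known limitations

* The G-matrix fit inherits whatever scale the chosen construction
  implies; raw IBS inflates sigma2_a by an arbitrary factor and is
  provided for comparison only.
* Paternity classification degrades in small closed populations (sample-
  frequency centring; see above).
* No leave-one-out model comparison, no maternal/common-environment
  variance, no multi-trait models, no genomic prediction of individual
  breeding values.
* The permutation p-value of the Mantel test is one-sided (positive
  association), which is the only direction of interest here.
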