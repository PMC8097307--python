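# Methods

`ryupop` re-implements, at desk scale, the population-genetic inference
chain used in fine-scale island demography studies of the southern Ryukyus:
a multi-deme demographic model, genotype quality control, the core
statistics (Hudson's F_ST, Patterson's D, the joint site-frequency spectrum,
runs of homozygosity, a haplotype-sharing index), IBD segment detection,
IBD-based recent-Ne inference, and SFS composite-likelihood demographic
fitting.  Because the underlying biobank genotypes are not public, every
analysis runs on synthetic data generated under the fitted demographic
model; the package is therefore organised around model-consistency and
parameter-recovery experiments rather than reanalysis of the original
cohort.

## The demographic model

The built-in fitted model has five sampled populations — an outgroup (CHB,
Han Chinese) and four island populations: Okinawajima (OKI), Miyakojima
northeast (MYNE), Miyakojima southwest (MYSW) and Irabu/Ikema (IKM) — plus
two internal demes: the ancestral Ryukyu population (RYU) and the deep trunk
(ANC).  Backwards in time, OKI and MYNE merge into RYU 7 generations ago,
MYSW joins at 16, IKM at 41, RYU merges into the trunk at 109, and the
outgroup joins at 3,000 generations.  IKM carries three size epochs (an
expansion about 10 generations ago), OKI two, and the six recent island
pairs exchange migrants at symmetric per-generation rates between 1.6e-9
and 3.4e-4.  All parameters are overridable keyword by keyword.

**Size units.**  Model sizes follow the gene-copy convention of the
coalescent software the source model was fitted with: a deme of size N holds
N haploid gene copies (N/2 diploids), so a haplotype pair coalesces at rate
1/N per generation.  This reading is adopted because it is the one under
which the fitted model reproduces the study's own published
between-population F_ST (simulated Hudson F_ST between MYNE and IKM is
~6.7e-3 against the published 6.79e-3, versus ~3.4e-3 under a diploid
reading).  A `size_units="diploid"` switch reinterprets sizes as diploid
individuals.

**Fixed deep parameters.**  The outgroup split time (3,000 generations),
outgroup size and trunk size (20,000 gene copies, i.e. the canonical
ancestral human effective size of ~10,000 diploids) are fixed, not fitted;
they are not printed in the source study's text.  Checks showed the headline
statistics are insensitive to the trunk size (the segregating-site ensemble
bounds the weight of deep genealogy), so these defaults are conventions, not
calibrations.

## The coalescent engine

Sites are simulated as independent single-site genealogies under a
discrete-generation structured coalescent with splits, size epochs and
symmetric migration.  Independent sites are deliberate: every downstream
statistic here is a single-site functional, block jackknives remain valid
(conservative) without linkage, and IBD structure is generated by a separate
pairwise engine.  Three regimes trade exactness for speed per generation:

* **Geometric skip** (total event hazard < 0.25): the waiting time to the
  next event is geometric and a single event (coalescence or migration) is
  placed, with the per-generation event probability `1 - exp(-H)`.
* **Binomial pair counts** (a deme's lineage count is at most 5% of its gene
  copies): the number of coalescing pairs that generation is binomial on the
  number of pairs; triple mergers, of relative probability about the
  occupancy ratio, are neglected.
* **Exact Wright-Fisher rounds** (crowded demes): every lineage picks a
  parental copy; lineages sharing a parent merge, reproducing simultaneous
  and multiple mergers exactly.  This regime governs the recent island
  epochs, where sample sizes are large relative to the effective sizes and
  multiple mergers genuinely occur.

The engine reproduces E[T2] = 2N, the neutral SFS shape and two-deme
divergence F_ST within Monte-Carlo error, and agrees with an independent
continuous-time simulator (msprime) on mean TMRCA and marginal SFS for small
two-deme designs.

**Mutations.**  The default places exactly one mutation uniformly on each
genealogy's total branch length — an array-like panel of segregating sites.
This conditioning weights every tree equally and therefore deviates from the
infinite-sites site-frequency shape by a few percent (short, star-like trees
are over-weighted); it is used consistently on both the observed and the
expected side of SFS fitting, so the fitting contrast is unaffected.  A
`poisson` mode draws genealogies by rejection with weight
`1 - exp(-mu * total length)` per base — the infinite-sites segregating-site
ensemble — and is used where the classical expectations (SFS proportional to
1/i, divergence F_ST formulas) are asserted.

**Per-site streams.**  Each site derives its RNG stream from (seed, site
index).  Likelihood evaluations at nearby parameter values therefore share
their randomness until an event actually depends on the changed parameter —
common random numbers, which makes the composite-likelihood objective a
deterministic and relatively smooth function of the parameters.

## Ground-truth IBD

For haplotype pairs within one deme, the TMRCA process along a chromosome is
generated as a stationary Markov renewal process: segment-level TMRCAs are
drawn from the length-biased distribution Q(g) proportional to P(g)·2g
(P(g) the geometric coalescence mass along the deme's own size trajectory,
migration ignored), and segment genetic lengths are exponential with rate 2g
per Morgan.  This reproduces the pointwise TMRCA marginal P(g) and the
expected count of segments from generation g with length in [a, b) Morgans,
L·P(g)·2g·(e^(-2ga) - e^(-2gb)) — the same length theory the Ne estimator
inverts — while remaining cheap enough to tile thousands of centimorgans for
hundreds of pairs.  Successive segments are drawn independently (the renewal
approximation); the local TMRCA autocorrelation of the full sequential
coalescent is not reproduced, which matters for none of the length-spectrum
statistics used here.

## IBD detection

The detector is a hash seed-and-extend matcher: non-overlapping 64-site
words are hashed per haplotype; pairs sharing an exact word are segmented
under a sliding mismatch budget (at most 2 discordant sites within any
64-site window), trimmed to concordant end sites, and reported when at least
6 cM long.  Gap merging joins same-pair segments separated by at most 0.6 cM
and at most 1 discordant site.  One bespoke detector replaces the three
external tools used in the source study; the study's own robustness strategy
(consistency across detectors) becomes a truth-versus-detected consistency
test against the renewal-process ground truth.  At array-like densities
(about one site per 0.01-0.02 cM) the detector recovers planted tracts of
8 cM and longer with recall and precision above 0.9 and endpoint errors
under 0.5 cM.

## Recent-Ne estimation

The estimator inverts the segment-length theory above: expected counts per
length bin are a linear functional of the per-generation coalescence mass,
and the per-generation diploid sizes N_g (g = 1..50) maximise a Poisson
composite likelihood of the binned counts with a smoothness penalty on
log N_g — squared second differences plus a weak (0.2x) first-difference
ridge, the latter removing the curvature penalty's null space of linear
trends that the oldest, nearly uninformative generations would otherwise
exploit (L-BFGS-B; deterministic initialisation from a one-dimensional
constant-N scan).  The penalty weight scales with the number of pairs so the
optimum is invariant to duplicating the data.  Expectations
extend 150 generations beyond the fitted window at the terminal size so old
coalescence mass is not misattributed to the recent window; the last length
bin is open-ended, absorbing segments clipped by chromosome ends.  Detection
error is not deconvolved (the estimator is validated by recovery: a constant
N = 5,000 design is recovered within 15% in harmonic mean and a 5-fold
bottleneck 10 generations ago is localised between generations 5 and 20).
As in the published trajectory estimators, sizes just after a strong
bottleneck are the least identifiable: few ancestral haplotypes survive the
bottleneck, so older generations carry little information.

## SFS composite-likelihood fitting

The observable is the joint derived-allele-count spectrum of independent
segregating sites.  Expected entry probabilities under candidate parameters
are estimated by simulation, and the multinomial composite log-likelihood
CL = Σ m_e log p_e is maximised by a grid search over the free parameters
followed by local refinement.  Three choices keep the Monte-Carlo noise
commensurate with the (genuinely shallow) likelihood signal of one-parameter
split-time refits:

* **Pairwise marginals.**  With five populations the full joint tensor has
  ~10^8 cells and observed entries are almost never seen among the simulated
  sites; the composite likelihood instead multiplies the ten dense 41x41
  pairwise marginal tables (optionally only the pairs touching populations
  whose history the free parameter moves — the remaining tables are nearly
  ancillary and contribute mostly noise).
* **Rao-Blackwellised expected tables.**  Instead of placing one mutation
  per simulated tree, every branch contributes its allele-count pattern with
  weight branch length / total length — the per-tree conditional expectation
  of the placement.  This removes the mutation-placement multinomial noise
  from the expected tables entirely (about an order of magnitude in CL
  standard deviation at these designs).
* **Response-surface refinement.**  The profile over a step-1 grid is
  pooled by a local least-squares parabola whose vertex is the estimate;
  this averages the residual evaluation noise of many grid points instead
  of trusting the single noisiest maximum.  (Multi-parameter fits fall back
  to Nelder-Mead on the cached objective.)

Confidence intervals are parametric bootstrap (re-simulate under the fitted
model, refit, percentile interval).  The supported regime is one-parameter
and small-subset refits; a full joint fit of all eighteen island parameters
is possible but runs for hours rather than minutes.

The likelihood for a single split time is intrinsically shallow — the
published 95% interval for the oldest island split spans 38-57 generations —
so recovered point estimates at the 200,000-site design scatter by a few
generations around the truth even with noise-free evaluation.

## Quality control

Filters run in a fixed order — SNP call rate ≥ 98%, sample call rate ≥ 98%,
exact Hardy-Weinberg test (drop p ≤ 1e-6), minor-allele frequency > 0, then
relatedness pruning (method-of-moments pi-hat > 0.25 drops the worse-called
member; ties drop the lexicographically larger id).  The exact HWE p-value
follows the conditional (Levene-Haldane) distribution with the
probability-mass two-sided definition and matches an exact-rational
enumeration oracle to 1e-12.  `apply_qc` is idempotent.  The pi-hat
method-of-moments estimator uses the classical IBS-given-IBD expectations
without small-sample bias corrections; at array scale (thousands of sites)
duplicates, parent-child pairs and unrelated pairs are separated cleanly,
which is all the 0.25 threshold requires.

## Synthetic data versus real cohorts

The generator emulates phased, biallelic, SNP-array-like panels under the
fitted model, including ground-truth IBD.  It does not model array
ascertainment (an optional MAF filter stands in), genotyping or phasing
error, linkage between sites (except in the pairwise IBD engine), or
population substructure beyond the five demes.  Passing recovery tests
therefore demonstrates correctness of the inference chain under the model's
own assumptions — not robustness to the artefacts of real array data, which
the source study addressed operationally (multiple IBD detectors, QC
filters) rather than by modelling.

## Problem sizes

Default experiment sizes were chosen so each stage is a desk-scale run:
100,000 independent SNPs with 50 diploids per population for the D statistic
(about sixty seconds), 200,000-site joint spectra with 20 diploids per
population and 50,000 simulated sites per likelihood evaluation for the
split-time refits (about two minutes per refit), 100,000 SNPs with 100
diploids per population for the F_ST consistency check, and 500 haplotype
pairs over 3,000 cM for the Ne recovery design.

The smoothing weight is an analysis choice, not a constant of the method: a
few hundred segments cannot constrain fifty free per-generation sizes, so
near-constant-history analyses (such as the constant-N recovery experiment)
use a strong penalty (about 1000), while trajectory-shape analyses (such as
bottleneck localisation) use a weak one (about 2-5, the default).
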