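# Methods

This note documents the models and procedures implemented in sigmapop,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Data model and filtering

All statistics operate on validated equal-length alignments over
{A,C,G,T,-,N}.  Columns are 0-based; exported site lists use half-open
intervals.  `N` and `-` are distinct and preserved by I/O; both trigger
column exclusion.  Before any statistic we apply *complete deletion*:
every column containing a gap or ambiguous base is dropped, so π, S,
θ_W and D share a single fixed denominator ("sites examined").
Pairwise deletion would make π and S use inconsistent denominators.

Strand sense (`genome`, `antigenome`, `mrna`) is user-supplied metadata
(default `mrna`): Sanger products do not record strand, and the ADAR
module needs an explicit convention.

## ADAR hyper-mutation masking

ADAR deaminates A→I (read as G) in dsRNA with a 5′-neighbour preference
A = U > C > G; we treat {A, U/T} as *preferred* context and {C, G} as
non-preferred, since the published preference order puts A and U
jointly first.  Editing can hit the negative-sense genome or its
positive-sense replication intermediate, so a stored column is an
eligible A-site either on the stored sense (consensus A; edit observed
as A→G) or on the opposite sense (consensus T; edit observed as T→C),
never both.  Opposite-sense context reads the complement of the
3′-stored neighbour; because {A,T} is closed under complementation,
"preferred" reduces to: consensus neighbour (left for stored, right for
opposite) ∈ {A,T}.  Terminal columns lacking the neighbour are
non-preferred; consensus-N columns are ineligible.

Choices worth stating:

* Classification uses the 50% majority-rule consensus, not
  per-sequence context; consensus ties become N (ineligible) rather
  than IUPAC codes, so tie-breaking can never tilt the Fisher table.
* The Fisher test's unit is the *site* (mutated if ≥1 sequence carries
  the A→G/T→C change), not the sequence×site event, avoiding
  pseudo-replication from shared ancestry; the test is one-sided
  (enrichment at preferred sites) because the mechanism is directional.
  The p-value is the hypergeometric tail sum (scipy), verified against
  explicit enumeration for all tables with ≤12 eligible sites.
* Masking removes **all** preferred columns, not only those with an
  observed edit: an unedited preferred site remains a likely target and
  keeping it would leave mutations non-independent.  Masking is
  provably idempotent: only A/T-consensus columns are ever removed, so
  a surviving eligible site keeps its blocking C/G neighbour.

## Diversity and neutrality

S counts columns with ≥2 observed bases (multi-allelic sites count
once).  A *singleton site* requires every non-major allele to occur in
exactly one sequence.  π is the mean pairwise Hamming difference per
site over all C(n,2) pairs; multi-allelic sites contribute per
differing pair.  Tajima's constants a₁…e₂ are functions of n alone;
D = (k̄ − S/a₁)/√(e₁S + e₂S(S−1)), reported as not-applicable (None)
when S = 0 rather than 0.

Two significance routes, both two-tailed (the original tests, as run in
standard software, are two-tailed even when the reported pattern is a
negative D):

* **Coalescent null** (all sites): neutral constant-size genealogies
  with no recombination, conditioned on the observed S — exactly S
  mutations dropped on branches with probability proportional to
  branch length, each mutation's derived count being the leaf count of
  its branch.  Fixed-S conditioning matches what DnaSP-style software
  conditions on; it is the main caveat against exact reproduction of
  published p-values.  p uses the (b+1)/(m+1) estimator per tail,
  doubled and capped at 1, so p ≥ 1/(m+1).
* **Beta approximation** (synonymous sites, or anywhere cheap): D is
  taken to follow a rescaled beta on [D_min, D_max] with mean 0 and
  variance 1, the bounds being the large-S singleton / intermediate-
  frequency extremes (parity-dependent D_max).  Values outside the
  attainable range are clamped with a warning.

Synonymous restriction: a segregating site is synonymous iff every
observed base, substituted into the majority-consensus codon with the
other two positions held at consensus, encodes the same amino acid
(changes creating stops are non-synonymous).  The synonymous site count
is Nei–Gojobori (per-codon fraction of one-step synonymous changes,
averaged over sequences; codons with N/‑ skipped per sequence).  The
exact site-counting conventions of published desktop software are not
printed anywhere, so equivalence is documented as a choice, not
asserted.

## Population structure (K_ST)

K_j is the mean pairwise difference count within population j;
K_S = Σ (n_j/n)·K_j — the n_j/n weighting is the natural
generalization of the two-population definition to several
populations — and K_T is the mean over all pooled pairs;
K_ST = 1 − K_S/K_T.  Populations with fewer than two sequences are
excluded with a warning; K_T = 0 yields "not applicable".  The
permutation test shuffles labels holding group sizes fixed (K_T is
permutation-invariant, so only K_S is recomputed), one-tailed toward
large K_ST, with p = (b+1)/(m+1).

Because identical sequences are interchangeable, the permutation
distribution has an atom at the observed value (≈10% of permutation
mass at typical viral diversity), making the test somewhat conservative
on low-diversity data; the calibration experiment therefore uses data
at the diversity of the real alignments (S ≈ 40 over ~1000 sites),
where the empirical size at α = 0.05 is ≈0.04.

## Coalescent simulator

Time is in coalescent units (a lineage pair coalesces at rate 1).
Mutations fall as Poisson(θ/2 · total branch length), each hitting a
uniform column and shifting the current base to one of the other three
(finite-sites Jukes–Cantor, deliberately allowing back-mutation and
multi-allelic sites so the statistics' edge cases are exercised).  The
root sequence is uniform per column.  With clock rate c (subs/site/
year) and length L, one coalescent unit is θ/(2cL) years; growth rates
given per year are converted through the same factor.

Exponential growth: N(t) = N₀e^(−rt) looking backwards gives pairwise
rate e^(r_c t); the cumulative rate inverts in closed form, so waiting
times are sampled exactly (no numerical inversion or discretization).
A declining population (r_c < 0) leaves finite total rate, so a
genealogy may never coalesce; such draws raise an error that the ABC
layer converts to infinite distance.  Two demes: independent
constant-size coalescents merged into one pool at the split time; no
migration.

Validation: E[TMRCA] = 1 for n = 2, E[S] = θa₁ (Watterson), Poisson
consistency of mutation counts with branch lengths, split-time
monotonicity of K_ST, and distributional agreement of the fixed-S null
for D with an msprime-based re-implementation.

## Demography: regression-adjusted ABC

The model is the paper-standard one — exponential-growth coalescent,
strict clock with informative prior Normal(9.9×10⁻⁵, 3.6×10⁻⁵)
subs/site/year truncated at 0, doubling time ln(2)/r — but the
inference engine is ABC rather than full Bayesian phylogenetic MCMC:
draw (r, θ, clock) from priors (r ~ Uniform(−2, 2) per year so the
constant-size exclusion rule is meaningful; θ ~ log-uniform(0.1, 100)
as a scale parameter), simulate an alignment of the observed dimensions,
and summarize by (S, π·L, singleton count, Tajima's D, variance of
pairwise differences), standardized by prior-predictive standard
deviations (deterministic given the seed).

Plain rejection at desk-scale simulation counts carries a first-order
tolerance bias: the accepted cloud is wide enough that the posterior
median of r is dragged toward the prior's bulk (roughly two-fold too
fast growth in recovery experiments).  We therefore apply the standard
weighted local-linear regression correction on the accepted draws
(Epanechnikov weights in summary distance; growth adjusted on a logit
scale over its prior support, θ/clock/TMRCA on log scales), with the
standard wider tolerance (default acceptance fraction 0.05 of 20,000
simulations).  `adjust=False` recovers plain rejection; the
prior-recovery (acceptance = 1) and tolerance-monotonicity properties
are checked on that engine.

TMRCA converts to years per draw via θ/(2cL).  Intervals are central
95% by default (more stable than HPD at a few hundred accepted draws);
an HPD option exists.  Doubling times summarize only r > 0 draws.
Constant size is excluded iff the 95% interval of r strictly excludes
zero.

What recovery shows — and does not.  At the study scale (n = 50,
L = 1000, diversity matching the focal virus, true doubling time 1.5
years) the posterior median doubling time lands within a factor of two
of truth in ≥90% of replicates, and constant-size data give growth
intervals covering zero.  In low-diversity or extreme-growth regimes
the genealogy is nearly star-like and only the product θ·TMRCA is well
identified, so the growth-rate marginal widens toward the prior; the
pipeline then correctly declines to exclude constant size (as the
worked example shows at S = 17).  ABC with five summaries cannot be
expected to match full-likelihood MCMC in those regimes.

## Transmission

The analysis unit is the per-cross proportion of infected offspring
(pooling offspring would pseudo-replicate); group means are unweighted.
Control (double-uninfected) crosses are screened for any infected
offspring as a contamination check.

The Wilcoxon rank-sum statistic W is the rank-sum of the first group.
With no ties and n₁+n₂ ≤ 16 the two-sided p is exact, from the full
rank-sum null distribution (dynamic programming, verified against
itertools enumeration); otherwise ties take mid-ranks and p is a seeded
Monte-Carlo permutation estimate with the (b+1)/(m+1) correction —
transmission proportions tie often (many crosses at 1.0), so the
permutation path is the common one in practice.  Published W values
from other software may follow a different convention (rank-sum vs
Mann–Whitney U); ours is documented rather than claimed equivalent.
Tests are two-sided throughout.

Prevalence heterogeneity: Pearson χ² on the populations ×
{infected, uninfected} table (df = k−1), with a warning when any
expected count is below 5.

## Synthetic study conditions

The generator defaults emulate the study system: 87 sequences × 929
sites for the focal virus under exponential growth with doubling time
1.5 years; θ = 40 per sequence, chosen to reproduce the observed
diversity scale of the focal virus (π·L ≈ 2 under growth, i.e. π ≈
0.2%); clock 9.9×10⁻⁵; ADAR injection of ~4 events with geometric
tracts (mean 6) at preferred-context sites only; two demes of 20 split
2 coalescent units ago for the structure stage; 20/18/8
maternal/paternal/control crosses with 4–8 offspring each at rates
0.9/0.5; eight populations of 66 tested for prevalence.

What the generators do not emulate: sequencing error, alignment error,
rate heterogeneity among sites (no HKY/codon partitions — simulation is
Jukes–Cantor), recombination (absent or rare in negative-sense RNA
viruses), serial sampling dates, selection, and within-host dynamics.
Passing tests therefore show the statistics and inference behave
correctly under the stated models at the stated scales, not that the
pipeline is robust to those unmodelled features.

## Problem sizes in the test suite

Calibration and recovery experiments run at: 500×500 replicates for
null-p uniformity of the coalescent D test (n = 20, S = 10); 500
replicates (m = 199) for K_ST size and 3×40 for split-time
monotonicity; 100 injection replicates plus 500 clean replicates for
ADAR power/size; 20 recovery replicates at 20,000 simulations each for
the ABC fit.  These sizes give binomial standard errors comfortably
inside the asserted tolerances.
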