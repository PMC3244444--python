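# Methods

This note documents the models implemented in `protsel`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Codon substitution model

The core is a Goldman–Yang-style Markov model on the 61 sense codons of
the universal genetic code.  Instantaneous rates for pairs of codons
differing at exactly one nucleotide are

    q_ij = pi_j                     synonymous transversion
    q_ij = kappa * pi_j             synonymous transition
    q_ij = omega * pi_j             nonsynonymous transversion
    q_ij = omega * kappa * pi_j     nonsynonymous transition

with all multi-nucleotide changes forbidden and rows summing to zero.
The generator is rescaled so that `sum_i pi_i * (-q_ii) = 1`: one unit
of branch length is one expected codon substitution.  The chain is
reversible, so P(t) is computed from a single symmetric
eigendecomposition per (kappa, pi, omega) and reused across branches.

**omega = dN/dS** is the object of inference: below 1 purifying
selection, near 1 neutral evolution (or relaxed constraint), above 1
positive selection.

### Equilibrium frequencies

Four empirical options: `equal` (1/61), `F1X4` (pooled nucleotide
frequencies), `F3X4` (per-codon-position nucleotide frequencies,
default), `F61` (observed codon counts), all with add-one smoothing so
no frequency is zero.  When the choice matters, `choose_frequency_model`
selects by AIC of single-ratio fits (the candidates are not all nested,
so AIC rather than an LRT chain).  Note an intrinsic approximation of
the F-style parameterisations: the stationary distribution of the
renormalised product measure does not have exactly the input position
marginals (stop-codon exclusion shifts them), so an omega estimated
under empirical F3X4 carries a small (few percent, downward) bias
relative to a generator using the same nominal frequencies.  This is a
property of the frequency model, not of the optimiser, and is shared by
standard implementations.

### Site mixtures and branch partitions

* M0 — one omega for all sites and branches.
* M1a — proportions p0 at omega0 in [0,1) and p1 at omega = 1.
* M2a — M1a plus a third class with omega2 >= 1.
* M7 — omega ~ beta(p, q), discretised into K equal-probability
  categories represented by their medians (K = 10 by default,
  configurable; the beta is silent about category construction, and
  medians are the common convention).
* M8 — proportion p0 of beta(p, q) sites plus p1 = 1 − p0 at
  omega_s >= 1.
* two-ratio — one omega for a designated foreground clade, one for the
  background; the relaxation null pins the foreground omega to 1.
* free-ratio — an independent omega per branch.

Mixture likelihoods average class likelihoods per site; partitioned
models assign omegas per branch.  The foreground includes the clade's
stem branch by default (configurable): the stem is where the clade's
regime shift begins under the usual interpretation, and excluding it is
a one-flag change.

### Fitting

Bounded quasi-Newton (L-BFGS-B) on transformed parameters: log scale
for kappa (bounds [0.1, 20]), omegas ([1e-6, 50]), branch lengths
([1e-7, 20]) and beta shapes ([0.005, 99]); raw (0,1) bounds for
proportions, with stick-breaking for the M2a simplex.  Tolerances:
`ftol` 1e-9, `gtol` 1e-6.  Deterministic restarts (default 3) start
from model-specific alternative regimes — mixture surfaces, M2a and M8
especially, are multimodal (e.g. a neutral class absorbed into the
selected class), and small random jitter does not escape those basins;
qualitatively different starts do.  Any parameter can be pinned via
`fixed=...`, which both holds it and removes it from the free-parameter
count; branch lengths can be pinned to the input tree
(`optimize_branch_lengths=False`).  Columns containing a gap or
ambiguity in any taxon are dropped before fitting by default
(`cleandata=True`, logged); with `cleandata=False` missing tip states
are summed over all 61 codons in the pruning recursion.

### Per-branch dN and dS

The scaled generator's substitution flux `pi_i q_ij` is split into
nonsynonymous and synonymous parts, and each is divided by the
corresponding flux proportion at omega = 1 (the mutational null, same
kappa and pi).  This makes omega = 1 give dN = dS = t exactly and keeps
per-site normalisation internal to the model.  Root-to-tip omega for a
species is sum(dN) / sum(dS) along the unique root-to-tip path — the
ratio of sums, which weights branches by their substitutional content,
not the mean of per-branch ratios, which does not accumulate correctly.
Species with zero synonymous path substitutions get an undefined ratio
and are dropped from downstream regressions with a warning.

## Likelihood-ratio tests and the clade decision

Nested fits are compared by 2*(lnL_alt − lnL_null) against chi-square
with df equal to the extra free parameters: df 1 for one-ratio vs
two-ratio and fixed vs free two-ratio, df 2 for M1a/M2a and M7/M8.  The
chi-square reference is used as printed convention even though the
boundary null (omega2 at 1, p at 0) makes the tests conservative — the
calibration test verifies the empirical size stays below nominal.
Significance thresholds 0.05 (*) and 0.01 (**), no multiple-testing
correction, mirroring standard practice for a three-gene analysis.

The clade decision rule over (omega_fg_hat, test 1 = one-ratio vs
two-ratio, test 2 = fixed vs free two-ratio), both at 0.05
(configurable):

| test 1 | test 2 | omega_fg > 1 | label      |
|--------|--------|--------------|------------|
| sig    | sig    | yes          | Positive   |
| sig    | ns     | any          | Relaxation |
| otherwise              | .    | None       |

This is exhaustive and mutually exclusive; "significant but omega below
1" is None (it indicates stronger constraint, not relaxation).

## Bayes Empirical Bayes site classification

Sites are classified into class 1 (omega < 1), class 2 (omega ≈ 1) and
class 3 (omega > 1).  Empirical-Bayes responsibilities are averaged
over a discrete grid prior on the mixture parameters, each grid point
weighted by its integrated likelihood — this absorbs the plug-in
estimation error NEB ignores.  Grids use 10 midpoint values per
dimension: M1a (p0, omega0); M2a (p0, p1) on the simplex, omega0 in
(0,1), omega2 in (1,11); M8 p0 and omega_s in (1,11) with the beta
shape fixed at its MLE.  For M7 the grid is the 1-point MLE, i.e. BEB
coincides with NEB there — M7 has no selection parameter of interest,
and positive-selection flags are disallowed for M1a/M7 in any case
("not allowed" in reports).  A 1-point grid (or `neb=True`) reproduces
NEB exactly for every model.

Class mapping of mixture components: M1a/M2a components map by identity
(omega0 class, neutral class, selected class); beta categories map by
value with a ±0.05 neutrality band around omega = 1 (operationalising
"omega close to 1"); the extra M8 class is the class-3 component.
Sites are assigned their maximum-posterior class and reported with the
posterior mean and s.d. of omega.  Positive-selection flags require
class-3 posterior > 0.95 (one star) or > 0.99 (two stars).

Power caveat: with a realistic number of taxa and tree depth, class-3
flags at PP > 0.95 are rare when the selected class is small and
omega_s is moderate (≈3); replicates flagging zero sites are the normal
outcome at that effect size, which is why the false-flag acceptance
check also asserts the enrichment direction of class-3 posterior mass.

## Phylogenetic GLS

The regression of root-to-tip omega on relative testes mass uses error
covariance `C_ij = exp(-alpha * d_ij)` with d the patristic distance —
the exponential-decay ("evolutionary constraint") parameterisation;
alpha -> infinity recovers OLS, alpha -> 0 full exchangeability.  alpha
is estimated by maximising the profile GLS likelihood on a log scale
over [1e-4, 1e3] (1-D bounded search around closed-form GLS).  The
slope CI is the normal approximation conditional on alpha-hat (a
t-based CI is available by flag); significance is "CI excludes zero".
At n = 14 the normal interval empirically covers a true zero slope
about 87% of the time and the t interval about 92% — alpha estimation
and the plug-in variance both cost coverage; callers who need
calibrated intervals at small n should use `t_ci=True`.
The reported correlation is the GLS correlation coefficient computed
from phylogenetically corrected sums of squares — equivalently the
standardized slope in the whitened space.  Near-singular covariances
(condition number above 1e10) raise with the condition number reported.

Relative testes mass is `testes_mass / (a * body_mass^b)`.  The rodent
allometry coefficients are **required inputs** with no hidden defaults:
they come from an external regression that this package does not own.
The synthetic trait generator uses a = 0.031, b = 0.77 as its own
stated world.

## Functional-region annotation

* DNA-anchoring domains: maximal runs of >= 3 consecutive Arg/Lys
  qualify when a cysteine lies within `flank_window` residues (default
  5; "short peptide segments" is not quantified anywhere authoritative)
  on at least one side (`flank_mode="any"`; `"both"` available).  The
  reported interval extends to the qualifying cysteines; overlapping
  regions merge.
* Phosphorylation motifs: ProSite-style consensus patterns — PKC
  [ST]-x-[RK], PKA [RK]-[RK]-x-[ST], CK2 [ST]-x-x-[DE] — replacing the
  original web-service scans; overlapping matches are all reported.
  Kinase sets are per-gene configuration (protamine 1 uses PKC+PKA,
  protamine 2 PKC+CK2).
* Cleavage sites are user-configured reference positions (they derive
  from prior experimental work, not from sequence alone) mapped through
  the reference row's alignment gaps.

## Synthetic data: what it emulates and what it does not

The generator is an exact generative twin of the likelihood: root
codons from pi, site classes from the mixture, branch transitions from
P(t) (or event-by-event Gillespie when realized substitution counts are
wanted).  Bundled trees are *synthetic stand-ins* shaped like the study
system — a 17-taxon ingroup+outgroup tree, a 16-taxon clade tree with
an 8-taxon foreground, a 14-taxon trait tree — with plausible but
invented branch lengths.  `site_tree()` scales the study tree 4x
(several substitutions per site over the tree), the regime site-level
inference actually needs; the unscaled tree is deliberately
conservative.  Trait pairs draw both predictor and noise from
`N(0, exp(-alpha d))`, so the GLS standardized slope estimates the
nominal correlation `slope / sqrt(slope^2 + noise_sd^2)`.

Not emulated: indels and alignment error (alignments are simulated
gap-free), recombination, selection regimes changing within a branch,
non-universal codes, and base-composition heterogeneity across
lineages.  A green simulation-recovery test therefore establishes
estimator correctness and calibration under the model's own
assumptions — not robustness to their violation.

Fixture defaults: 165-codon alignments (protamine-2-precursor scale),
kappa 2, background omega 0.3, foreground regimes at 2.44 (positive),
1.0 (relaxed), and a uniform 0.3 (neutral); trait world alpha 8.17 with
correlation −0.574.

## Known limitations

* Free-ratio omegas on the two root-adjacent branches are only weakly
  separable (reversibility); root-to-tip sums are unaffected.
* M8 beta-shape parameters (p, q) are weakly identified when p is
  small; omega_s and p0 are the reliably recovered quantities.
* The pGLS alpha MLE is noisy at n = 14 and often hits the search
  bounds on simulated data; slope and correlation are insensitive to
  this in the regimes tested.
* Site-class percentages depend on the ±0.05 neutrality band for beta
  categories; the band only affects M7/M8 class summaries, not flags.
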