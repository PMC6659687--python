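# Methods

`matrophylo` implements the comparative-phylogenetics toolchain used to ask
how female provisioning mode (lecithotrophy vs placentotrophy), male
pre-copulatory sexual selection, and speciation rate interact in livebearing
fishes (subfamily Poeciliinae): trait scoring, ancestral-state
reconstruction, correlated evolution of trait pairs, trait-dependent
diversification, and the false-positive safeguards those diversification
tests require. Everything runs equally on real data (a time-calibrated tree
plus a species-by-trait table) and on the package's own simulators, which
carry full latent histories so that every estimator can be checked against
known truth.

## Trait scoring

The matrotrophy index (MI) is the ratio of offspring dry mass at birth to
egg dry mass at fertilization. It is estimated per population from the OLS
slope *b* of ln(embryo dry mass in mg) on developmental stage (the standard
0–50 staging scale): MI = exp(50·*b*). The slope corresponding to a given MI
is ln(MI)/50; for MI = 0.7 this is −0.00713, which reproduces the
conventional −0.0071 boundary at 4 decimal places only under natural
logarithms — the reason base-e is fixed throughout.

Placentotrophy is scored conservatively, to avoid false positives. A species
is *trustworthy* when its pooled collection has more than 7 broods spanning
a stage range above 25 (pooling follows the reading that these thresholds
apply to "the collection"; a per-population switch exists). A trustworthy
species is scored placentotrophic when either (1) some population's slope is
significantly greater than 0 (one-sided *t*, n−2 df, α = 0.05), or (2) at
least two populations have estimated MI > 1 with slopes significantly above
the MI = 0.7 boundary. Anything else — including insufficient data — scores
0. No multiplicity correction is applied; the α is a fixed scoring rule, not
an inference.

The male sexual-selection index is the count of courtship, dichromatism and
ornamentation present (0–3), missing if any component is missing. Continuous
male traits (relative gonopodium length, size-dimorphism index) are
binarized by median split: the lowest ⌈n/2⌉ species become state 0, and
boundary ties all go to 0 (the "bottom 50%" reading; the tie rule is our
choice and is documented because nothing in the data dictates it).

## Trees

`TimeTree` is a rooted binary tree with branch lengths in Myr, stored in
flat postorder arrays. Polytomies are resolved deterministically (children
ordered by smallest descendant label, merged pairwise with zero-length
edges) because every downstream likelihood assumes a binary tree; the
resolution is logged and likelihood-neutral. Ultrametricity is checked as
max |depth − mean depth| / mean depth ≤ 1e-6; failing trees are accepted
with a warning (dating error is tolerated) except in the SSE likelihoods,
which require an ultrametric tree and refuse otherwise. Before MCMC the
tree is rescaled to a mean edge length of 0.1 — any constant works, since
rates back-transform through the recorded scale factor; 0.1 keeps rates in
a numerically comfortable range under the U(0,20) hyperprior.

## Mk models and ancestral states

Likelihoods use Felsenstein pruning with per-node rescaling; transition
matrices come from a batched scaling-and-squaring matrix exponential.
Equal-rates (ER) and all-rates-different (ARD) generators are fitted by
bounded L-BFGS-B on log rates (bounds 1e-8–1e3 on the mean-edge-0.1 scale,
5 multistarts from seeded log-uniform draws) and compared by AIC. Marginal
("scaled likelihood") node posteriors come from the standard two-pass
inside/outside algorithm. The root prior defaults to uniform — matching
the common ML-reconstruction default — with stationary and FitzJohn
options; the choice is exposed because reconstructions can be sensitive
to it.

Parsimony uses unit-cost Sankoff down- and up-passes, returning the minimum
change count and the full most-parsimonious-reconstruction state sets.

Stochastic character maps are drawn by joint node-state sampling (root from
its conditional, children given parents) followed by endpoint-conditioned
path sampling per branch: rejection sampling with a forced first jump for
unequal endpoints, falling back to exact uniformization sampling after 10⁴
rejections, so sampling always terminates. Origin/loss counts are provided
two ways — from max-probability node states (ties broken toward absence,
the conservative direction for a gain count) and as posterior means over
maps — because a reconstruction figure can be read either way.

## Correlated evolution of trait pairs

Two binary traits define four joint states (1=(0,0), 2=(0,1), 3=(1,0),
4=(1,1)). The independent model gives each trait its own gain and loss rate
(4 parameters); the dependent model lets each single-trait rate depend on
the other trait's background state (8 parameters: q12, q13, q21, q24, q31,
q34, q42, q43). Dual transitions are fixed at zero in both, the standard
Discrete formulation. Species missing either trait are dropped before
pruning the tree.

The reversible-jump sampler places each rate either in a zero bin or at a
positive value with an Exp(mean *m*) prior, *m* itself sampled on (0, 20).
Moves: a multiplicative log-normal update of one free rate; a jump that
toggles a rate between zero and a fresh prior draw (prior-as-proposal, so
the jump acceptance reduces to the likelihood ratio under a uniform prior
over zero-bin configurations); and a random-walk update of *m*. Treating
*m* hierarchically (re-sampled along the chain) is our resolution of the
ambiguous phrase "seeded from a uniform hyperprior"; a fixed-mean switch
exists. Shared positive bins (rates set equal to each other) are not
implemented — the zero bin is what the Z-score machinery consumes; this is
the one deliberate narrowing of the reversible-jump move set, and results
are validated against quadrature oracles rather than against any reference
program. Chains run in triplicate by default; effective sample sizes are
computed per rate (initial-positive-sequence truncation) and low values
warn rather than fail.

Z-scores are the percentage of posterior samples in which a rate sits in
the zero bin; Z < 5% marks a supported pathway. Model comparison uses
stepping-stone marginal likelihoods: power-posterior path with
Beta(0.3, 1)-quantile spacing (the stone counts are configurable; spacing
is our choice, concentrated near the prior where the integrand moves
fastest), prior stone sampled iid, warm starts between stones, per-stone
contributions combined in log space with a delta-method Monte-Carlo SE.
Bayes factors are 2·Δlog-ML with the conventional labels (>2 positive,
>5 strong, >10 very strong). Harmonic-mean estimates are deliberately
absent.

Default chain lengths are desk-scale (2×10⁶ iterations, burn-in 10⁵,
thinning 200); the published-scale preset (4×10⁸ iterations, 200 stones ×
200 000 iterations) is a config choice, not a default.

## Trait-dependent diversification

BiSSE couples a binary character to state-dependent speciation λ_i and
extinction μ_i (6 parameters); MuSSE generalizes to k states (k = 4 gives
4 + 4 + 12 = 20 — the 4-state chain allows all 12 transitions rather than
stepwise index changes only, matching that parameter count). The two-trait
main-effects model writes λ(a,b) = λ0 + a·λA + b·λB (likewise μ) over the
four joint states with four single-trait transition rates — 10 parameters;
proposals or optimizer steps implying a negative per-state rate are
rejected. The main-effects model is evaluated by exact expansion to the
4-state MuSSE, so the reparameterization is invertible by construction and
asserted in tests.

The likelihood integrates the coupled E/D ODEs branch-by-branch with a
fixed-step RK4 whose step count scales with branch length × dominant rate
(floor of 20 steps per branch), extinction probabilities clamped to [0,1],
and per-node log rescaling; a `steps_mult` knob refines the grid, and the
tests' fine-grid oracle is the same scheme at ~100× resolution. Tips enter
with D = f·1[state], E(0) = 1 − f, where f = n_scored/n_described is the
global sampling fraction (state-specific fractions are available but off
by default, following the global wording of the sampling-fraction
correction). At the root, states are weighted by their share of the data
likelihood (FitzJohn) and the likelihood is conditioned on survival of
both root lineages; equal weights and fixed-root options exist. The
unresolved-tips correction and time-varying or hidden-state models are out
of scope.

ML fits optimize log rates (main-effect deltas on a natural scale) with
bounded multistart L-BFGS-B from a character-independent heuristic start
(Yule-like λ, μ = λ/5, q = λ/10). Constraints are declarative strings
("lambda1==lambda0" ties, "muA==0" fixes), and nested fits are compared by
AIC and by chi-square LRT with df equal to the difference in free
parameters. The Bayesian layer is a Metropolis sampler under independent
Exp(rate 1/(2r)) priors — r the character-independent diversification
rate, so every rate's prior mean is 2r — started from the MLE, with the
first 10% of generations discarded as burn-in. Main-effect deltas get the
symmetric (Laplace-shaped) version of the same density so the prior stays
proper while leaving the sign free; this is our choice and matters only
through the prior's mild shrinkage toward 0. Net diversification d_i =
λ_i − μ_i is reported per sample, with both posterior means and medians
(since a "two-fold" contrast could be read off either).

## Safeguards against SSE false positives

The tip-rate test computes each tip's equal-splits measure
ES = Σ_j l_j / 2^(j−1) (j = 1 at the terminal edge, walking rootward) and
compares mean 1/ES between states. The null re-simulates the character on
the same tree under its fitted ER Mk rate (ER because that is the
typically best-fitting reconstruction model; the root of each simulation
is drawn from the ER stationary distribution), and the two-tailed p is
2·min(tail proportions) with the +1 correction, capped at 1. Monomorphic
simulations are redrawn so the null count stays fixed.

The parametric-bootstrap calibration re-simulates the trait on the real
tree under the fitted 2-rate chain from the ancestral (absent) state,
repeats the equal-rates vs free-rates BiSSE comparison per replicate, and
takes the empirical 5th percentile (nearest-rank: the ⌈0.05·n⌉-th smallest,
i.e. the 5th smallest of 100) of the null p-values as the calibrated
cutoff. When the naive p < 0.05 rule is anticonservative the empirical
cutoff falls below 0.05, so calibrated rejections are a subset of naive
ones. A gains-only null chain is a switch; the default uses both fitted
directions.

## Synthetic data

Generators are deterministic given their seed and record full latent
histories. Trees grow forward from a crown (two-lineage) start; stopping
at n tips cuts uniformly inside the waiting interval after the n-th
extant lineage appears — simple forward stopping, not the
generalized-sampling algorithm, a known small-n bias that is acceptable
here because every comparison is generator-vs-estimator on the same
convention. Total extinction retries (counted). The state-dependent
simulator adds per-lineage character transitions; its state-symmetric
special case is distributionally checked against birth–death trees with an
independently overlaid Mk character. Brood data follow
ln(mass) = ln(egg mass) + (ln(MI)/50)·stage + N(0, σ), stages uniform over
a window of the 0–50 scale.

Default study conditions used by the tests and the acceptance script:
scoring recovery at true MI ∈ {0.6, 1.0, 3.0} with 12 broods, stage range
40, σ = 0.15; BiSSE recovery at λ0 = 0.1, λ1 = 0.2, μ = 0.03, q = 0.01 on
200-tip trees; calibration nulls on 60–80-tip trees with an ER character
rate of 0.8 per unit tree depth (variable but not saturated). What the
simulators do not emulate: dating error, non-random taxon sampling,
state-dependent sampling, among-lineage rate heterogeneity, and
measurement error in trait scoring — so green tests certify the estimators
under their own model assumptions, not robustness to violations of them.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run everything at desk scale:
oracle equivalence on 200 random parameterizations of ≤6-tip trees
(|ΔlnL| < 1e-8) and 30 SSE cases against the fine grid (< 1e-6);
factorization on 50-tip trees (< 1e-6); parameter recovery with 60–100
replicates; calibration with 12–15 outer replicates of 19 null fits each
(19 nulls make the nearest-rank 5th percentile the first order statistic,
giving an exact 1/20 rejection probability under exchangeability); the
tip-rate type-I check on 25–40 trees of 100 simulations each;
stepping-stone validation with 40 stones × 600 iterations against 1-D
quadrature (< 0.1 log units); prior recovery within 3 ESS-adjusted
Monte-Carlo standard errors. The pipeline's per-stage defaults in
`RunConfig` are similarly desk-scale and are the knobs to raise for
published-scale runs.

## Known limitations

* The RJ sampler's model space is zero-bin-only (no equal-rate bins).
* Marginal-likelihood SEs treat stones as independent after ESS
  adjustment; very short stones underestimate the error.
* The n-tip stopping rule biases small-tree shape relative to the
  generalized sampling algorithm.
* ER is the default null-model class for both safeguards; a trait whose
  real gain/loss asymmetry is strong would warrant the ARD switch.
* The two-pass marginal reconstruction and the simmap sampler assume the
  fitted rates are known; parameter uncertainty is not propagated into
  node posteriors.
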