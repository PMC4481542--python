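# Methods

`monma` jointly synthesizes two correlated outcomes, labelled R (e.g.
response) and D (e.g. dropout), over a connected network of treatments
compared in 2- and 3-arm randomized trials.  This note records the models,
their assumptions, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## The linear model

All observed contrasts are stacked into `Y = X beta + delta + epsilon`.
`beta` holds the *basic parameters*: one relative effect per non-reference
treatment and outcome, `2 (N_T - 1)` in total when both outcomes are
observed.  The design matrix encodes consistency: a contrast between two
non-reference treatments B and C contributes a row `beta_C - beta_B`, so all
indirect comparisons are linear combinations of the basic parameters.  Every
contrast in a study is taken against the study's first-listed (base) arm,
which fixes where the shared-arm covariances of three-arm studies go.  A
treatment observed for only one outcome has no basic parameter for the other
outcome; the design builder raises an error rather than silently dropping
data, and the caller excludes such (treatment, outcome) pairs explicitly.

## Model 1: structured within- and between-study covariance

Random effects `delta` are normal with a block-diagonal covariance.  Under
two simplifying assumptions — heterogeneity equal across comparisons
(`tau_{AB,o}^2 = tau_o^2`), and equal cross-comparison cross-outcome
correlations — a two-arm study's block is the 2x2 matrix with variances
`tau_R^2, tau_D^2` and covariance `rho_tau tau_R tau_D`; a three-arm study's
4x4 block has same-outcome cross-comparison covariance `tau_o^2 / 2` (from
the shared base arm) and cross-outcome cross-comparison covariance
`rho_tau tau_R tau_D / 2`.  These blocks are positive semidefinite for any
`|rho_tau| < 1`.

Sampling errors `epsilon` are normal with per-study covariance
`Sigma_i = Sigma_{i,1} + rho_i Sigma_{i,2}`.  For binary outcomes the
data-estimated part uses the standard cell-reciprocal estimators: row
variance `1/e_A + 1/f_A + 1/e_B + 1/f_B` and shared-arm covariance
`kappa = 1/e_A + 1/f_A` for two contrasts sharing arm A.  The correlation
skeleton `Sigma_{i,2}` carries `sigma sigma'` in same-comparison
cross-outcome cells and `sigma sigma' / 2` in cross-comparison cross-outcome
cells.  The halving follows from assuming arms balanced in size and
treatments of comparable effect (so all contrast variances of an outcome are
roughly equal within a study), which implies that the cross-comparison
correlation is half the same-comparison one.  The package checks this
identity by direct simulation (`verify_half_rho_identity`): replicated
balanced three-arm trials with copula-correlated binary outcomes give an
empirical ratio converging to 1/2; with strongly unbalanced arms the
identity visibly fails, and the function warns.

### Positive definiteness and the rho limits

`Sigma_{i,1}` contains data-estimated `kappa` terms, so `Sigma_i(rho)` is
not positive definite for every `rho` in (-1, 1).  Rather than repairing the
matrix spectrally, the within-study correlation is *truncated*: for each
study the open interval `(l_i, u_i)` containing 0 on which the smallest
eigenvalue stays positive is found by bisection (tolerance 1e-6, exploiting
concavity of the smallest eigenvalue in `rho`, so each side of zero has at
most one crossing), and any prior on `rho` is restricted to the
intersection of these intervals (per group of studies, for grouped models).
Limits depend only on data; they are computed once per fit and echoed in the
run log.  Two-arm two-outcome blocks always give (-1, 1); single-outcome
blocks have no `rho` dependence at all.

## Model 2: hybrid overall correlation

The alternative model folds both variability layers into one covariance
`Omega_i` with diagonal `zeta = sigma^2 + psi_o^2`, same-comparison
cross-outcome correlation `rho_h`, same-outcome cross-comparison correlation
1/2, and cross-comparison cross-outcome correlation `rho_h / 2`.  `psi_R,
psi_D` absorb between-study variation (comparable to, but not identical
with, `tau_R, tau_D` unless sampling variances are small), and `rho_h` is a
single hybrid of the within- and between-study correlations.  `Omega_i` is
positive definite for every `|rho_h| < 1`, so no truncation is needed —
the practical reason to prefer this model when shared-arm covariances are
unavailable.  With `psi = 0` and balanced-arm `kappa = sigma sigma'/2` the
two models' within-study structures coincide exactly (tested).

## Inference

Both layers are normal, so the random effects are integrated analytically
and MCMC runs on the marginal likelihood: per study,
`y_i ~ N(X_i beta, Sigma_i(rho_i) + Delta_i)` (Model 1) or
`y_i ~ N(X_i beta, Omega_i)` (Model 2).  Studies reporting one outcome
contribute the corresponding sub-vector density — this is the mechanism by
which the joint model "borrows strength" for the missing outcome; nothing is
imputed.

The sampler is Metropolis-within-Gibbs:

* `beta | rest` is drawn exactly from its conditional normal (prior
  `N(0, 100^2 I)`), using batched small-matrix factorizations of the
  per-study covariances grouped by block dimension;
* each variance/correlation parameter takes an adaptive random-walk
  Metropolis step (target acceptance 0.44, scale adapted only during
  burn-in so the post-burn-in kernel is fixed).  Proposals outside the
  truncated uniform support are rejected, which implements the truncated
  priors exactly;
* per-study `rho_i` (optional `rho_model="per_study"`) update only their own
  study's likelihood contribution.

Prior scenarios: I (univariate; all correlations frozen at 0 in the same
code path, so equivalence with separate per-outcome fits is a testable
property), II.a (`rho, rho_tau ~ U(-1,0)`), II.b (`rho ~ U(-0.7,-0.5)`),
II.c (`rho = -0.7` fixed), II.d (separate `rho` for active-vs-active and
active-vs-placebo studies; a study counts as active-vs-placebo if any arm is
the designated placebo), III (hybrid model, `rho_h ~ U(-1,0)`,
`psi ~ U(0,1)`).  Heterogeneity priors are uniform on the SD scale, `U(0,1)`
by default on the log-OR scale (configurable upper bound for other effect
scales), and any prior bound can be overridden per parameter — e.g.
`rho ~ U(-1,1)` to check a negativity assumption.

Defaults are desk-scale: 4 chains x 25,000 iterations, 5,000 burn-in,
thinning 10.  Production runs (e.g. full replication of a published
68-trial analysis) use 1,000,000 iterations with thinning 100 after a 5,000
burn-in via the same configuration object.  Chains are seeded from a single
`SeedSequence`, making runs byte-reproducible.  Split-chain R-hat and ESS
(via ArviZ) are attached to every fit; R-hat > 1.05 raises a warning, never
an error.  Initial values: `beta` from a GLS solve at the chain's randomly
drawn initial variance parameters; variance/correlation parameters start
uniformly inside the middle of their support, giving over-dispersed-enough
starts for split-chain diagnostics at these chain counts.

## Ranking and precision comparison

Per posterior draw, treatments are ranked on their relative effects versus
the reference (direction must be stated explicitly per outcome; ties, which
have probability zero for continuous draws, get midranks).  SUCRA is
computed by the cumulative-rank formula and equals the normalized mean rank
`(N_T - E[rank]) / (N_T - 1)` (identity tested to 1e-12).  The
two-dimensional ranking plots SUCRA for one outcome against the other over
the treatments ranked for both.  `precision_gain` reports the per-comparison
percent reduction in OR credible-interval width of a joint fit relative to a
univariate fit, plus the average over active-versus-reference comparisons
(an all-pairs option exists via explicit pair lists); negative values
(widening) are reported, not clipped.

## Synthetic data

The generator draws, per study: a 2- or 3-arm treatment set (placebo-anchored
with probability 0.7; designs resampled until the network is connected);
true contrasts from the between-study law above; arm sizes lognormal around
150 patients (balanced within a study, matching the balanced-arm assumption
of the covariance structure); and per-patient correlated binary outcomes
from a Gaussian copula, so within-study correlation arises from patients
contributing to both outcomes rather than being injected at the contrast
level.  A configurable fraction of studies (default 0.25, weighted 95:5
towards dropping R, mirroring the empirical pattern that response is the
under-reported outcome) loses one outcome wholesale.  The copula parameter
maps monotonically to the induced contrast-level correlation;
`calibrate_latent_rho` inverts this map by bisection on a seeded empirical
estimate.  Note a hard constraint of binary outcomes: the attainable
correlation between two Bernoulli variables (phi coefficient) is bounded by
their margins — e.g. risks (0.4, 0.3) cannot produce a correlation of -0.6
— so strongly correlated settings must use baseline risks near 0.5; the
calibration raises an informative error when a target is infeasible.  Zero cells are avoided by default (clipping event counts to
[1, n-1]); a flag re-enables them for continuity-correction tests, where
the default policy adds 0.5 to all four cells of the affected study-outcome
table (a "none" policy errors instead).

Default generating values (60 studies, 6 treatments, `tau_R = 0.3`,
`tau_D = 0.35`, `rho_tau = -0.8`, baseline risks 0.4/0.3, response effects
0.2-0.8 and dropout effects -0.4-0 on the log-OR scale) are chosen to look
like a realistic psychiatric-drug network: moderate heterogeneity
(`tau^2` of order 0.1), strongly negative between-study correlation, mostly
placebo-controlled two-arm trials.

What the generator does *not* emulate: selective (outcome-dependent)
reporting — missingness is completely at random; unbalanced arms; more than
three arms; continuous or time-to-event outcomes (the contrast-level loader
accepts those for fitting, but they are not simulated); patient dropout
actually censoring the response measurement (the two outcomes are measured
on all randomized patients).  Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the model's own assumptions,
not robustness to informative missingness or design imbalance.

## Numerical details and edge cases

* All block constructions assert symmetry; positive definiteness is
  enforced by Cholesky factorization wherever theory guarantees it, and a
  factorization failure inside the truncated support is a hard error naming
  the study.
* Contrast-level input with a missing shared-arm covariance for a three-arm
  study imputes `kappa = min(sigma_1^2, sigma_2^2)/2` (the balanced-arm
  value), with a warning; supplying a `kappa` column overrides this.
* More than three arms is refused explicitly: the covariance structures are
  derived only up to three arms, and generalizing them is an extension
  point, not an implicit behaviour.
* The default reference treatment is the one appearing in the most study
  arms (ties broken lexicographically); any treatment can be chosen, and
  all pairwise relative-effect distributions are invariant to that choice
  (tested by re-expressing fixed draws in two parameterizations).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at desk scale, chosen so the
whole suite completes in minutes on one core: recovery uses 5 replicate
60-study networks at 4x25k iterations (the full 50-replicate version of the
same check is a straightforward loop for a nightly run); the univariate-
equivalence and borrowing-strength checks use 24- and 40-study networks with
longer thinned chains; the half-rho simulation uses 1e5 replicates; the
rho-limit oracle scans 100 random blocks on a 1e-3 grid.
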