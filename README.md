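# monma — multiple-outcomes network meta-analysis

`monma` jointly synthesizes **two correlated outcomes** (say response `R`
and dropout `D`) over a **network of treatments** compared in 2- and 3-arm
randomized trials.  It is written for meta-analysts who today run one
network meta-analysis per outcome and lose the information that the same
patients generate both outcomes: joint modelling propagates that
correlation, tightens the credible intervals of the under-reported outcome
by borrowing strength from the fully reported one, and can change the
treatment ranking.

## The models

All contrasts are stacked into the linear model

```
Y = X beta + delta + epsilon
```

where `beta` holds one basic parameter per non-reference treatment and
outcome and `X` embeds the consistency equations
(`beta_BC = beta_AC - beta_AB`).

**Model 1 (structured)** keeps the two variability layers separate:
`delta ~ N(0, Delta)` with per-study blocks built from `tau_R, tau_D` and
the between-study correlation `rho_tau` (three-arm blocks carry the factor
1/2 on shared-arm cells), and `epsilon ~ N(0, Sigma_i(rho_i))` with
`Sigma_i = Sigma_i1 + rho_i Sigma_i2`: variances and shared-arm covariances
`kappa` estimated from arm-level counts, and a single within-study
correlation `rho_i` scaling the cross-outcome cells (cross-comparison cells
halved, by the balanced-arm argument `rho** = rho*/2`).  Because the
`kappa` terms are data, `Sigma_i(rho)` is positive definite only on a
per-study interval `(l_i, u_i)`; the package finds these limits by
bisection on the smallest eigenvalue and truncates the prior on `rho`
accordingly.

**Model 2 (hybrid)** uses one overall covariance `Omega_i` per study with
inflated variances `zeta = sigma^2 + psi^2` and a single *hybrid*
correlation `rho_h` amalgamating within- and between-study correlation.  It
needs no within-study covariances and is positive definite for any
`|rho_h| < 1`.

Fitting is Bayesian: the random effects are marginalized analytically and a
Metropolis-within-Gibbs sampler draws `beta` from its exact conditional
normal and each variance/correlation parameter with an adaptive random-walk
step on its (truncated) uniform prior.  Treatment rankings use SUCRA
(surface under the cumulative ranking curve: 1 = certainly best, 0 =
certainly worst).  See `docs/methods.md` for assumptions, prior scenarios
(I, II.a–d, III) and numerical details.

## Worked example

`examples/simulate_and_fit.py` simulates a 60-trial, 6-treatment network
(25% three-arm, 25% of trials reporting only one outcome, generating
`tau_R^2 = 0.09`, `tau_D^2 = 0.1225`, `rho_tau = -0.8`) and fits the
negative-correlation scenario II.a.  The variance-parameter rows of the
printed summary from one run:

```
         median  lower  upper   mean     sd       ess   rhat
tau_R^2   0.131  0.071  0.229  0.136  0.041  5721.087  1.000
tau_D^2   0.128  0.075  0.213  0.133  0.036  6529.889  1.000
rho      -0.543 -0.902 -0.079 -0.532  0.231  3838.070  1.001
rho_tau  -0.815 -0.990 -0.483 -0.796  0.136  3524.189  1.000
```

Each `beta[T,o]` row (not shown) is the log odds ratio of treatment `T`
versus the reference with its 95% credible interval; `tau^2` are the
between-study heterogeneity variances, `rho` the common within-study
correlation between the two outcomes' contrast errors and `rho_tau` the
correlation of the true study-level effects — here recovered close to the
generating -0.8.  The other examples demonstrate the covariance blocks and
PD limits (`covariance_blocks.py`), precision gain for an under-reported
outcome (`borrowing_strength.py`), two-dimensional SUCRA ranking
(`ranking_demo.py`), and a production-scale replication recipe for a real
68-trial acute-mania network (`replicate_acute_mania.py`; requires the
trial-level data, which are not shipped).

A thin CLI wraps the same library calls:

```sh
monma simulate --seed 7 --out data/
monma fit --data data/arms.csv --scenario II.a --reference T0 --seed 42 --out run/
monma rank --data data/arms.csv --scenario II.a --direction-r higher \
           --direction-d lower --out run/
monma compare --data data/arms.csv --scenario II.a --out run/
```

Every run writes a `manifest.json` (command, config, seed, input hashes), and
fixed seeds reproduce draws exactly.

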