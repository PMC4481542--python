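"""Quantify borrowing of strength for an under-reported outcome.

When 30% of studies fail to report the response outcome and the two outcomes
are negatively correlated, the joint model recovers precision for response by
exploiting the fully reported dropout outcome.  This script compares the
credible-interval widths of the response odds ratios between a univariate
fit on the reduced data and the joint fit.
"""

from monma import (
    MCMCConfig, ScenarioConfig, SimulationConfig, calibrate_latent_rho, fit,
    or_forest_plot, or_summary, precision_gain, simulate_network,
)

# baseline risks near 0.5 so that a contrast-level correlation of -0.6 is
# attainable for binary outcomes (phi is bounded by the margins)
latent = calibrate_latent_rho(-0.6, p_R=0.5, p_D=0.45, n_rep=20_000, seed=0)
print(f"patient-level copula correlation for contrast-level rho=-0.6: "
      f"{latent:.3f}")

cfg = SimulationConfig(
    n_studies=40, latent_rho=latent, missing_prob=0.30,
    missing_outcome_weights={"R": 1.0, "D": 0.0},
    baseline_p={"R": 0.5, "D": 0.45}, seed=42,
)
ds = simulate_network(cfg, seed=42).to_contrasts()
mcmc = dict(iterations=20_000, burn_in=5_000, thinning=10, chains=4)

joint = fit(ds, ScenarioConfig("II.a", reference="T0",
                               mcmc=MCMCConfig(**mcmc, seed=3)))
univariate = fit(ds.restrict_outcome("R"),
                 ScenarioConfig("I", reference="T0",
                                mcmc=MCMCConfig(**mcmc, seed=4)))

uni_or = or_summary(univariate, "R")
joint_or = or_summary(joint, "R")
gain = precision_gain(uni_or, joint_or)
print(gain.round(3).to_string())
or_forest_plot({"univariate": uni_or, "joint II.a": joint_or},
               path="forest_response.png")
print("forest plot of the response ORs written to forest_response.png")
print(
    "\nPositive reduction_pct means the joint model produced a narrower "
    "95% interval for that response odds ratio than the univariate model "
    "fitted to the same reduced data."
)
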