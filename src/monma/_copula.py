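"""Gaussian-copula cell probabilities for two correlated binary outcomes."""

from __future__ import annotations

import numpy as np
from scipy import stats


def bivariate_cell_probs(p_r: float, p_d: float, latent_rho: float) -> np.ndarray:
    """Joint cell probabilities [p11, p10, p01, p00] for two Bernoulli margins.

    A patient's pair of binary outcomes is generated by thresholding a latent
    bivariate standard normal with correlation ``latent_rho`` at the normal
    quantiles of the marginal probabilities.  First index: outcome R event;
    second: outcome D event.
    """
    if not (0.0 < p_r < 1.0 and 0.0 < p_d < 1.0):
        raise ValueError(f"marginal probabilities must be in (0,1): {p_r}, {p_d}")
    if not -1.0 < latent_rho < 1.0:
        raise ValueError(f"latent correlation must be in (-1,1): {latent_rho}")
    z_r = stats.norm.ppf(p_r)
    z_d = stats.norm.ppf(p_d)
    cov = np.array([[1.0, latent_rho], [latent_rho, 1.0]])
    p11 = float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([z_r, z_d]))
    p11 = min(max(p11, 0.0), min(p_r, p_d))
    p10 = p_r - p11
    p01 = p_d - p11
    p00 = 1.0 - p11 - p10 - p01
    return np.array([p11, p10, p01, p00])
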