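"""Structured covariance matrices for the two joint-synthesis models.

Model 1 keeps within- and between-study variation separate.  The between-study
(random-effects) block for a two-arm study reporting both outcomes is

    Delta_2x2 = [[tau_R^2,            rho_tau tau_R tau_D],
                 [rho_tau tau_R tau_D, tau_D^2           ]]

and for a three-arm study, under equal heterogeneity across comparisons and
equal cross-comparison cross-outcome correlation, the 4x4 block decomposes as
tau_R^2 P_R + tau_D^2 P_D + rho_tau tau_R tau_D P_X with 0/1/(1/2) pattern
matrices (same-outcome cross-comparison entries tau^2/2; cross-outcome
same-comparison entries rho_tau tau_R tau_D; cross-outcome cross-comparison
entries rho_tau tau_R tau_D / 2).

The within-study block is Sigma_i = Sigma_i1 + rho_i Sigma_i2 (see
:mod:`monma.network`): under balanced arms the cross-comparison cross-outcome
correlation is half the same-comparison one (rho** = rho*/2).  Because
Sigma_i1 carries data-estimated shared-arm covariances, positive definiteness
of Sigma_i is only guaranteed on a per-study interval (l_i, u_i) of rho, which
is found by bisection on the smallest eigenvalue.

Model 2 replaces both layers with a single "overall" covariance Omega_i whose
diagonal inflates each sampling variance by an additional-variation term
(zeta = sigma^2 + psi^2) and whose correlations are functions of one hybrid
coefficient rho_h; Omega_i is positive definite for any |rho_h| < 1, so no
truncation is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._copula import bivariate_cell_probs
from .network import OUTCOMES, ContrastBlock, ContrastRow

__all__ = [
    "Model1Params",
    "Model2Params",
    "RhoLimits",
    "delta_block",
    "delta_patterns",
    "sigma_block_model1",
    "rho_limits",
    "omega_block_model2",
    "omega_patterns",
    "verify_half_rho_identity",
    "rho_limits_table",
]


class CovarianceError(ValueError):
    pass


@dataclass
class Model1Params:
    """Heterogeneity and correlation parameters of the structured model."""

    tau_R: float
    tau_D: float
    rho_tau: float
    rho_model: str = "common"  # common | grouped | fixed | per_study
    rho: float | dict | None = None

    def __post_init__(self) -> None:
        if self.tau_R < 0 or self.tau_D < 0:
            raise CovarianceError("heterogeneity SDs must be nonnegative")
        if not -1.0 < self.rho_tau < 1.0:
            raise CovarianceError("between-study correlation must be in (-1,1)")
        if self.rho_model not in ("common", "grouped", "fixed", "per_study"):
            raise CovarianceError(f"unknown rho_model {self.rho_model!r}")


@dataclass
class Model2Params:
    """Additional-variation SDs and the hybrid overall correlation."""

    psi_R: float
    psi_D: float
    rho_h: float

    def __post_init__(self) -> None:
        if self.psi_R < 0 or self.psi_D < 0:
            raise CovarianceError("additional-variation SDs must be nonnegative")
        if not -1.0 < self.rho_h < 1.0:
            raise CovarianceError("hybrid correlation must be in (-1,1)")


@dataclass
class RhoLimits:
    """Per-study open interval of rho on which Sigma_i stays positive definite."""

    study_id: str
    l: float
    u: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.l < self.u <= 1.0):
            raise CovarianceError(
                f"study {self.study_id}: invalid limits ({self.l}, {self.u})"
            )

    def contains(self, rho: float) -> bool:
        return self.l < rho < self.u


# ---------------------------------------------------------------------------
# pattern construction
# ---------------------------------------------------------------------------

def _generic_rows(n_arms: int, outcomes: tuple[str, ...]) -> list[ContrastRow]:
    others = ["B", "C"][: n_arms - 1]
    return [ContrastRow("A", oth, o) for oth in others for o in outcomes]


def delta_patterns(rows: list[ContrastRow]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pattern matrices (P_R, P_D, P_X) of the between-study block for rows.

    Delta = tau_R^2 P_R + tau_D^2 P_D + rho_tau tau_R tau_D P_X.
    """
    d = len(rows)
    P_R = np.zeros((d, d))
    P_D = np.zeros((d, d))
    P_X = np.zeros((d, d))
    for i, ri in enumerate(rows):
        (P_R if ri.outcome == "R" else P_D)[i, i] = 1.0
        for j in range(i + 1, d):
            rj = rows[j]
            same_cmp = ri.comparison == rj.comparison
            if ri.outcome == rj.outcome:
                P = P_R if ri.outcome == "R" else P_D
                P[i, j] = P[j, i] = 0.5  # shared-arm random effects
            else:
                P_X[i, j] = P_X[j, i] = 1.0 if same_cmp else 0.5
    return P_R, P_D, P_X


def delta_block(
    params: Model1Params, n_arms: int, outcomes_present: tuple[str, ...] = OUTCOMES
) -> np.ndarray:
    """Between-study covariance block for a study design.

    Rows are ordered (AB_R, AB_D[, AC_R, AC_D]) restricted to the outcomes
    present.  Symmetric positive semidefinite for |rho_tau| < 1.
    """
    if n_arms not in (2, 3):
        raise CovarianceError(
            f"{n_arms}-arm studies unsupported (2 or 3 arms only)"
        )
    outs = tuple(o for o in OUTCOMES if o in outcomes_present)
    if not outs:
        raise CovarianceError("no outcomes present")
    P_R, P_D, P_X = delta_patterns(_generic_rows(n_arms, outs))
    return (
        params.tau_R**2 * P_R
        + params.tau_D**2 * P_D
        + params.rho_tau * params.tau_R * params.tau_D * P_X
    )


def omega_patterns(rows: list[ContrastRow]) -> tuple[np.ndarray, np.ndarray]:
    """Correlation patterns (C0, C1) of the hybrid model: Corr = C0 + rho_h C1.

    C0: 1 on the diagonal, 1/2 at same-outcome cross-comparison cells.
    C1: 1 at same-comparison cross-outcome cells, 1/2 at cross-comparison
    cross-outcome cells.
    """
    d = len(rows)
    C0 = np.eye(d)
    C1 = np.zeros((d, d))
    for i, ri in enumerate(rows):
        for j in range(i + 1, d):
            rj = rows[j]
            same_cmp = ri.comparison == rj.comparison
            if ri.outcome == rj.outcome:
                C0[i, j] = C0[j, i] = 0.5
            else:
                C1[i, j] = C1[j, i] = 1.0 if same_cmp else 0.5
    return C0, C1


# ---------------------------------------------------------------------------
# block builders
# ---------------------------------------------------------------------------

def sigma_block_model1(
    block: ContrastBlock, rho_i: float, limits: RhoLimits | None = None
) -> np.ndarray:
    """Within-study covariance Sigma_i1 + rho_i Sigma_i2 of the structured model.

    ``rho_i`` must lie strictly inside the study's positive-definiteness
    limits (computed here if not supplied).
    """
    if limits is None:
        limits = rho_limits(block)
    if not limits.contains(rho_i):
        raise CovarianceError(
            f"study {block.study_id}: rho = {rho_i} outside the positive-"
            f"definiteness limits ({limits.l:.6f}, {limits.u:.6f})"
        )
    return block.sigma(rho_i)


def omega_block_model2(block: ContrastBlock, params: Model2Params) -> np.ndarray:
    """Overall covariance Omega_i of the hybrid model for one study.

    zeta = sigma^2 + psi^2 per row; correlations: rho_h within a comparison
    across outcomes, 1/2 across comparisons within an outcome, rho_h/2 across
    both.  Positive definite for |rho_h| < 1 (asserted by factorization).
    """
    psi2 = {"R": params.psi_R**2, "D": params.psi_D**2}
    zeta = np.array(
        [block.sigma1[i, i] + psi2[r.outcome] for i, r in enumerate(block.rows)]
    )
    s = np.sqrt(zeta)
    C0, C1 = omega_patterns(block.rows)
    omega = (C0 + params.rho_h * C1) * np.outer(s, s)
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:  # pragma: no cover - guaranteed PD in theory
        raise CovarianceError(
            f"study {block.study_id}: hybrid covariance unexpectedly not "
            "positive definite"
        ) from None
    return omega


# ---------------------------------------------------------------------------
# positive-definiteness limits
# ---------------------------------------------------------------------------

def _lambda_min(S1: np.ndarray, S2: np.ndarray, rho: float) -> float:
    return float(np.linalg.eigvalsh(S1 + rho * S2)[0])


def rho_limits(block: ContrastBlock, tolerance: float = 1e-6) -> RhoLimits:
    """Widest open interval around 0 on which Sigma_i(rho) is positive definite.

    Exploits that the smallest eigenvalue of an affine matrix family is
    concave in rho, so on each side of 0 there is at most one crossing of
    zero; it is located by bisection to ``tolerance`` and the interval is
    clipped to [-1, 1].  Blocks without any rho-dependence (single-outcome
    studies) return (-1, 1).
    """
    S1, S2 = block.sigma1, block.sigma2
    if _lambda_min(S1, S2, 0.0) <= 0.0:
        raise CovarianceError(
            f"study {block.study_id}: base covariance Sigma_1 is not positive "
            "definite; check the input variances/shared-arm covariances"
        )
    if not np.any(S2):
        return RhoLimits(block.study_id, -1.0, 1.0)

    def crossing(lo_bad: float, hi_good: float) -> float:
        # invariant: lambda_min <= 0 at lo_bad, > 0 at hi_good
        while abs(hi_good - lo_bad) > tolerance:
            mid = 0.5 * (lo_bad + hi_good)
            if _lambda_min(S1, S2, mid) > 0.0:
                hi_good = mid
            else:
                lo_bad = mid
        return 0.5 * (lo_bad + hi_good)

    l = -1.0 if _lambda_min(S1, S2, -1.0) > 0.0 else crossing(-1.0, 0.0)
    u = 1.0 if _lambda_min(S1, S2, 1.0) > 0.0 else crossing(1.0, 0.0)
    return RhoLimits(block.study_id, l, u)


def rho_limits_table(blocks: list[ContrastBlock], tolerance: float = 1e-6) -> pd.DataFrame:
    """Per-study (l_i, u_i) diagnostic table (CSV-exportable)."""
    lims = [rho_limits(b, tolerance) for b in blocks]
    return pd.DataFrame(
        {
            "study_id": [x.study_id for x in lims],
            "n_arms": [b.n_arms for b in blocks],
            "dim": [b.dim for b in blocks],
            "l": [x.l for x in lims],
            "u": [x.u for x in lims],
        }
    )


# ---------------------------------------------------------------------------
# half-rho identity check by simulation
# ---------------------------------------------------------------------------

@dataclass
class HalfRhoResult:
    rho_same: float      # corr of same-comparison contrasts across outcomes (rho*)
    rho_cross: float     # corr of cross-comparison contrasts across outcomes (rho**)
    ratio: float         # rho** / rho*
    n_sim: int


def verify_half_rho_identity(
    n_per_arm: int | tuple[int, int, int] = 200,
    latent_rho: float = -0.6,
    p_R: float = 0.5,
    p_D: float = 0.35,
    n_sim: int = 100_000,
    seed: int | np.random.Generator | None = 0,
) -> HalfRhoResult:
    """Monte-Carlo check that rho** = rho*/2 under balanced three-arm designs.

    Replicates a three-arm trial whose patients carry two correlated binary
    outcomes (Gaussian copula with ``latent_rho``), with identical event
    probabilities in all arms (so the contrast variances are equal).  Across
    replicates, the correlation between the two log-OR errors of the *same*
    comparison (rho*) and between different comparisons (rho**) are estimated
    empirically; balance implies their ratio tends to 1/2.  With unbalanced
    arm sizes the identity is not expected to hold and a warning is raised.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if np.isscalar(n_per_arm):
        sizes = (int(n_per_arm),) * 3
    else:
        sizes = tuple(int(n) for n in n_per_arm)
        if len(set(sizes)) > 1:
            warnings.warn(
                "unbalanced arm sizes requested: the half-rho identity is not "
                "expected to hold",
                stacklevel=2,
            )
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    cells = bivariate_cell_probs(p_R, p_D, latent_rho)

    # counts[rep, arm, cell]; cells ordered (R&D, R&~D, ~R&D, ~R&~D)
    counts = np.stack(
        [rng.multinomial(n, cells, size=n_sim) for n in sizes], axis=1
    ).astype(float)
    e_R = counts[..., 0] + counts[..., 1]
    e_D = counts[..., 0] + counts[..., 2]
    n_arr = np.array(sizes, dtype=float)
    f_R = n_arr - e_R
    f_D = n_arr - e_D
    # zero-cell guard (negligible at the default sizes/probabilities)
    e_R, f_R, e_D, f_D = (np.maximum(x, 0.5) for x in (e_R, f_R, e_D, f_D))

    logit_R = np.log(e_R / f_R)
    logit_D = np.log(e_D / f_D)
    ab_R = logit_R[:, 1] - logit_R[:, 0]
    ac_R = logit_R[:, 2] - logit_R[:, 0]
    ab_D = logit_D[:, 1] - logit_D[:, 0]
    ac_D = logit_D[:, 2] - logit_D[:, 0]

    def corr(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    rho_same = 0.5 * (corr(ab_R, ab_D) + corr(ac_R, ac_D))
    rho_cross = 0.5 * (corr(ab_R, ac_D) + corr(ac_R, ab_D))
    ratio = rho_cross / rho_same if rho_same != 0.0 else np.nan
    return HalfRhoResult(rho_same, rho_cross, ratio, n_sim)
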