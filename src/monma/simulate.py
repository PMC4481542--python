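"""Synthetic two-outcome trial networks with the generative structure the
joint models assume.

Each simulated study draws its true contrast effects from the between-study
law (consistency-implied means plus a random effect with the structured
covariance block), converts them to arm-level event probabilities, and then
samples each patient's pair of binary outcomes from a Gaussian copula so that
the two outcomes are correlated *within* the study through the patients
themselves — the same mechanism that induces within-study correlation in real
trials.  A configurable fraction of studies drops one outcome entirely,
emulating partial outcome reporting.

Default condition (mirroring a large psychiatric drug network: ~60 trials,
a placebo hub, a quarter of trials with three arms, a quarter reporting only
one outcome, response heterogeneity tau^2 ~ 0.08-0.13 and strongly negative
between-study correlation): see :class:`SimulationConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from ._copula import bivariate_cell_probs
from .covariance import Model1Params, delta_patterns
from .network import Arm, ContrastRow, NetworkDataset, Study

__all__ = [
    "SimulationConfig",
    "simulate_network",
    "make_fixture",
    "empirical_contrast_rho",
    "calibrate_latent_rho",
]


def _default_beta() -> dict[str, list[float]]:
    # active treatments vs reference: modest positive response effects,
    # modest negative dropout effects (log-OR scale)
    return {
        "R": [0.2, 0.35, 0.5, 0.65, 0.8],
        "D": [-0.4, -0.3, -0.2, -0.1, 0.0],
    }


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic network.

    ``beta`` maps each outcome to the true effects of treatments T1..T{k}
    versus the reference T0, on the log-odds scale.  ``latent_rho`` is the
    patient-level copula correlation between the two binary outcomes; the
    contrast-level within-study correlation it induces is close to the
    tetrachoric-implied phi coefficient and can be calibrated with
    :func:`calibrate_latent_rho`.
    """

    n_treatments: int = 6
    n_studies: int = 60
    prop_three_arm: float = 0.25
    patients_mean: float = 150.0
    patients_dispersion: float = 0.3  # lognormal coefficient of variation
    beta: dict[str, list[float]] = field(default_factory=_default_beta)
    tau_R: float = 0.3
    tau_D: float = 0.35
    rho_tau: float = -0.8
    latent_rho: float = -0.5
    baseline_p: dict[str, float] = field(
        default_factory=lambda: {"R": 0.4, "D": 0.3}
    )
    baseline_sd: float = 0.3  # SD of study-level baseline logit shifts
    missing_prob: float = 0.25
    missing_outcome_weights: dict[str, float] = field(
        default_factory=lambda: {"R": 0.95, "D": 0.05}
    )
    placebo_anchor_prob: float = 0.7
    allow_zero_cells: bool = False
    seed: int | None = 0

    def __post_init__(self) -> None:
        k = self.n_treatments - 1
        for o, b in self.beta.items():
            if len(b) != k:
                raise ValueError(
                    f"beta[{o!r}] must list {k} effects (non-reference treatments)"
                )
        for o, p in self.baseline_p.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"baseline_p[{o!r}] must be in (0,1)")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing_prob must be in [0,1)")
        if not -1.0 < self.latent_rho < 1.0:
            raise ValueError("latent_rho must be in (-1,1)")

    @property
    def treatments(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_treatments)]

    def truth(self) -> dict:
        """Generating parameters as a JSON-serializable dict."""
        return asdict(self)


def _sample_designs(cfg: SimulationConfig, rng: np.random.Generator) -> list[list[str]]:
    """Treatment sets per study; resampled until the union graph is connected."""
    trts = cfg.treatments
    for _ in range(100):
        designs = []
        for _ in range(cfg.n_studies):
            k = 3 if rng.random() < cfg.prop_three_arm else 2
            if rng.random() < cfg.placebo_anchor_prob:
                others = rng.choice(trts[1:], size=k - 1, replace=False)
                arms = [trts[0], *others]
            else:
                arms = list(rng.choice(trts[1:], size=k, replace=False))
            designs.append([str(a) for a in arms])
        g = nx.Graph()
        g.add_nodes_from(trts)
        for arms in designs:
            g.add_edges_from(
                (a, b) for i, a in enumerate(arms) for b in arms[i + 1 :]
            )
        if nx.is_connected(g):
            return designs
    raise RuntimeError("failed to generate a connected network in 100 attempts")


def simulate_network(
    cfg: SimulationConfig, seed: int | np.random.Generator | None = None
) -> NetworkDataset:
    """Draw one arm-level network under the configured generating law.

    Per study: true contrast effects ~ N(consistency means, Delta block);
    arm-level event probabilities from a study baseline logit plus the
    contrasts; per-patient correlated outcomes via the Gaussian copula; an
    outcome dropped wholesale with probability ``missing_prob``.
    """
    if seed is None:
        seed = cfg.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    designs = _sample_designs(cfg, rng)
    beta = {
        o: dict(zip(cfg.treatments[1:], cfg.beta[o])) | {cfg.treatments[0]: 0.0}
        for o in ("R", "D")
    }
    params = Model1Params(cfg.tau_R, cfg.tau_D, cfg.rho_tau)
    mw = cfg.missing_outcome_weights
    w = np.array([mw.get("R", 0.0), mw.get("D", 0.0)], dtype=float)
    w = w / w.sum()

    studies = []
    for s, arms in enumerate(designs):
        sid = f"S{s + 1:03d}"
        base, *others = arms
        rows = [ContrastRow(base, oth, o) for oth in others for o in ("R", "D")]
        mean = np.array([beta[r.outcome][r.other] - beta[r.outcome][r.base] for r in rows])
        P_R, P_D, P_X = delta_patterns(rows)
        delta_cov = (
            params.tau_R**2 * P_R
            + params.tau_D**2 * P_D
            + params.rho_tau * params.tau_R * params.tau_D * P_X
        )
        # "eigh" tolerates the positive-semidefinite (e.g. tau = 0) case
        theta = rng.multivariate_normal(mean, delta_cov, method="eigh")

        base_logit = {
            o: float(
                np.log(cfg.baseline_p[o] / (1 - cfg.baseline_p[o]))
                + rng.normal(0.0, cfg.baseline_sd)
            )
            for o in ("R", "D")
        }
        logits = {(base, o): base_logit[o] for o in ("R", "D")}
        for r, th in zip(rows, theta):
            logits[(r.other, r.outcome)] = base_logit[r.outcome] + float(th)

        n = max(10, int(round(rng.lognormal(
            np.log(cfg.patients_mean) - 0.5 * np.log1p(cfg.patients_dispersion**2),
            np.sqrt(np.log1p(cfg.patients_dispersion**2)),
        ))))

        report: tuple[str, ...] = ("R", "D")
        if rng.random() < cfg.missing_prob:
            dropped = ("R", "D")[int(rng.choice(2, p=w))]
            report = tuple(o for o in ("R", "D") if o != dropped)

        study_arms = []
        for t in arms:
            p = {o: 1.0 / (1.0 + np.exp(-logits[(t, o)])) for o in ("R", "D")}
            cells = bivariate_cell_probs(p["R"], p["D"], cfg.latent_rho)
            c = rng.multinomial(n, cells)
            e = {"R": int(c[0] + c[1]), "D": int(c[0] + c[2])}
            counts = {}
            for o in report:
                ev, fl = e[o], n - e[o]
                if not cfg.allow_zero_cells:
                    ev = min(max(ev, 1), n - 1)
                    fl = n - ev
                counts[o] = (ev, fl)
            study_arms.append(Arm(sid, t, counts))
        studies.append(Study(sid, study_arms))
    return NetworkDataset(studies)


# ---------------------------------------------------------------------------
# latent -> contrast-level correlation mapping
# ---------------------------------------------------------------------------

def empirical_contrast_rho(
    latent_rho: float,
    p_R: float = 0.4,
    p_D: float = 0.3,
    n_per_arm: int = 150,
    n_rep: int = 4000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Within-study correlation of the two log ORs induced by the copula.

    Estimated by replicating one balanced two-arm study many times and
    correlating the two contrast errors; monotone in ``latent_rho``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = bivariate_cell_probs(p_R, p_D, latent_rho)
    counts = np.stack(
        [rng.multinomial(n_per_arm, cells, size=n_rep) for _ in range(2)], axis=1
    ).astype(float)
    e_R = np.maximum(counts[..., 0] + counts[..., 1], 0.5)
    e_D = np.maximum(counts[..., 0] + counts[..., 2], 0.5)
    f_R = np.maximum(n_per_arm - e_R, 0.5)
    f_D = np.maximum(n_per_arm - e_D, 0.5)
    lor_R = np.log(e_R[:, 1] / f_R[:, 1]) - np.log(e_R[:, 0] / f_R[:, 0])
    lor_D = np.log(e_D[:, 1] / f_D[:, 1]) - np.log(e_D[:, 0] / f_D[:, 0])
    return float(np.corrcoef(lor_R, lor_D)[0, 1])


def calibrate_latent_rho(
    target_rho: float,
    p_R: float = 0.4,
    p_D: float = 0.3,
    n_per_arm: int = 150,
    n_rep: int = 20000,
    seed: int = 0,
    tol: float = 0.02,
) -> float:
    """Latent copula correlation inducing a target contrast-level correlation.

    Bisection on the (noisy but monotone) empirical map; the same seed is
    reused at every evaluation so the map is deterministic in ``latent_rho``.
    """
    if not -1.0 < target_rho < 1.0:
        raise ValueError("target_rho must be in (-1,1)")
    lo, hi = -0.999, 0.999

    def f(x: float) -> float:
        return empirical_contrast_rho(
            x, p_R, p_D, n_per_arm, n_rep, np.random.default_rng(seed)
        ) - target_rho

    flo, fhi = f(lo), f(hi)
    if not flo < 0.0 < fhi:
        raise ValueError(
            f"target correlation {target_rho} outside the achievable range "
            f"[{flo + target_rho:.3f}, {fhi + target_rho:.3f}] for margins "
            f"({p_R}, {p_D}); binary outcomes bound the attainable phi "
            "coefficient — use margins closer to 0.5 for strong correlations"
        )
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < tol:
            return mid
        if fm < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str) -> NetworkDataset:
    """Small hand-written networks used across the test suite.

    ``two_arm_minimal``: 3 two-arm studies, 3 treatments, both outcomes,
    no zero cells.  ``three_arm_minimal``: one three-arm plus two two-arm
    studies (shared-arm covariances hand-checkable, e.g. kappa = 1/20 + 1/30
    for F1's base arm on R).  ``mixed_missing``: as two_arm_minimal plus a
    study reporting only D and one reporting only R.
    """
    def arm(sid, t, eR, fR, eD, fD):
        return Arm(sid, t, {"R": (eR, fR), "D": (eD, fD)})

    if name == "two_arm_minimal":
        studies = [
            Study("F1", [arm("F1", "P", 20, 30, 15, 35), arm("F1", "A", 30, 20, 10, 40)]),
            Study("F2", [arm("F2", "P", 18, 32, 12, 38), arm("F2", "B", 25, 25, 8, 42)]),
            Study("F3", [arm("F3", "A", 28, 22, 11, 39), arm("F3", "B", 24, 26, 9, 41)]),
        ]
    elif name == "three_arm_minimal":
        studies = [
            Study("F1", [
                arm("F1", "P", 20, 30, 15, 35),
                arm("F1", "A", 30, 20, 10, 40),
                arm("F1", "B", 26, 24, 12, 38),
            ]),
            Study("F2", [arm("F2", "P", 18, 32, 12, 38), arm("F2", "A", 27, 23, 9, 41)]),
            Study("F3", [arm("F3", "A", 28, 22, 11, 39), arm("F3", "B", 24, 26, 9, 41)]),
        ]
    elif name == "mixed_missing":
        studies = [
            Study("F1", [arm("F1", "P", 20, 30, 15, 35), arm("F1", "A", 30, 20, 10, 40)]),
            Study("F2", [arm("F2", "P", 18, 32, 12, 38), arm("F2", "B", 25, 25, 8, 42)]),
            Study("F3", [arm("F3", "A", 28, 22, 11, 39), arm("F3", "B", 24, 26, 9, 41)]),
            Study("F4", [  # reports only dropout
                Arm("F4", "P", {"D": (14, 36)}), Arm("F4", "A", {"D": (10, 40)}),
            ]),
            Study("F5", [  # reports only response
                Arm("F5", "P", {"R": (19, 31)}), Arm("F5", "B", {"R": (26, 24)}),
            ]),
        ]
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return NetworkDataset(studies)
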