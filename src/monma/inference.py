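"""Bayesian estimation of the two joint-synthesis models by MCMC.

The random effects are integrated out analytically (both layers are normal),
so the sampler works on the marginal likelihood: per study i,

    y_i ~ N(X_i beta,  Sigma_i(rho_i) + Delta_i)        (Model 1)
    y_i ~ N(X_i beta,  Omega_i(psi, rho_h))             (Model 2)

Sampling is Metropolis-within-Gibbs: the basic parameters beta are drawn in
one block from their exact conditional normal (the covariances are fixed
within an update), and each variance/correlation parameter gets an adaptive
random-walk Metropolis step whose proposals outside the (possibly truncated)
uniform prior support are rejected — this is how the per-study positive-
definiteness limits on rho are enforced.

Prior scenarios follow a common analysis plan for two negatively correlated
outcomes:

* ``I``     univariate/independent: all correlations fixed at 0,
  tau_R, tau_D ~ U(0,1) — a single code path with the joint model.
* ``II.a``  rho ~ U(-1,0) common, rho_tau ~ U(-1,0).
* ``II.b``  strongly informative rho ~ U(-0.7,-0.5).
* ``II.c``  rho fixed at -0.7.
* ``II.d``  separate rho for active-vs-active and active-vs-placebo studies.
* ``III``   hybrid model: rho_h ~ U(-1,0), psi_R, psi_D ~ U(0,1).

Prior bounds can be overridden per parameter (e.g. rho ~ U(-1,1) to evaluate
a negativity assumption).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .covariance import (
    CovarianceError,
    Model1Params,
    Model2Params,
    delta_patterns,
    omega_patterns,
    rho_limits,
)
from .design import BasicParameterIndex, build_design, relative_effect
from .network import ContrastDataset, NetworkDataset

__all__ = [
    "MCMCConfig",
    "ScenarioConfig",
    "PosteriorSamples",
    "fit",
    "log_likelihood",
    "summarize",
    "or_summary",
    "SCENARIOS",
]

SCENARIOS = ("I", "II.a", "II.b", "II.c", "II.d", "III")

_RHAT_WARN = 1.05


@dataclass
class MCMCConfig:
    """Desk-scale defaults; raise iterations/thinning for replication runs."""

    iterations: int = 25_000
    burn_in: int = 5_000
    thinning: int = 10
    chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thinning < 1 or self.chains < 1:
            raise ValueError("thinning and chains must be >= 1")


@dataclass
class ScenarioConfig:
    scenario: str
    reference: str | None = None
    placebo: str | None = None  # required for II.d grouping
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    priors: dict[str, object] = field(default_factory=dict)  # name -> (lo,hi) | float
    rho_model: str | None = None  # override: "per_study" with scenario II.a
    exclude: list[tuple[str, str]] | None = None
    beta_prior_sd: float = 100.0
    tau_upper: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.scenario == "II.d" and self.placebo is None:
            raise ValueError("scenario II.d requires the placebo treatment id")


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws, (chains, draws[, p]) arrays."""

    beta: np.ndarray
    params: dict[str, np.ndarray]
    fixed: dict[str, float]
    index: BasicParameterIndex
    diagnostics: pd.DataFrame
    meta: dict

    def flat_beta(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def flat(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]


# ---------------------------------------------------------------------------
# likelihood engine: blocks grouped by dimension, batched linear algebra
# ---------------------------------------------------------------------------

class _Group:
    def __init__(self, dim: int, positions: list[int], blocks, X_rows, row_offsets):
        self.dim = dim
        self.pos = np.asarray(positions)
        n = len(positions)
        self.S1 = np.empty((n, dim, dim))
        self.S2 = np.empty((n, dim, dim))
        self.PR = np.empty((n, dim, dim))
        self.PD = np.empty((n, dim, dim))
        self.PX = np.empty((n, dim, dim))
        self.C0 = np.empty((n, dim, dim))
        self.C1 = np.empty((n, dim, dim))
        self.maskR = np.empty((n, dim))
        self.y = np.empty((n, dim))
        p = X_rows.shape[1]
        self.X = np.empty((n, dim, p))
        for k, b_pos in enumerate(positions):
            b = blocks[b_pos]
            self.S1[k] = b.sigma1
            self.S2[k] = b.sigma2
            self.PR[k], self.PD[k], self.PX[k] = delta_patterns(b.rows)
            self.C0[k], self.C1[k] = omega_patterns(b.rows)
            self.maskR[k] = [1.0 if r.outcome == "R" else 0.0 for r in b.rows]
            self.y[k] = b.y
            off = row_offsets[b_pos]
            self.X[k] = X_rows[off : off + dim]


class _Engine:
    """Marginal likelihood for one dataset/design under either model."""

    def __init__(
        self,
        dataset: ContrastDataset,
        X: np.ndarray,
        model: str,
        rho_map: list[tuple[str, object]],
    ):
        self.model = model
        self.rho_map = rho_map
        blocks = dataset.blocks
        self.n_blocks = len(blocks)
        offsets = np.concatenate([[0], np.cumsum([b.dim for b in blocks])])[:-1]
        by_dim: dict[int, list[int]] = {}
        for i, b in enumerate(blocks):
            by_dim.setdefault(b.dim, []).append(i)
        self.groups = [
            _Group(d, pos, blocks, X, offsets) for d, pos in sorted(by_dim.items())
        ]
        self.study_ids = [b.study_id for b in blocks]
        self.p = X.shape[1]

    def rho_vec(self, theta: dict[str, float]) -> np.ndarray:
        out = np.zeros(self.n_blocks)
        for i, (kind, val) in enumerate(self.rho_map):
            out[i] = theta[val] if kind == "param" else float(val)
        return out

    def build_V(self, theta: dict[str, float]) -> list[np.ndarray]:
        Vs = []
        if self.model == "model1":
            tr, td, rt = theta["tau_R"], theta["tau_D"], theta["rho_tau"]
            rho = self.rho_vec(theta)
            for g in self.groups:
                r = rho[g.pos][:, None, None]
                V = (
                    g.S1
                    + r * g.S2
                    + tr**2 * g.PR
                    + td**2 * g.PD
                    + rt * tr * td * g.PX
                )
                Vs.append(V)
        else:
            pr2, pd2, rh = theta["psi_R"] ** 2, theta["psi_D"] ** 2, theta["rho_h"]
            for g in self.groups:
                zeta = np.diagonal(g.S1, axis1=1, axis2=2) + pr2 * g.maskR + pd2 * (
                    1.0 - g.maskR
                )
                s = np.sqrt(zeta)
                Vs.append((g.C0 + rh * g.C1) * (s[:, :, None] * s[:, None, :]))
        return Vs

    def factorize(self, theta: dict[str, float]):
        """(Vinv list, per-study logdet, ok flag)."""
        Vs = self.build_V(theta)
        Vinv, logdet = [], np.empty(self.n_blocks)
        for g, V in zip(self.groups, Vs):
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return None, None, False
            logdet[g.pos] = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
            Vinv.append(np.linalg.inv(V))
        return Vinv, logdet, True

    def loglik_vec(self, beta: np.ndarray, Vinv: list, logdet: np.ndarray) -> np.ndarray:
        out = np.empty(self.n_blocks)
        for g, Vi in zip(self.groups, Vinv):
            z = g.y - g.X @ beta
            quad = np.einsum("nd,nde,ne->n", z, Vi, z)
            out[g.pos] = -0.5 * (g.dim * np.log(2.0 * np.pi) + logdet[g.pos] + quad)
        return out

    def beta_suffstats(self, Vinv: list) -> tuple[np.ndarray, np.ndarray]:
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        for g, Vi in zip(self.groups, Vinv):
            A += np.einsum("ndp,nde,neq->pq", g.X, Vi, g.X)
            b += np.einsum("ndp,nde,ne->p", g.X, Vi, g.y)
        return A, b

    def study_update(
        self, b_pos: int, theta: dict[str, float], beta: np.ndarray
    ):
        """Recompute one study's (V_inv, logdet, loglik); None if not PD."""
        g = next(g for g in self.groups if b_pos in g.pos)
        k = int(np.where(g.pos == b_pos)[0][0])
        if self.model == "model1":
            tr, td, rt = theta["tau_R"], theta["tau_D"], theta["rho_tau"]
            kind, val = self.rho_map[b_pos]
            r = theta[val] if kind == "param" else float(val)
            V = (
                g.S1[k]
                + r * g.S2[k]
                + tr**2 * g.PR[k]
                + td**2 * g.PD[k]
                + rt * tr * td * g.PX[k]
            )
        else:  # pragma: no cover - per-study rho is a Model 1 feature
            raise NotImplementedError
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Vi = np.linalg.inv(V)
        z = g.y[k] - g.X[k] @ beta
        ll = -0.5 * (g.dim * np.log(2.0 * np.pi) + logdet + z @ Vi @ z)
        return g, k, Vi, logdet, ll


# ---------------------------------------------------------------------------
# scenario resolution
# ---------------------------------------------------------------------------

@dataclass
class _ParamSpec:
    name: str
    lo: float
    hi: float
    local_block: int | None = None  # per-study rho: index of its block


def _act_pl_label(block, placebo: str) -> str:
    return "rho_act_pl" if placebo in block.treatments else "rho_act_act"


def _resolve_scenario(
    cfg: ScenarioConfig, dataset: ContrastDataset
) -> tuple[str, list[_ParamSpec], dict[str, float], list[tuple[str, object]], dict]:
    """-> (model, sampled params, fixed params, per-block rho map, rho support info)."""
    outs = dataset.outcomes
    both = len(outs) == 2
    sampled: list[_ParamSpec] = []
    fixed: dict[str, float] = {}
    info: dict = {}

    def bounds(name: str, lo: float, hi: float) -> tuple[float, float] | None:
        """Prior bounds with user override; None means fixed."""
        ov = cfg.priors.get(name)
        if ov is None:
            return lo, hi
        if np.isscalar(ov):
            fixed[name] = float(ov)
            return None
        lo2, hi2 = ov
        return float(lo2), float(hi2)

    def add(name: str, lo: float, hi: float, local: int | None = None) -> None:
        b = bounds(name, lo, hi)
        if b is not None:
            sampled.append(_ParamSpec(name, b[0], b[1], local))

    model = "model2" if cfg.scenario == "III" else "model1"

    if model == "model1":
        for o in ("R", "D"):
            if o in outs:
                add(f"tau_{o}", 0.0, cfg.tau_upper)
            else:
                fixed[f"tau_{o}"] = 0.0
        if both and cfg.scenario != "I":
            add("rho_tau", -1.0, 0.0)
        else:
            fixed["rho_tau"] = 0.0

        # within-study correlation structure
        blocks = dataset.blocks
        lims = {
            i: rho_limits(b) for i, b in enumerate(blocks) if np.any(b.sigma2)
        }
        info["rho_limits"] = {blocks[i].study_id: (l.l, l.u) for i, l in lims.items()}
        rho_map: list[tuple[str, object]] = [("fixed", 0.0)] * len(blocks)

        def common_support(idx: list[int], lo: float, hi: float, name: str):
            l = max([lims[i].l for i in idx], default=-1.0)
            u = min([lims[i].u for i in idx], default=1.0)
            lo2, hi2 = max(lo, l), min(hi, u)
            if lo2 >= hi2:
                raise CovarianceError(
                    f"empty support for {name}: prior ({lo}, {hi}) does not "
                    f"intersect the PD limits ({l:.4f}, {u:.4f})"
                )
            info.setdefault("rho_support", {})[name] = (lo2, hi2)
            return lo2, hi2

        if not both or cfg.scenario == "I":
            fixed["rho"] = 0.0  # univariate/independent: no within-study coupling
        elif cfg.rho_model == "per_study" and cfg.scenario == "II.a":
            for i in sorted(lims):
                name = f"rho_i[{blocks[i].study_id}]"
                lo, hi = common_support([i], -1.0, 0.0, name)
                add(name, lo, hi, local=i)
                rho_map[i] = ("param", name)
        elif cfg.scenario in ("II.a", "II.b"):
            dlo, dhi = (-1.0, 0.0) if cfg.scenario == "II.a" else (-0.7, -0.5)
            idx = sorted(lims)
            b = bounds("rho", dlo, dhi)
            if b is None:  # fixed by a scalar prior override
                for i in idx:
                    if not lims[i].contains(fixed["rho"]):
                        raise CovarianceError(
                            f"fixed rho = {fixed['rho']} outside PD limits of "
                            f"study {blocks[i].study_id}"
                        )
                    rho_map[i] = ("fixed", fixed["rho"])
            else:
                lo, hi = common_support(idx, b[0], b[1], name="rho")
                sampled.append(_ParamSpec("rho", lo, hi))
                for i in idx:
                    rho_map[i] = ("param", "rho")
        elif cfg.scenario == "II.c":
            val = float(cfg.priors.get("rho", -0.7))
            fixed["rho"] = val
            for i in sorted(lims):
                if not lims[i].contains(val):
                    raise CovarianceError(
                        f"fixed rho = {val} outside PD limits of study "
                        f"{blocks[i].study_id}"
                    )
                rho_map[i] = ("fixed", val)
        elif cfg.scenario == "II.d":
            groups: dict[str, list[int]] = {"rho_act_act": [], "rho_act_pl": []}
            for i in sorted(lims):
                groups[_act_pl_label(blocks[i], cfg.placebo)].append(i)
            for name, idx in groups.items():
                if not idx:
                    continue
                b = bounds(name, -1.0, 0.0)
                if b is None:
                    for i in idx:
                        rho_map[i] = ("fixed", fixed[name])
                    continue
                lo, hi = common_support(idx, *b, name=name)
                sampled.append(_ParamSpec(name, lo, hi))
                for i in idx:
                    rho_map[i] = ("param", name)
        return model, sampled, fixed, rho_map, info

    # model 2 (scenario III)
    for o in ("R", "D"):
        if o in outs:
            add(f"psi_{o}", 0.0, 1.0)
        else:
            fixed[f"psi_{o}"] = 0.0
    if both:
        add("rho_h", -1.0, 0.0)
    else:
        fixed["rho_h"] = 0.0
    return model, sampled, fixed, [("fixed", 0.0)] * dataset.n_studies, info


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _run_chain(
    engine: _Engine,
    sampled: list[_ParamSpec],
    fixed: dict[str, float],
    mcmc: MCMCConfig,
    beta_prior_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    p = engine.p
    theta = dict(fixed)
    for s in sampled:
        theta[s.name] = s.lo + (0.2 + 0.6 * rng.random()) * (s.hi - s.lo)

    # GLS initialization of beta at the current theta
    Vinv, logdet, ok = engine.factorize(theta)
    if not ok:
        raise RuntimeError("initial covariance not positive definite")
    prior_prec = np.eye(p) / beta_prior_sd**2
    A, b = engine.beta_suffstats(Vinv)
    A += prior_prec
    beta = np.linalg.solve(A, b)
    ll = engine.loglik_vec(beta, Vinv, logdet)

    scales = {s.name: 0.1 * (s.hi - s.lo) for s in sampled}
    n_adapt = {s.name: 0 for s in sampled}

    n_keep = (mcmc.iterations - mcmc.burn_in) // mcmc.thinning
    beta_out = np.empty((n_keep, p))
    theta_out = {s.name: np.empty(n_keep) for s in sampled}
    kept = 0

    for it in range(mcmc.iterations):
        # --- beta | theta: exact conditional normal draw
        A, b = engine.beta_suffstats(Vinv)
        A += prior_prec
        L = np.linalg.cholesky(A)
        mu = np.linalg.solve(A, b)
        z = rng.standard_normal(p)
        beta = mu + np.linalg.solve(L.T, z)
        ll = engine.loglik_vec(beta, Vinv, logdet)
        ll_total = ll.sum()

        # --- variance/correlation parameters: adaptive random-walk MH
        for s in sampled:
            cur = theta[s.name]
            prop = cur + scales[s.name] * rng.standard_normal()
            accepted = False
            if s.lo < prop < s.hi:  # truncated uniform prior
                theta[s.name] = prop
                if s.local_block is None:
                    Vinv_p, logdet_p, ok = engine.factorize(theta)
                    if ok:
                        ll_p = engine.loglik_vec(beta, Vinv_p, logdet_p)
                        if np.log(rng.random()) < ll_p.sum() - ll_total:
                            Vinv, logdet, ll = Vinv_p, logdet_p, ll_p
                            ll_total = ll.sum()
                            accepted = True
                else:
                    res = engine.study_update(s.local_block, theta, beta)
                    if res is not None:
                        g, k, Vi_k, ld_k, ll_k = res
                        if np.log(rng.random()) < ll_k - ll[s.local_block]:
                            gi = engine.groups.index(g)
                            Vinv[gi][k] = Vi_k
                            logdet[s.local_block] = ld_k
                            ll[s.local_block] = ll_k
                            ll_total = ll.sum()
                            accepted = True
                if not accepted:
                    theta[s.name] = cur
            if it < mcmc.burn_in:
                n_adapt[s.name] += 1
                step = (1.0 if accepted else 0.0) - 0.44
                scales[s.name] *= np.exp(step / n_adapt[s.name] ** 0.6)

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0 and kept < n_keep:
            beta_out[kept] = beta
            for s in sampled:
                theta_out[s.name][kept] = theta[s.name]
            kept += 1

    return beta_out, theta_out


def fit(
    dataset: ContrastDataset | NetworkDataset,
    config: ScenarioConfig,
) -> PosteriorSamples:
    """Posterior sampling for one prior scenario.

    Runs ``config.mcmc.chains`` chains (reproducible under a fixed seed),
    attaches split-chain R-hat and effective sample sizes per parameter, and
    warns — without failing — when any R-hat exceeds 1.05.
    """
    if isinstance(dataset, NetworkDataset):
        dataset = dataset.to_contrasts()
    X, index = build_design(dataset, config.reference, config.exclude)
    model, sampled, fixed, rho_map, info = _resolve_scenario(config, dataset)
    engine = _Engine(dataset, X, model, rho_map)

    t0 = time.perf_counter()
    seeds = np.random.SeedSequence(config.mcmc.seed).spawn(config.mcmc.chains)
    beta_chains, theta_chains = [], []
    for ss in seeds:
        b, th = _run_chain(
            engine, sampled, fixed, config.mcmc, config.beta_prior_sd,
            np.random.default_rng(ss),
        )
        beta_chains.append(b)
        theta_chains.append(th)
    runtime = time.perf_counter() - t0

    beta = np.stack(beta_chains)  # (chains, draws, p)
    params = {
        s.name: np.stack([th[s.name] for th in theta_chains]) for s in sampled
    }

    names = index.names
    azdict = {n: beta[:, :, j] for j, n in enumerate(names)} | params
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # arviz warns on short chains
        idata = az.from_dict(posterior=azdict)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    diag = pd.DataFrame(
        {
            "rhat": {n: float(rhat[n].values) for n in azdict},
            "ess": {n: float(ess[n].values) for n in azdict},
        }
    )
    bad = diag[diag["rhat"] > _RHAT_WARN]
    if len(bad):
        warnings.warn(
            f"convergence statistic > {_RHAT_WARN} for {list(bad.index)}; "
            "consider more iterations or stronger thinning",
            stacklevel=2,
        )

    meta = {
        "scenario": config.scenario,
        "model": model,
        "seed": config.mcmc.seed,
        "chains": config.mcmc.chains,
        "iterations": config.mcmc.iterations,
        "burn_in": config.mcmc.burn_in,
        "thinning": config.mcmc.thinning,
        "reference": index.reference,
        "runtime_s": runtime,
        **info,
    }
    return PosteriorSamples(beta, params, dict(fixed), index, diag, meta)


# ---------------------------------------------------------------------------
# public likelihood (reference path, per-study loop)
# ---------------------------------------------------------------------------

def log_likelihood(
    beta: np.ndarray,
    params: Model1Params | Model2Params,
    dataset: ContrastDataset,
    design: tuple[np.ndarray, BasicParameterIndex] | None = None,
    reference: str | None = None,
) -> float:
    """Marginal log likelihood of the observed contrasts at fixed parameters.

    Model 1 uses per-study covariance Sigma_i(rho_i) + Delta_i with rho_i
    resolved from ``params.rho`` (scalar, or dict study_id -> rho); Model 2
    uses Omega_i.  Studies reporting one outcome contribute the corresponding
    marginal (sub-vector) normal density.
    """
    from .covariance import omega_block_model2  # local to avoid cycle at import

    if design is None:
        design = build_design(dataset, reference)
    X, _ = design
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    off = 0
    for b in dataset.blocks:
        d = b.dim
        Xi = X[off : off + d]
        off += d
        if isinstance(params, Model1Params):
            if isinstance(params.rho, dict):
                rho_i = float(params.rho.get(b.study_id, 0.0))
            else:
                rho_i = float(params.rho or 0.0)
            P_R, P_D, P_X = delta_patterns(b.rows)
            delta = (
                params.tau_R**2 * P_R
                + params.tau_D**2 * P_D
                + params.rho_tau * params.tau_R * params.tau_D * P_X
            )
            V = b.sigma(rho_i) + delta
        else:
            V = omega_block_model2(b, params)
        z = b.y - Xi @ beta
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            raise CovarianceError(
                f"study {b.study_id}: total covariance not positive definite"
            ) from None
        w = np.linalg.solve(L, z)
        total += -0.5 * (
            d * np.log(2.0 * np.pi)
            + 2.0 * np.sum(np.log(np.diag(L)))
            + w @ w
        )
    return float(total)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def _mcse(draws: np.ndarray, ess: float) -> float:
    return float(np.std(draws)) / np.sqrt(max(ess, 1.0))


def summarize(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Posterior medians and equal-tailed credible intervals per parameter.

    Heterogeneity/additional-variation SDs are also reported on the variance
    scale (``tau_R^2`` etc.), the scale on which such results are usually
    tabulated.  Fixed parameters appear with zero-width intervals.
    """
    a = (1.0 - level) / 2.0
    qs = (0.5, a, 1.0 - a)
    rows = {}

    def entry(name: str, draws: np.ndarray, diag_key: str | None = None):
        med, lo, hi = np.quantile(draws, qs)
        ess = rhat = np.nan
        if diag_key is not None and diag_key in samples.diagnostics.index:
            ess = samples.diagnostics.loc[diag_key, "ess"]
            rhat = samples.diagnostics.loc[diag_key, "rhat"]
        rows[name] = {
            "median": med, "lower": lo, "upper": hi,
            "mean": float(np.mean(draws)), "sd": float(np.std(draws)),
            "ess": ess, "rhat": rhat,
            "mcse": _mcse(draws, ess) if np.isfinite(ess) else np.nan,
        }

    for j, n in enumerate(samples.index.names):
        entry(n, samples.flat_beta()[:, j], n)
    for n, arr in samples.params.items():
        entry(n, arr.reshape(-1), n)
        if n.startswith(("tau_", "psi_")):
            entry(n + "^2", arr.reshape(-1) ** 2, n)
    for n, v in samples.fixed.items():
        if n.startswith(("tau_", "psi_", "rho")):
            rows[n] = {
                "median": v, "lower": v, "upper": v, "mean": v, "sd": 0.0,
                "ess": np.nan, "rhat": np.nan, "mcse": 0.0,
            }
    return pd.DataFrame(rows).T


def or_summary(
    samples: PosteriorSamples,
    outcome: str,
    pairs: list[tuple[str, str]] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Posterior odds ratios (median and credible interval) per comparison.

    Defaults to every identified treatment versus the reference.  The OR
    interval is the endpointwise exp of the log-OR interval.
    """
    idx = samples.index
    if pairs is None:
        pairs = [
            (idx.reference, t)
            for t in idx.order
            if (t, outcome) not in idx.excluded
        ]
    a = (1.0 - level) / 2.0
    flat = samples.flat_beta()
    recs = []
    for t1, t2 in pairs:
        draws = relative_effect(flat, idx, (t1, t2), outcome)
        lo, med, hi = np.quantile(draws, (a, 0.5, 1.0 - a))
        recs.append(
            {
                "comparison": f"{t2} vs {t1}",
                "outcome": outcome,
                "or": np.exp(med),
                "or_lower": np.exp(lo),
                "or_upper": np.exp(hi),
                "log_or": med,
            }
        )
    return pd.DataFrame(recs).set_index("comparison")
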