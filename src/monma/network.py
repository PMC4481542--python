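"""Data model and I/O for multi-arm, two-outcome trial networks.

Trials compare 2 or 3 treatments and report up to two correlated binary
outcomes, labelled ``R`` (e.g. response) and ``D`` (e.g. dropout).  Arm-level
data carry event/failure counts per outcome; contrast-level data carry a log
odds ratio (or any effect on an additive scale) per comparison with its
standard error.  Every contrast of a study is taken against the study's
first-listed arm, so that the shared-arm covariances of a three-arm study are
placed deterministically.

The central derived object is the :class:`ContrastBlock`: one study's observed
effect vector ``y`` together with the decomposition of its within-study
covariance into a data-estimated part ``sigma1`` (variances on the diagonal,
shared-arm covariances kappa off it) and a correlation skeleton ``sigma2``
that is scaled by the unknown within-study correlation rho.  For a two-arm
study reporting both outcomes the skeleton holds sigma_R*sigma_D in the
cross-outcome cell; for a three-arm study the cross-comparison cross-outcome
cells carry an extra factor 1/2, which follows from assuming balanced arms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("monma")

OUTCOMES = ("R", "D")

__all__ = [
    "OUTCOMES",
    "Arm",
    "Study",
    "NetworkDataset",
    "ContrastRow",
    "ContrastBlock",
    "ContrastDataset",
    "load_arm_level",
    "write_arm_level",
    "estimate_contrasts",
    "load_contrast_level",
    "write_contrast_level",
]


class NetworkDataError(ValueError):
    """Raised when input trial data violate a structural constraint."""


@dataclass
class Arm:
    """One treatment arm: per-outcome (events, failures) counts.

    An outcome key may be absent when the arm did not report it.
    """

    study_id: str
    treatment: str
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for o, (e, f) in self.counts.items():
            if o not in OUTCOMES:
                raise NetworkDataError(
                    f"study {self.study_id}: unknown outcome {o!r} (expected R or D)"
                )
            if e < 0 or f < 0 or e != int(e) or f != int(f):
                raise NetworkDataError(
                    f"study {self.study_id}, arm {self.treatment}, outcome {o}: "
                    f"events/failures must be nonnegative integers, got ({e}, {f})"
                )


@dataclass
class Study:
    """An ordered collection of 2 or 3 arms; the first arm is the base arm."""

    study_id: str
    arms: list[Arm]

    def __post_init__(self) -> None:
        n = len(self.arms)
        if not 2 <= n <= 3:
            raise NetworkDataError(
                f"study {self.study_id}: {n} arms; only 2- and 3-arm studies are "
                "supported"
            )
        trts = [a.treatment for a in self.arms]
        if len(set(trts)) != n:
            raise NetworkDataError(
                f"study {self.study_id}: duplicate treatment in arms {trts}"
            )
        # an outcome reported by some but not all arms is unusable for a contrast
        for o in OUTCOMES:
            have = [o in a.counts for a in self.arms]
            if any(have) and not all(have):
                raise NetworkDataError(
                    f"study {self.study_id}: partial outcome reporting for "
                    f"outcome {o} (present in some arms only)"
                )
        if not self.reported_outcomes:
            raise NetworkDataError(
                f"study {self.study_id}: no outcome reported in any arm"
            )

    @property
    def treatments(self) -> list[str]:
        return [a.treatment for a in self.arms]

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    @property
    def reported_outcomes(self) -> tuple[str, ...]:
        return tuple(o for o in OUTCOMES if all(o in a.counts for a in self.arms))


def _check_connected(edges_per_study: dict[str, list[tuple[str, str]]]) -> None:
    g = nx.Graph()
    for edges in edges_per_study.values():
        g.add_edges_from(edges)
    if g.number_of_nodes() and not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise NetworkDataError(
            f"treatment network is disconnected; components: {comps}"
        )


@dataclass
class NetworkDataset:
    """A connected network of studies with arm-level counts."""

    studies: list[Study]

    def __post_init__(self) -> None:
        if not self.studies:
            raise NetworkDataError("dataset contains no studies")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise NetworkDataError("duplicate study ids in dataset")
        edges = {
            s.study_id: [
                (a.treatment, b.treatment)
                for i, a in enumerate(s.arms)
                for b in s.arms[i + 1 :]
            ]
            for s in self.studies
        }
        _check_connected(edges)

    @property
    def treatments(self) -> list[str]:
        return sorted({t for s in self.studies for t in s.treatments})

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def to_contrasts(self, correction: str = "halves") -> "ContrastDataset":
        """Compute contrast-level statistics for every study."""
        blocks = [estimate_contrasts(s, correction=correction) for s in self.studies]
        return ContrastDataset(blocks)


@dataclass(frozen=True)
class ContrastRow:
    base: str
    other: str
    outcome: str

    @property
    def comparison(self) -> tuple[str, str]:
        return (self.base, self.other)


@dataclass
class ContrastBlock:
    """One study's effect vector and within-study covariance skeleton.

    ``sigma(rho) = sigma1 + rho * sigma2`` is the estimated within-study
    covariance for a given within-study correlation rho.
    """

    study_id: str
    rows: list[ContrastRow]
    y: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    n_arms: int

    def __post_init__(self) -> None:
        d = len(self.rows)
        self.y = np.asarray(self.y, dtype=float)
        self.sigma1 = np.asarray(self.sigma1, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.y.shape != (d,) or self.sigma1.shape != (d, d) or self.sigma2.shape != (d, d):
            raise NetworkDataError(
                f"study {self.study_id}: inconsistent block dimensions"
            )
        if not np.allclose(self.sigma1, self.sigma1.T) or not np.allclose(
            self.sigma2, self.sigma2.T
        ):
            raise NetworkDataError(f"study {self.study_id}: asymmetric covariance")
        if np.any(np.diag(self.sigma1) <= 0):
            raise NetworkDataError(
                f"study {self.study_id}: nonpositive variance on sigma1 diagonal"
            )
        if np.any(np.diag(self.sigma2) != 0):
            raise NetworkDataError(
                f"study {self.study_id}: sigma2 must have a zero diagonal"
            )

    @property
    def dim(self) -> int:
        return len(self.rows)

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(o for o in OUTCOMES if any(r.outcome == o for r in self.rows))

    @property
    def treatments(self) -> set[str]:
        return {t for r in self.rows for t in r.comparison}

    def sigma(self, rho: float) -> np.ndarray:
        return self.sigma1 + rho * self.sigma2

    def restrict_outcome(self, outcome: str) -> "ContrastBlock | None":
        """Subset the block to one outcome's rows (None if it has none)."""
        keep = [i for i, r in enumerate(self.rows) if r.outcome == outcome]
        if not keep:
            return None
        idx = np.asarray(keep)
        return ContrastBlock(
            study_id=self.study_id,
            rows=[self.rows[i] for i in keep],
            y=self.y[idx],
            sigma1=self.sigma1[np.ix_(idx, idx)],
            sigma2=self.sigma2[np.ix_(idx, idx)],
            n_arms=self.n_arms,
        )


@dataclass
class ContrastDataset:
    """A connected network expressed as per-study contrast blocks."""

    blocks: list[ContrastBlock]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise NetworkDataError("dataset contains no contrast blocks")
        ids = [b.study_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise NetworkDataError("duplicate study ids in contrast dataset")
        edges = {
            b.study_id: [r.comparison for r in b.rows] for b in self.blocks
        }
        _check_connected(edges)

    @property
    def treatments(self) -> list[str]:
        return sorted({t for b in self.blocks for t in b.treatments})

    @property
    def n_studies(self) -> int:
        return len(self.blocks)

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(
            o for o in OUTCOMES if any(o in b.outcomes for b in self.blocks)
        )

    def restrict_outcome(self, outcome: str) -> "ContrastDataset":
        blocks = [
            rb
            for b in self.blocks
            if (rb := b.restrict_outcome(outcome)) is not None
        ]
        if not blocks:
            raise NetworkDataError(f"no study reports outcome {outcome}")
        return ContrastDataset(blocks)


# ---------------------------------------------------------------------------
# arm-level I/O and contrast estimation
# ---------------------------------------------------------------------------

_ARM_COLUMNS = ["study_id", "treatment", "outcome", "events", "total"]


def load_arm_level(path) -> NetworkDataset:
    """Read an arm-level CSV (``study_id,treatment,outcome,events,total``).

    Failures are derived as ``total - events``.  Gzip-compressed files are
    accepted transparently.  Structural problems (duplicate rows, >3 arms,
    partial outcome reporting, disconnected networks) raise
    :class:`NetworkDataError` naming the offending study.
    """
    df = pd.read_csv(path, dtype={"study_id": str, "treatment": str, "outcome": str})
    missing = [c for c in _ARM_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkDataError(f"arm-level CSV missing columns: {missing}")
    dup = df.duplicated(subset=["study_id", "treatment", "outcome"])
    if dup.any():
        rows = df.loc[dup, ["study_id", "treatment", "outcome"]].values.tolist()
        raise NetworkDataError(f"duplicate (study, treatment, outcome) rows: {rows}")
    bad = df["total"] < df["events"]
    if bad.any():
        r = df.loc[bad].iloc[0]
        raise NetworkDataError(
            f"study {r.study_id}, arm {r.treatment}, outcome {r.outcome}: "
            f"total ({r.total}) < events ({r.events})"
        )

    studies: list[Study] = []
    for sid, g in df.groupby("study_id", sort=False):
        arms: dict[str, Arm] = {}
        # preserve first-appearance order of treatments: first arm = base arm
        for _, row in g.iterrows():
            arm = arms.setdefault(row.treatment, Arm(sid, row.treatment))
            arm.counts[row.outcome] = (int(row.events), int(row.total - row.events))
        if len(arms) > 3:
            raise NetworkDataError(
                f"study {sid}: {len(arms)} arms; only 2- and 3-arm studies are "
                "supported"
            )
        studies.append(Study(sid, list(arms.values())))

    ds = NetworkDataset(studies)
    n_by_arms = {k: sum(1 for s in studies if s.n_arms == k) for k in (2, 3)}
    n_by_outcome = {
        o: sum(1 for s in studies if o in s.reported_outcomes) for o in OUTCOMES
    }
    logger.info(
        "loaded %d studies (%s by arm count; %s report each outcome)",
        len(studies), n_by_arms, n_by_outcome,
    )
    return ds


def write_arm_level(dataset: NetworkDataset, path) -> None:
    rows = [
        {
            "study_id": s.study_id,
            "treatment": a.treatment,
            "outcome": o,
            "events": e,
            "total": e + f,
        }
        for s in dataset.studies
        for a in s.arms
        for o, (e, f) in a.counts.items()
    ]
    pd.DataFrame(rows, columns=_ARM_COLUMNS).to_csv(path, index=False)


def _log_or_and_var(
    e_b: float, f_b: float, e_o: float, f_o: float
) -> tuple[float, float]:
    y = np.log((e_o / f_o) / (e_b / f_b))
    var = 1.0 / e_b + 1.0 / f_b + 1.0 / e_o + 1.0 / f_o
    return float(y), float(var)


def estimate_contrasts(study: Study, correction: str = "halves") -> ContrastBlock:
    """Contrast statistics for one study from its arm-level binary counts.

    Effects are log odds ratios of each non-base arm versus the base (first)
    arm.  Row variances use the standard cell-reciprocal estimator
    ``1/e_base + 1/f_base + 1/e_other + 1/f_other``; for a three-arm study the
    two contrasts of one outcome share the base arm, contributing the
    shared-arm covariance ``kappa = 1/e_base + 1/f_base``.

    ``correction`` governs zero cells: ``"halves"`` adds 0.5 to all four cells
    of the affected study-outcome 2x2 table (arm x outcome status) wherever a
    zero occurs (logged); ``"none"`` raises.
    """
    if correction not in ("halves", "none"):
        raise ValueError(f"unknown continuity-correction policy {correction!r}")

    outs = study.reported_outcomes
    base = study.arms[0]
    others = study.arms[1:]

    # resolve continuity correction per (study, outcome)
    counts: dict[tuple[str, str], tuple[float, float]] = {}
    for o in outs:
        raw = {a.treatment: a.counts[o] for a in study.arms}
        if any(e == 0 or f == 0 for e, f in raw.values()):
            if correction == "none":
                arm = next(t for t, (e, f) in raw.items() if e == 0 or f == 0)
                raise NetworkDataError(
                    f"study {study.study_id}, outcome {o}, arm {arm}: zero cell "
                    "with continuity correction disabled"
                )
            logger.info(
                "study %s outcome %s: zero cell, adding 0.5 to all cells",
                study.study_id, o,
            )
            raw = {t: (e + 0.5, f + 0.5) for t, (e, f) in raw.items()}
        for t, (e, f) in raw.items():
            counts[(t, o)] = (float(e), float(f))

    rows: list[ContrastRow] = []
    for other in others:
        for o in outs:
            rows.append(ContrastRow(base.treatment, other.treatment, o))

    d = len(rows)
    y = np.zeros(d)
    sigma1 = np.zeros((d, d))
    sigma2 = np.zeros((d, d))
    sd = np.zeros(d)
    for i, r in enumerate(rows):
        e_b, f_b = counts[(r.base, r.outcome)]
        e_o, f_o = counts[(r.other, r.outcome)]
        y[i], sigma1[i, i] = _log_or_and_var(e_b, f_b, e_o, f_o)
        sd[i] = np.sqrt(sigma1[i, i])
    for i, ri in enumerate(rows):
        for j in range(i + 1, d):
            rj = rows[j]
            if ri.outcome == rj.outcome:
                # different comparisons sharing the base arm
                e_b, f_b = counts[(ri.base, ri.outcome)]
                sigma1[i, j] = sigma1[j, i] = 1.0 / e_b + 1.0 / f_b
            else:
                fac = 1.0 if ri.comparison == rj.comparison else 0.5
                sigma2[i, j] = sigma2[j, i] = fac * sd[i] * sd[j]
    return ContrastBlock(study.study_id, rows, y, sigma1, sigma2, study.n_arms)


# ---------------------------------------------------------------------------
# contrast-level I/O
# ---------------------------------------------------------------------------

_CONTRAST_COLUMNS = ["study_id", "base", "other", "outcome", "effect", "se"]


def load_contrast_level(path) -> ContrastDataset:
    """Read contrast-level data (``study_id,base,other,outcome,effect,se[,kappa]``).

    Supports any effect on an additive scale (log OR, mean difference, log
    hazard ratio).  All contrasts of a study must share one base arm.  For a
    three-arm study without a ``kappa`` column the shared-arm covariance of
    each same-outcome contrast pair is imputed as half the smaller of the two
    row variances (balanced-arm heuristic; a warning is emitted).
    """
    df = pd.read_csv(
        path, dtype={"study_id": str, "base": str, "other": str, "outcome": str}
    )
    missing = [c for c in _CONTRAST_COLUMNS if c not in df.columns]
    if missing:
        raise NetworkDataError(f"contrast-level CSV missing columns: {missing}")
    if (df["se"] <= 0).any():
        r = df.loc[df["se"] <= 0].iloc[0]
        raise NetworkDataError(
            f"study {r.study_id} ({r.base} vs {r.other}, outcome {r.outcome}): "
            f"se must be positive, got {r.se}"
        )
    has_kappa = "kappa" in df.columns

    blocks = []
    for sid, g in df.groupby("study_id", sort=False):
        bases = g["base"].unique()
        if len(bases) != 1:
            raise NetworkDataError(
                f"study {sid}: inconsistent base arms {sorted(bases)}"
            )
        others = list(dict.fromkeys(g["other"]))
        n_arms = 1 + len(others)
        if n_arms > 3:
            raise NetworkDataError(
                f"study {sid}: {n_arms} arms; only 2- and 3-arm studies are "
                "supported"
            )
        outs = [o for o in OUTCOMES if (g["outcome"] == o).any()]
        rows, y, var, kap = [], [], [], {}
        for other in others:
            for o in outs:
                sel = g[(g["other"] == other) & (g["outcome"] == o)]
                if len(sel) != 1:
                    raise NetworkDataError(
                        f"study {sid}: expected exactly one row for "
                        f"({other}, {o}), found {len(sel)}"
                    )
                rows.append(ContrastRow(bases[0], other, o))
                y.append(float(sel["effect"].iloc[0]))
                var.append(float(sel["se"].iloc[0]) ** 2)
                if has_kappa and not pd.isna(sel["kappa"].iloc[0]):
                    kap[(other, o)] = float(sel["kappa"].iloc[0])
        d = len(rows)
        sigma1 = np.diag(var)
        sigma2 = np.zeros((d, d))
        sd = np.sqrt(var)
        for i in range(d):
            for j in range(i + 1, d):
                ri, rj = rows[i], rows[j]
                if ri.outcome == rj.outcome:
                    k = kap.get((ri.other, ri.outcome), kap.get((rj.other, rj.outcome)))
                    if k is None:
                        k = 0.5 * min(var[i], var[j])
                        warnings.warn(
                            f"study {sid}: shared-arm covariance missing for "
                            f"outcome {ri.outcome}; imputing half the smaller "
                            f"row variance ({k:.4g})",
                            stacklevel=2,
                        )
                    sigma1[i, j] = sigma1[j, i] = k
                else:
                    fac = 1.0 if ri.comparison == rj.comparison else 0.5
                    sigma2[i, j] = sigma2[j, i] = fac * sd[i] * sd[j]
        blocks.append(ContrastBlock(str(sid), rows, np.array(y), sigma1, sigma2, n_arms))
    return ContrastDataset(blocks)


def write_contrast_level(dataset: ContrastDataset, path) -> None:
    """Inverse of :func:`load_contrast_level` (round-trips up to formatting)."""
    recs = []
    for b in dataset.blocks:
        for i, r in enumerate(b.rows):
            kappa = np.nan
            if b.n_arms == 3:
                same = [
                    j for j, rj in enumerate(b.rows)
                    if rj.outcome == r.outcome and j != i
                ]
                if same:
                    kappa = b.sigma1[i, same[0]]
            recs.append(
                {
                    "study_id": b.study_id,
                    "base": r.base,
                    "other": r.other,
                    "outcome": r.outcome,
                    "effect": b.y[i],
                    "se": np.sqrt(b.sigma1[i, i]),
                    "kappa": kappa,
                }
            )
    pd.DataFrame(recs).to_csv(path, index=False)
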