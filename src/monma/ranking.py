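"""Treatment ranking (SUCRA), two-dimensional ranking and precision comparison.

For an outcome, each posterior draw induces a ranking of the treatments by
their relative effects versus the reference (direction-aware: rank 1 is the
most favourable).  The surface under the cumulative ranking curve,

    SUCRA_A = sum_{k=1..N_T-1} P(A ranks among the best k) / (N_T - 1),

is 1 when A is certainly the best and 0 when certainly the worst, and equals
the normalized mean-rank transform (N_T - E[rank]) / (N_T - 1).

The precision comparison quantifies the gain of the joint model over
independent univariate syntheses as the percent reduction in credible-interval
width of each odds ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import relative_effect
from .inference import PosteriorSamples

logger = logging.getLogger("monma")

__all__ = [
    "RankingResult",
    "sucra",
    "precision_gain",
    "two_dimensional_ranking",
    "or_forest_plot",
]


@dataclass
class RankingResult:
    outcome: str
    direction: str  # "higher" or "lower" (which effect is better)
    treatments: list[str]
    rank_probs: pd.DataFrame   # treatments x ranks, P(rank = k)
    cumulative: pd.DataFrame   # treatments x ranks, P(rank <= k)
    sucra: pd.Series
    mean_rank: pd.Series


def sucra(
    samples: PosteriorSamples,
    outcome: str,
    direction: str,
) -> RankingResult:
    """Rank probabilities and SUCRA for every treatment identified for an outcome.

    ``direction`` must be given explicitly ("higher": larger effect versus the
    reference is better, e.g. response; "lower": smaller is better, e.g.
    dropout) — there is no clinical default.  Treatments without a basic
    parameter for the outcome (excluded/unidentified) are omitted.  Ties
    within a draw are broken by midrank.
    """
    if direction not in ("higher", "lower"):
        raise ValueError(
            "ranking direction must be 'higher' or 'lower' (no default)"
        )
    idx = samples.index
    treatments = [idx.reference] + [
        t for t in idx.order if (t, outcome) not in idx.excluded
    ]
    n_t = len(treatments)
    if n_t < 2:
        raise ValueError(f"fewer than 2 treatments identified for outcome {outcome}")
    flat = samples.flat_beta()
    eff = np.column_stack(
        [relative_effect(flat, idx, (idx.reference, t), outcome)
         if t != idx.reference else np.zeros(len(flat))
         for t in treatments]
    )
    signed = -eff if direction == "higher" else eff
    ranks = stats.rankdata(signed, axis=1, method="average")  # rank 1 = best

    ks = np.arange(1, n_t + 1)
    probs = np.stack([(ranks == k).mean(axis=0) for k in ks], axis=1)
    cum = np.stack([(ranks <= k).mean(axis=0) for k in ks], axis=1)
    sucra_vals = cum[:, : n_t - 1].sum(axis=1) / (n_t - 1)

    cols = [f"rank{k}" for k in ks]
    return RankingResult(
        outcome=outcome,
        direction=direction,
        treatments=treatments,
        rank_probs=pd.DataFrame(probs, index=treatments, columns=cols),
        cumulative=pd.DataFrame(cum, index=treatments, columns=cols),
        sucra=pd.Series(sucra_vals, index=treatments, name=f"sucra_{outcome}"),
        mean_rank=pd.Series(ranks.mean(axis=0), index=treatments, name="mean_rank"),
    )


def precision_gain(
    univariate: pd.DataFrame,
    multivariate: pd.DataFrame,
    outcome: str | None = None,
) -> pd.DataFrame:
    """Percent reduction in OR credible-interval width, joint vs univariate.

    Both inputs are :func:`monma.inference.or_summary` tables on the same
    comparisons.  Returns per-comparison reductions
    ``100 * (width_uni - width_multi) / width_uni`` plus an ``average`` row;
    negative values (widening) are reported as-is.
    """
    if outcome is not None:
        univariate = univariate[univariate["outcome"] == outcome]
        multivariate = multivariate[multivariate["outcome"] == outcome]
    if set(univariate.index) != set(multivariate.index) or len(univariate) == 0:
        raise ValueError(
            "univariate and multivariate summaries cover different comparisons"
        )
    multivariate = multivariate.loc[univariate.index]
    w_uni = univariate["or_upper"] - univariate["or_lower"]
    w_mult = multivariate["or_upper"] - multivariate["or_lower"]
    red = 100.0 * (w_uni - w_mult) / w_uni
    out = pd.DataFrame(
        {
            "width_univariate": w_uni,
            "width_multivariate": w_mult,
            "reduction_pct": red,
        }
    )
    out.loc["average"] = [w_uni.mean(), w_mult.mean(), red.mean()]
    return out


def or_forest_plot(
    summaries: dict[str, pd.DataFrame],
    outcome: str | None = None,
    path: str | None = None,
):
    """Forest-style plot of summary odds ratios, one marker row per comparison.

    ``summaries`` maps a model label (e.g. "univariate", "joint") to an
    :func:`monma.inference.or_summary` table; comparisons are taken from the
    first table and each model's interval is drawn slightly offset so the
    widths can be compared visually.  Returns the figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not summaries:
        raise ValueError("no summaries given")
    labels = list(summaries)
    first = summaries[labels[0]]
    if outcome is not None:
        summaries = {
            k: v[v["outcome"] == outcome] for k, v in summaries.items()
        }
        first = summaries[labels[0]]
    comparisons = list(first.index)
    n = len(comparisons)
    fig, ax = plt.subplots(figsize=(6, 0.5 * n * max(len(labels), 1) + 1.5))
    styles = ["o", "s", "^", "d"]
    for m, label in enumerate(labels):
        tab = summaries[label].reindex(comparisons)
        ys = np.arange(n)[::-1] + (m - (len(labels) - 1) / 2) * 0.22
        ax.errorbar(
            tab["or"], ys,
            xerr=[tab["or"] - tab["or_lower"], tab["or_upper"] - tab["or"]],
            fmt=styles[m % len(styles)], ms=4, lw=1.2, capsize=2, label=label,
        )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(np.arange(n)[::-1])
    ax.set_yticklabels(comparisons)
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (95% CrI)")
    if len(labels) > 1:
        ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def two_dimensional_ranking(
    rank_a: RankingResult,
    rank_b: RankingResult,
    path: str | None = None,
):
    """Scatter of SUCRA for one outcome against the other, plus its table.

    Only treatments ranked for both outcomes appear; exclusions are logged.
    Returns ``(figure, table)``; the figure is also written to ``path`` when
    given (png/svg by extension).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shared = [t for t in rank_a.treatments if t in set(rank_b.treatments)]
    if not shared:
        raise ValueError("no treatment is ranked for both outcomes")
    dropped = sorted(
        set(rank_a.treatments) ^ set(rank_b.treatments)
    )
    if dropped:
        logger.info(
            "two-dimensional ranking omits treatments ranked for one outcome "
            "only: %s", dropped,
        )
    table = pd.DataFrame(
        {
            f"sucra_{rank_a.outcome}": rank_a.sucra[shared],
            f"sucra_{rank_b.outcome}": rank_b.sucra[shared],
        }
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    x = table.iloc[:, 0]
    y = table.iloc[:, 1]
    ax.scatter(x, y, s=30, color="tab:blue", zorder=3)
    for t in shared:
        ax.annotate(t, (x[t], y[t]), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel(f"SUCRA, outcome {rank_a.outcome} ({rank_a.direction} better)")
    ax.set_ylabel(f"SUCRA, outcome {rank_b.outcome} ({rank_b.direction} better)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.grid(alpha=0.3)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig, table
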