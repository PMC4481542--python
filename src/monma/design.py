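"""Basic parameters and the design matrix embedding the consistency equations.

In a consistent network every relative effect is a linear combination of the
"basic parameters": the effects of each non-reference treatment versus the
reference, one per outcome.  A row observing the comparison (A -> B, outcome o)
with A the reference is a unit vector selecting beta[B, o]; a row (B -> C, o)
between two non-reference treatments encodes beta_BC = beta_C - beta_B with a
(-1, +1) pair.  Stacking these rows over all contrast blocks gives the design
matrix X of the linear model Y = X beta + delta + epsilon.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import OUTCOMES, ContrastDataset

__all__ = ["BasicParameterIndex", "build_design", "relative_effect", "default_reference"]


class DesignError(ValueError):
    pass


@dataclass
class BasicParameterIndex:
    """Bijection between (treatment, outcome) and columns of X.

    Columns are grouped by outcome (all R columns first, then D), each group
    ordered by ``order``.  Excluded (treatment, outcome) pairs have no column.
    """

    reference: str
    order: list[str]
    outcomes: tuple[str, ...]
    excluded: frozenset[tuple[str, str]] = frozenset()
    _col: dict[tuple[str, str], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._col = {}
        c = 0
        for o in self.outcomes:
            for t in self.order:
                if (t, o) in self.excluded:
                    continue
                self._col[(t, o)] = c
                c += 1

    @property
    def n_params(self) -> int:
        return len(self._col)

    def column(self, treatment: str, outcome: str) -> int | None:
        """Column of a basic parameter; None for the reference treatment."""
        if treatment == self.reference:
            return None
        try:
            return self._col[(treatment, outcome)]
        except KeyError:
            raise DesignError(
                f"treatment {treatment} has no basic parameter for outcome "
                f"{outcome} (not in network or excluded)"
            ) from None

    @property
    def names(self) -> list[str]:
        inv = sorted(self._col.items(), key=lambda kv: kv[1])
        return [f"beta[{t},{o}]" for (t, o), _ in inv]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "reference": self.reference,
                    "columns": {f"{t}|{o}": c for (t, o), c in self._col.items()},
                },
                fh,
                indent=2,
            )


def default_reference(dataset: ContrastDataset) -> str:
    """Treatment appearing in the most study arms; ties broken lexically."""
    counts: Counter[str] = Counter()
    for b in dataset.blocks:
        for t in sorted(b.treatments):
            counts[t] += 1
    top = max(counts.values())
    return min(t for t, c in counts.items() if c == top)


def build_design(
    dataset: ContrastDataset,
    reference: str | None = None,
    exclude: list[tuple[str, str]] | None = None,
) -> tuple[np.ndarray, BasicParameterIndex]:
    """Stack the consistency-equation rows of all blocks into X.

    Raises :class:`DesignError` if a basic parameter would receive no data
    (its column of X is all zero) — e.g. a drug reported only for dropout is
    unidentified for response and must be excluded explicitly for that
    outcome via ``exclude=[(drug, "R")]``.
    """
    if reference is None:
        reference = default_reference(dataset)
    treatments = dataset.treatments
    if reference not in treatments:
        raise DesignError(f"reference treatment {reference!r} not in network")
    excluded = frozenset(exclude or [])
    for t, o in excluded:
        if t == reference:
            raise DesignError("cannot exclude the reference treatment")
    order = [t for t in treatments if t != reference]
    index = BasicParameterIndex(reference, order, dataset.outcomes, excluded)

    n_rows = sum(b.dim for b in dataset.blocks)
    X = np.zeros((n_rows, index.n_params))
    i = 0
    for b in dataset.blocks:
        for r in b.rows:
            for t, sign in ((r.base, -1.0), (r.other, +1.0)):
                if t == reference:
                    continue
                if (t, r.outcome) in excluded:
                    raise DesignError(
                        f"study {b.study_id} observes ({t}, {r.outcome}), "
                        "which was excluded from the parameterization"
                    )
                X[i, index.column(t, r.outcome)] = sign
            i += 1

    empty = np.flatnonzero(~np.any(X != 0.0, axis=0))
    if empty.size:
        names = [index.names[c] for c in empty]
        raise DesignError(
            f"treatment unidentified for outcome: no data reach {names}; "
            "exclude these (treatment, outcome) pairs or drop the treatment"
        )
    return X, index


def relative_effect(
    beta_draws: np.ndarray,
    index: BasicParameterIndex,
    pair: tuple[str, str],
    outcome: str,
) -> np.ndarray:
    """Per-draw relative effect of pair[1] versus pair[0] for an outcome.

    ``beta_draws`` has the basic parameters on its last axis.  Under
    consistency the effect is beta[T2, o] - beta[T1, o]; either treatment may
    be the reference (contributing 0).
    """
    t1, t2 = pair
    beta_draws = np.asarray(beta_draws)
    c1 = index.column(t1, outcome)
    c2 = index.column(t2, outcome)
    e1 = beta_draws[..., c1] if c1 is not None else 0.0
    e2 = beta_draws[..., c2] if c2 is not None else 0.0
    return e2 - e1


def export_design(X: np.ndarray, index: BasicParameterIndex, path) -> None:
    """Dense CSV dump of X with named columns, for debugging."""
    pd.DataFrame(X, columns=index.names).to_csv(path, index=False)
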