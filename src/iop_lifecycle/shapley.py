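"""Shapley decomposition of the dissimilarity index by circumstance group.

Each "player" is a named group of circumstance columns (a single circumstance
or a block such as all socio-economic variables).  The value of a coalition S
is D(S): the dissimilarity index obtained by re-fitting the circumstance
logit using only the columns belonging to the players in S and evaluating
the index on the resulting counterfactual distribution.  D of the empty
coalition is 0 — an intercept-only model predicts the same probability for
everyone.

The relative contribution of player c is its Shapley value divided by the
full-model index:

    RC_c = sum_{S : c in S} (N-|S|)! (|S|-1)! / N! * [D(S) - D(S\\{c})] / D(CI)

equivalently the average of its marginal contributions over all N! orders of
inclusion.  Shares always sum to 1 (efficiency); individual shares can be
negative because the marginals are signed.

Subsets whose logit cannot be fitted (separation, non-convergence) fall back
to the grouped-empirical-means predictor so a single ill-behaved coalition
does not poison the whole decomposition; the fallback is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

from .exceptions import CellDegenerate, RankDeficientDesign, ShareUndefined
from .iop import (
    dissimilarity_index,
    empirical_type_means,
    fit_logit,
    predict_counterfactual,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ShapleySpec",
    "ShapleyResult",
    "d_of_subset",
    "shapley_decompose",
    "aggregate_contributions",
]


@dataclass
class ShapleySpec:
    """What to decompose and how.

    Parameters
    ----------
    players : mapping player label -> iterable of circumstance column names.
        Players must be disjoint; together they define the circumstance set.
    method : "exact" (enumerate all 2^N coalitions) or "sampling" (uniform
        random orderings).  Exact is the default and the required path for
        small N.
    n_permutations, seed : sampling method only.
    """

    players: dict
    method: str = "exact"
    n_permutations: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if not self.players:
            raise ValueError("at least one player required")
        seen = set()
        for label, cols in self.players.items():
            cols = list(cols)
            if not cols:
                raise ValueError(f"player {label!r} has no circumstances")
            overlap = seen.intersection(cols)
            if overlap:
                raise ValueError(f"players overlap on columns {sorted(overlap)}")
            seen.update(cols)
        if self.method not in ("exact", "sampling"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "sampling":
            if self.n_permutations is None or self.n_permutations < 1:
                raise ValueError("sampling requires n_permutations >= 1")
            if self.seed is None:
                raise ValueError("sampling requires a seed")

    @property
    def labels(self):
        return list(self.players.keys())

    def columns(self, subset) -> list:
        cols = []
        for label in self.labels:  # canonical order
            if label in subset:
                cols.extend(self.players[label])
        return cols


@dataclass
class ShapleyResult:
    """Relative contributions of each player to the cell's D index."""

    rc: dict
    d_full: float
    d_by_subset: dict = field(default_factory=dict)
    cell: object = None
    method: str = "exact"
    se: dict | None = None  # Monte-Carlo SE per player (sampling only)

    def summary(self) -> str:
        lines = [
            "Shapley decomposition of the dissimilarity index",
            "=" * 48,
            f"cell:    {self.cell}",
            f"D(full): {self.d_full:.4f}    method: {self.method}",
            "-" * 48,
            f"{'player':<22}{'share':>10}{'share %':>10}",
        ]
        for label, share in self.rc.items():
            lines.append(f"{label:<22}{share:>10.4f}{100 * share:>9.1f}%")
        lines.append("-" * 48)
        total = sum(self.rc.values())
        lines.append(f"{'total':<22}{total:>10.4f}{100 * total:>9.1f}%")
        return "\n".join(lines)


def d_of_subset(records: pd.DataFrame, columns, outcome: str) -> float:
    """D index from a logit restricted to ``columns``; 0 for the empty set.

    Falls back to within-type empirical means when the restricted logit is
    unusable (separation, non-convergence, collinearity among the subset's
    columns).
    """
    columns = list(columns)
    if not columns:
        return 0.0
    try:
        fit = fit_logit(records, outcome, columns)
        bad = fit.separation_flag or not fit.converged
    except RankDeficientDesign:
        fit, bad = None, True
    if bad:
        logger.info("subset %s: logit unusable, using type-mean fallback", columns)
        yhat = empirical_type_means(records, columns, outcome)
    else:
        yhat = predict_counterfactual(fit, records)
    try:
        return dissimilarity_index(yhat)
    except CellDegenerate:
        return 0.0


def _subset_values(records, spec, outcome):
    """D(S) for every coalition, memoised, bitmask-ascending enumeration."""
    labels = spec.labels
    values = {}
    for size in range(len(labels) + 1):
        for combo in combinations(labels, size):
            key = frozenset(combo)
            values[key] = d_of_subset(records, spec.columns(key), outcome)
    return values


def shapley_decompose(
    records: pd.DataFrame,
    spec: ShapleySpec,
    outcome: str,
    cell=None,
) -> ShapleyResult:
    """Decompose the cell's D index into per-player relative contributions.

    Raises :class:`ShareUndefined` when the full-model index is zero.
    """
    labels = spec.labels
    n_players = len(labels)

    if spec.method == "exact":
        values = _subset_values(records, spec, outcome)
        d_full = values[frozenset(labels)]
        if d_full <= 0.0:
            raise ShareUndefined("full-model D index is zero")
        fact = factorial
        rc = {}
        for c in labels:
            others = [p for p in labels if p != c]
            total = 0.0
            for size in range(n_players):
                w = fact(n_players - size - 1) * fact(size) / fact(n_players)
                for combo in combinations(others, size):
                    s_without = frozenset(combo)
                    s_with = s_without | {c}
                    total += w * (values[s_with] - values[s_without])
            rc[c] = total / d_full
        return ShapleyResult(rc=rc, d_full=d_full, d_by_subset=values,
                             cell=cell, method="exact")

    # sampling: uniform random orderings, incremental marginals
    rng = np.random.default_rng(spec.seed)
    cache = {frozenset(): 0.0}

    def value(key):
        if key not in cache:
            cache[key] = d_of_subset(records, spec.columns(key), outcome)
        return cache[key]

    d_full = value(frozenset(labels))
    if d_full <= 0.0:
        raise ShareUndefined("full-model D index is zero")

    draws = {c: [] for c in labels}
    order_idx = np.arange(n_players)
    for _ in range(spec.n_permutations):
        rng.shuffle(order_idx)
        prefix = frozenset()
        prev = 0.0
        for i in order_idx:
            c = labels[i]
            prefix = prefix | {c}
            cur = value(prefix)
            draws[c].append(cur - prev)
            prev = cur
    rc = {c: float(np.mean(v)) / d_full for c, v in draws.items()}
    se = {
        c: float(np.std(v, ddof=1) / np.sqrt(len(v))) / d_full
        if len(v) > 1 else np.nan
        for c, v in draws.items()
    }
    return ShapleyResult(rc=rc, d_full=d_full, d_by_subset=dict(cache),
                         cell=cell, method="sampling", se=se)


def aggregate_contributions(result: ShapleyResult, super_groups: dict) -> dict:
    """Sum player shares into super-groups.

    ``super_groups`` maps a super-group label to the player labels it
    absorbs and must partition the players of ``result`` exactly.
    """
    players = set(result.rc)
    claimed = [p for members in super_groups.values() for p in members]
    if len(claimed) != len(set(claimed)) or set(claimed) != players:
        raise ValueError(
            "super_groups must partition the players: "
            f"have {sorted(players)}, got {sorted(claimed)}"
        )
    return {
        label: float(sum(result.rc[p] for p in members))
        for label, members in super_groups.items()
    }
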