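"""Reliability checks for predicted compound–target interactions.

The recovery test asks whether a set of predicted pairs overlaps a validated
gold standard more than chance would allow, given the universe of all
predictable pairs. Two routes answer it: an exact hypergeometric upper tail
P(X >= k) and an empirical permutation null that redraws the predicted set
uniformly from the universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "RecoveryTestResult",
    "hypergeometric_recovery_test",
    "empirical_recovery_null",
    "empirical_pvalue",
]


@dataclass
class RecoveryTestResult:
    """Outcome of the predicted-vs-validated overlap test.

    N = all predictable pairs, K = validated pairs within them, n = pairs
    called positive by the predictor, k = validated pairs recovered.
    """

    n_universe: int
    n_gold: int
    n_predicted: int
    n_overlap: int
    p_hypergeometric: float
    p_empirical: float | None = None
    n_permutations: int = 0

    def as_dict(self) -> dict:
        return {
            "n_universe": self.n_universe,
            "n_gold": self.n_gold,
            "n_predicted": self.n_predicted,
            "n_overlap": self.n_overlap,
            "p_hypergeometric": self.p_hypergeometric,
            "p_empirical": self.p_empirical,
            "n_permutations": self.n_permutations,
        }


def _as_pair_set(pairs: Iterable) -> set:
    return {tuple(p) for p in pairs}


def hypergeometric_recovery_test(
    universe: Iterable, gold: Iterable, predicted: Iterable
) -> RecoveryTestResult:
    """Exact over-representation tail P(X >= k) of the recovered overlap.

    X follows a hypergeometric(N, K, n) law: draw n pairs from the universe
    of N, of which K are gold, and count gold draws. The at-least-k upper
    tail is the conventional over-representation p-value.
    """
    universe = _as_pair_set(universe)
    gold = _as_pair_set(gold)
    predicted = _as_pair_set(predicted)
    stray_gold = gold - universe
    if stray_gold:
        raise ValidationError(
            f"gold pair(s) outside the universe: {sorted(stray_gold)[:5]}"
        )
    stray_pred = predicted - universe
    if stray_pred:
        raise ValidationError(
            f"predicted pair(s) outside the universe: {sorted(stray_pred)[:5]}"
        )
    N, K, n = len(universe), len(gold), len(predicted)
    k = len(gold & predicted)
    # sf(k-1) = P(X >= k); exact, no continuity games.
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    return RecoveryTestResult(
        n_universe=N, n_gold=K, n_predicted=n, n_overlap=k, p_hypergeometric=p
    )


def empirical_recovery_null(
    universe: Iterable,
    gold: Iterable,
    n_predicted: int,
    n_permutations: int,
    rng: np.random.Generator,
) -> list[int]:
    """Permutation null: overlap-with-gold counts of random predicted sets.

    Each permutation draws ``n_predicted`` pairs uniformly without
    replacement from the universe and records how many are gold. Determinism
    follows the supplied generator.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    universe = sorted(_as_pair_set(universe))
    gold = _as_pair_set(gold)
    if n_predicted > len(universe):
        raise ValidationError(
            f"cannot draw {n_predicted} pairs from a universe of {len(universe)}"
        )
    is_gold = np.fromiter((p in gold for p in universe), dtype=bool)
    counts = []
    for _ in range(n_permutations):
        idx = rng.choice(len(universe), size=n_predicted, replace=False)
        counts.append(int(is_gold[idx].sum()))
    return counts


def empirical_pvalue(null_counts: Iterable[int], observed: int) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (1 + n).

    The pseudo-count keeps the estimate strictly positive, as a permutation
    p of exactly zero is an artifact of finite resampling.
    """
    counts = list(null_counts)
    if not counts:
        raise ValidationError("empty null sample")
    hits = sum(1 for c in counts if c >= observed)
    return (1 + hits) / (1 + len(counts))
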