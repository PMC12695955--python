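"""Permutation test for paired beach distances.

The null hypothesis is that a female's pupping beach is unrelated to her
natal (or first-pupping) beach: any alignment of the two beach columns is
equally likely.  Shuffling one column against the other and recomputing the
mean (or median) pair distance builds a Monte-Carlo null distribution; the
one-tailed lower p-value is the fraction of shuffled statistics less than
or equal to the observed one, reflecting the directional alternative that
observed distances are *shorter* than chance (philopatry / fidelity).

Shuffling only the second column is equivalent to shuffling the pair
alignment itself: the statistic depends only on which beach of column A is
matched with which beach of column B.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .geo import DistanceMatrix

StatisticKind = Literal["mean", "median"]


@dataclass(frozen=True)
class PermutationResult:
    statistic_kind: StatisticKind
    observed_m: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    n_pairs: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_median(self) -> float:
        return float(np.median(self.null_values))

    def p_label(self) -> str:
        """Human-readable p; a zero count reports the resolution bound."""
        if self.p_value == 0.0:
            return f"p < {1.0 / self.n_perm:g}"
        return f"p = {self.p_value:g}"

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "statistic_kind": self.statistic_kind,
            "observed_m": self.observed_m,
            "p_value": self.p_value,
            "p_label": self.p_label(),
            "n_perm": self.n_perm,
            "n_pairs": self.n_pairs,
            "seed": self.seed,
            "null_mean_m": self.null_mean,
            "null_median_m": self.null_median,
        }
        if include_null:
            out["null_values_m"] = [float(v) for v in self.null_values]
        return out

    def write_json(self, path: str | Path, include_null: bool = False) -> None:
        Path(path).write_text(json.dumps(self.to_dict(include_null), indent=1))


def _statistic(kind: StatisticKind):
    if kind == "mean":
        return np.mean
    if kind == "median":
        return np.median
    raise ValueError(f"unknown statistic kind {kind!r}")


def _pair_indices(
    beach_a: Sequence[str], beach_b: Sequence[str], matrix: DistanceMatrix
) -> tuple[np.ndarray, np.ndarray]:
    if len(beach_a) != len(beach_b):
        raise ValueError(
            f"beach lists must be aligned: {len(beach_a)} vs {len(beach_b)}"
        )
    ia = np.array([matrix.index_of(c) for c in beach_a])
    ib = np.array([matrix.index_of(c) for c in beach_b])
    return ia, ib


def permutation_test(
    beach_a: Sequence[str],
    beach_b: Sequence[str],
    matrix: DistanceMatrix,
    statistic_kind: StatisticKind = "mean",
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Monte-Carlo permutation test of paired beach distances.

    Each replicate draws a uniform random permutation of ``beach_b`` against
    the fixed ``beach_a``, recomputes distances by matrix lookup, and records
    the statistic.  ``p = #(null <= observed) / n_perm``; identical seeds
    give identical results.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ia, ib = _pair_indices(beach_a, beach_b, matrix)
    stat = _statistic(statistic_kind)
    observed = float(stat(matrix.values[ia, ib]))

    rng = np.random.default_rng(seed)
    n = len(ia)
    null_values = np.empty(n_perm)
    dist_rows = matrix.values[ia]  # (n, n_sites): distances from each natal beach
    for k in range(n_perm):
        perm = rng.permutation(n)
        null_values[k] = stat(dist_rows[np.arange(n), ib[perm]])

    p = float(np.count_nonzero(null_values <= observed)) / n_perm
    return PermutationResult(
        statistic_kind=statistic_kind,
        observed_m=observed,
        null_values=null_values,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        n_pairs=n,
    )


def exhaustive_null(
    beach_a: Sequence[str],
    beach_b: Sequence[str],
    matrix: DistanceMatrix,
    statistic_kind: StatisticKind = "mean",
    max_n: int = 8,
) -> float:
    """Exact one-tailed lower p from enumeration of all n! permutations.

    Intended as a small-sample oracle; guarded at ``n <= max_n``.
    """
    ia, ib = _pair_indices(beach_a, beach_b, matrix)
    n = len(ia)
    if n > max_n:
        raise ValueError(f"exhaustive_null limited to n <= {max_n} (got {n})")
    stat = _statistic(statistic_kind)
    observed = stat(matrix.values[ia, ib])
    count = 0
    total = 0
    for perm in permutations(range(n)):
        value = stat(matrix.values[ia, ib[list(perm)]])
        count += value <= observed
        total += 1
    assert total == math.factorial(n)
    return count / total
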