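"""Baselines and validation harness for the influencer-set heuristics.

On tiny graphs the global optimum is available by exhaustive search; on
larger ones the heuristic pick is judged against the distribution of F
over random k-subsets: its sampled mean E_L[F_k] (what a random guess
buys), the best-of-L sampled value M_L[F_k] (an empirical lower-tail
quantile), and the ratios of both to F(A_hat).  A Chebyshev bound plans
how many independent replications are needed to pin down a lower-tail
threshold c with given half-width and confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph_core import Network, VertexSet, all_k_subsets
from .hitting_exact import objective_F
from .optimizer import HeuristicResult

__all__ = [
    "SampleSummary",
    "ExhaustiveBudgetError",
    "n_candidate_subsets",
    "exhaustive_optimum",
    "expected_F_sampled",
    "best_of_samples",
    "improvement_ratios",
    "chebyshev_repetitions",
    "tail_threshold_estimate",
]


class ExhaustiveBudgetError(RuntimeError):
    """C(|V|, k) exceeds the configured enumeration budget."""


@dataclass(frozen=True)
class SampleSummary:
    """Distribution summary of F over L uniformly sampled k-subsets."""

    L: int
    mu: float
    sigma: float
    se: float
    min_F: float
    argmin: tuple

    def __post_init__(self):
        assert self.min_F <= self.mu + 1e-9


def n_candidate_subsets(n: int, k: int) -> int:
    """Size of the exhaustive search space: C(n, k)."""
    return math.comb(n, k)


def exhaustive_optimum(
    net: Network, k: int, budget: int = 100_000
) -> tuple[VertexSet, float]:
    """Global minimizer of exact F over all k-subsets, ties lexicographic.

    Refuses to run when C(|V|, k) exceeds ``budget`` — full sweeps at the
    scale of real networks take millions of linear solves and belong to
    dedicated offline runs, not this helper.
    """
    if not 1 <= k < net.n:
        raise ValueError("need 1 <= k < |V|")
    n_sets = n_candidate_subsets(net.n, k)
    if n_sets > budget:
        raise ExhaustiveBudgetError(
            f"C({net.n},{k}) = {n_sets} exceeds budget {budget}"
        )
    best_S, best_F = None, math.inf
    for S in all_k_subsets(range(net.n), k):
        F = objective_F(net, S)
        if F < best_F - 1e-12:
            best_S, best_F = S, F
    return VertexSet.of(net, best_S), best_F


def expected_F_sampled(net: Network, k: int, L: int, seed: int = 0) -> SampleSummary:
    """Sampled mean of F over random k-subsets (uniform, with replacement).

    L >= 30 is required so the normal approximation behind the reported
    standard error se = sigma / sqrt(L) is defensible.
    """
    if L < 30:
        raise ValueError("L >= 30 required for the CLT-based summary")
    if not 1 <= k < net.n:
        raise ValueError("need 1 <= k < |V|")
    rng = np.random.default_rng(seed)
    values = np.empty(L)
    sets = []
    for i in range(L):
        S = tuple(sorted(rng.choice(net.n, size=k, replace=False)))
        sets.append(S)
        values[i] = objective_F(net, S)
    i_min = int(values.argmin())
    return SampleSummary(
        L=L,
        mu=float(values.mean()),
        sigma=float(values.std(ddof=1)),
        se=float(values.std(ddof=1) / math.sqrt(L)),
        min_F=float(values[i_min]),
        argmin=sets[i_min],
    )


def best_of_samples(summary: SampleSummary) -> float:
    """Best-of-L sampled value M_L[F_k] = min over the L sampled subsets."""
    return summary.min_F


def improvement_ratios(
    net: Network, k: int, result: HeuristicResult, summary: SampleSummary
) -> tuple[float, float]:
    """(E_L[F_k]/F(A_hat), M_L[F_k]/F(A_hat)) — how much the heuristic beats
    a random guess and the best of L random guesses."""
    if result.A_hat.k != k:
        raise ValueError("result cardinality does not match k")
    F_hat = result.best_F
    return summary.mu / F_hat, summary.min_F / F_hat


def chebyshev_repetitions(var_c: float, eps: float, conf: float) -> int:
    """Independent replications T so that the averaged tail-threshold
    estimate lies within eps of c with the given confidence.

    From Chebyshev's inequality the confidence after T replications is
    1 - Var(c)/(T eps^2); solving for the smallest adequate T gives
    T = ceil(Var(c) / ((1 - conf) eps^2)).
    """
    if var_c < 0:
        raise ValueError("variance must be >= 0")
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if not 0 < conf < 1:
        raise ValueError("confidence must lie in (0, 1)")
    if var_c == 0:
        return 1
    T = var_c / ((1 - conf) * eps**2)
    # guard the ceiling against float noise (e.g. 4/0.1 -> 40.000000000000006)
    return max(1, math.ceil(T - 1e-9))


def tail_threshold_estimate(values) -> float:
    """Estimate c_hat of the lower-tail threshold: the largest F value among
    the final-stage candidates of one heuristic run."""
    values = list(values)
    if not values:
        raise ValueError("need at least one final-stage value")
    return float(max(values))
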