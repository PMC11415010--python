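"""Multi-stage hub heuristics for the minimum-hitting-time set problem.

Exhaustive minimization of F(A) over all (|V| choose k) subsets is
infeasible beyond tiny graphs, so both heuristics restrict the search to
sets built from the h highest-degree vertices (hubs), which act as
attractors for random walks on heavy-tailed networks:

* combinatorial: enumerate all k-subsets of the hub pool, keep the b with
  the largest p-neighborhood coverage, then the q with the smallest
  farness C (a lower bound on F, hence a conservative screen), rank those
  by a cheap Monte Carlo estimate F_{M1} and re-rank the survivors with a
  larger budget F_{M2};
* semi-greedy: seed with the hub pair of largest joint coverage (starting
  from a pair rather than the single top hub avoids an obvious local
  minimum), then repeatedly add the hub with the largest coverage gain
  until |A| = k.

A final fallback compares the heuristic pick against the plain top-k-hub
set and returns whichever has the smaller (estimated or exact) F.

All argmax/argmin ties are broken by lexicographic vertex order, so every
stage is deterministic given the parameters and seed.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

from .graph_core import Network, VertexSet, farness, neighborhood
from .hitting_exact import objective_F
from .hitting_mc import McEstimate, WalkConfig, estimate_F

__all__ = [
    "HeuristicParams",
    "HeuristicResult",
    "StageRecord",
    "CandidateBudgetError",
    "top_hubs",
    "coverage_rank",
    "combinatorial_search",
    "semi_greedy_search",
    "hub_fallback",
    "n_hub_subsets",
]


class CandidateBudgetError(RuntimeError):
    """The combinatorial stage would enumerate too many candidate sets."""


@dataclass(frozen=True)
class HeuristicParams:
    """Search-depth and budget knobs for the multi-stage heuristics.

    k      target-set cardinality
    h      hub pool size (default 10k; h = |V| makes the combinatorial
           variant an exhaustive search)
    p      neighborhood radius for the coverage stage (1 = friends,
           2 = friends of friends; 1 suits large graphs)
    b, q   survivors of the coverage and farness screens
    M1, M2 Monte Carlo budgets of the preliminary and refinement rankings
    """

    k: int
    h: int | None = None
    p: int = 1
    b: int = 5
    q: int = 5
    M1: int = 100
    M2: int = 10_000

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not 1 <= self.q <= self.b:
            raise ValueError("need 1 <= q <= b")
        if not 1 <= self.M1 <= self.M2:
            raise ValueError("need M2 >= M1 >= 1")

    def pool_size(self, net: Network) -> int:
        h = 10 * self.k if self.h is None else self.h
        h = min(h, net.n)
        if h < self.k:
            raise ValueError(f"hub pool h={h} smaller than k={self.k}")
        return h


@dataclass(frozen=True)
class StageRecord:
    """One pruning stage: its name, how many sets it kept, and (when small
    enough to store) the kept sets themselves as sorted index tuples."""

    name: str
    size: int
    kept: tuple | None = None


@dataclass(frozen=True)
class HeuristicResult:
    """Selected set with its screen value, F estimates, and stage provenance."""

    A_hat: VertexSet
    C_value: float
    F_estimate: McEstimate | None
    F_exact: float | None
    stage_log: tuple[StageRecord, ...]
    method: str

    @property
    def best_F(self) -> float:
        return self.F_exact if self.F_exact is not None else self.F_estimate.F_M

    def to_json(self, net: Network) -> str:
        return json.dumps(
            {
                "method": self.method,
                "A": [str(l) for l in net.to_labels(self.A_hat)],
                "k": self.A_hat.k,
                "C": self.C_value,
                "F_M": None if self.F_estimate is None else self.F_estimate.F_M,
                "F_exact": self.F_exact,
                "stages": [[r.name, r.size] for r in self.stage_log],
            }
        )


def n_hub_subsets(h: int, k: int) -> int:
    """Number of k-subsets the combinatorial stage enumerates: C(h, k)."""
    return math.comb(h, k)


def top_hubs(net: Network, h: int) -> list[int]:
    """The h highest-degree vertices, ties broken by ascending vertex index."""
    if h > net.n:
        raise ValueError(f"h={h} exceeds |V|={net.n}")
    deg = net.degrees
    order = sorted(range(net.n), key=lambda v: (-deg[v], v))
    return order[:h]


def coverage_rank(net: Network, candidates, p: int, b: int) -> list[tuple]:
    """The b candidate sets with the largest p-neighborhood |N^p[S]|.

    Ties broken lexicographically on the sorted members, so disjoint hub
    pairs outrank overlapping ones of equal degree.
    """
    scored = sorted(
        (tuple(sorted(S)) for S in candidates),
        key=lambda S: (-len(neighborhood(net, S, p)), S),
    )
    return scored[:b]


def _farness_rank(net: Network, candidates, q: int) -> list[tuple]:
    scored = sorted(candidates, key=lambda S: (farness(net, S), S))
    return scored[:q]


def _mc_rank(net: Network, candidates, M: int, seed: int, step_cap=None):
    """Rank candidate sets by F_M, smaller first; deterministic child seeds."""
    scored = []
    for idx, S in enumerate(candidates):
        cfg = WalkConfig(M=M, seed=(seed * 1_000_003 + idx) % (2**31), step_cap=step_cap)
        est = estimate_F(net, S, cfg)
        scored.append((est.F_M, S, est))
    scored.sort(key=lambda x: (x[0], x[1]))
    return scored


def _finalize(
    net: Network,
    survivors: list[tuple],
    params: HeuristicParams,
    seed: int,
    exact_final: bool,
    method: str,
    stage_log: list[StageRecord],
    compute_exact: bool,
) -> HeuristicResult:
    """Final F-based ranking of the surviving candidate sets."""
    if exact_final:
        scored = sorted(survivors, key=lambda S: (objective_F(net, S), S))
        A_hat = scored[0]
        stage_log.append(StageRecord("exact_final", 1, (A_hat,)))
        return HeuristicResult(
            A_hat=VertexSet.of(net, A_hat),
            C_value=farness(net, A_hat),
            F_estimate=None,
            F_exact=objective_F(net, A_hat),
            stage_log=tuple(stage_log),
            method=method,
        )
    prelim = _mc_rank(net, survivors, params.M1, seed)
    n_refine = max(1, math.ceil(len(survivors) / 2))
    finalists = [S for _, S, _ in prelim[:n_refine]]
    stage_log.append(StageRecord("mc_prelim", len(finalists), tuple(finalists)))
    refined = _mc_rank(net, finalists, params.M2, seed + 1)
    _, A_hat, est = refined[0]
    stage_log.append(StageRecord("mc_refine", 1, (A_hat,)))
    return HeuristicResult(
        A_hat=VertexSet.of(net, A_hat),
        C_value=farness(net, A_hat),
        F_estimate=est,
        F_exact=objective_F(net, A_hat) if compute_exact else None,
        stage_log=tuple(stage_log),
        method=method,
    )


def combinatorial_search(
    net: Network,
    params: HeuristicParams,
    seed: int = 0,
    exact_final: bool = False,
    compute_exact: bool = False,
    candidate_budget: int = 200_000,
) -> HeuristicResult:
    """Enumerative hub heuristic: screen all k-subsets of the hub pool.

    Stages: C(h,k) candidates -> b best by p-neighborhood coverage -> q
    best (smallest) by farness -> Monte Carlo ranking (or exact F when
    ``exact_final``).  With h = |V|, b = q = C(h,k) and exact_final the
    search is exhaustive.
    """
    h = params.pool_size(net)
    n_cand = n_hub_subsets(h, params.k)
    if n_cand > candidate_budget:
        raise CandidateBudgetError(
            f"C({h},{params.k}) = {n_cand} exceeds the candidate budget "
            f"{candidate_budget}; use semi_greedy_search for this size"
        )
    hubs = top_hubs(net, h)
    candidates = list(itertools.combinations(sorted(hubs), params.k))
    stage_log = [StageRecord("hub_subsets", n_cand,
                             tuple(candidates) if n_cand <= 10_000 else None)]
    B = coverage_rank(net, candidates, params.p, params.b)
    stage_log.append(StageRecord("coverage", len(B), tuple(B)))
    Q = _farness_rank(net, B, params.q)
    stage_log.append(StageRecord("farness", len(Q), tuple(Q)))
    return _finalize(
        net, Q, params, seed, exact_final, "combinatorial", stage_log, compute_exact
    )


def semi_greedy_search(
    net: Network,
    params: HeuristicParams,
    seed: int = 0,
    exact_final: bool = False,
    compute_exact: bool = False,
) -> HeuristicResult:
    """Incremental hub heuristic for larger k.

    Seeds with the hub pair of largest joint p-neighborhood over all
    C(h,2) pairs, then greedily adds the hub with the largest coverage
    gain until |A| = k; reports C(A_hat) and the Monte Carlo F_M (or
    exact F when requested).  k = 1 degenerates to the single hub with
    the best coverage.
    """
    h = params.pool_size(net)
    hubs = sorted(top_hubs(net, h))
    cover = {v: neighborhood(net, (v,), params.p) for v in hubs}
    stage_log = [StageRecord("hub_pool", len(hubs), tuple((v,) for v in hubs))]

    if params.k == 1:
        best = min(hubs, key=lambda v: (-len(cover[v]), v))
        A = [best]
        stage_log.append(StageRecord("seed", 1, ((best,),)))
    else:
        pairs = itertools.combinations(hubs, 2)
        best_pair = min(
            pairs, key=lambda uv: (-len(cover[uv[0]] | cover[uv[1]]), uv)
        )
        A = list(best_pair)
        stage_log.append(StageRecord("seed_pair", 1, (best_pair,)))
        covered = cover[best_pair[0]] | cover[best_pair[1]]
        while len(A) < params.k:
            rest = [v for v in hubs if v not in A]
            v_star = min(rest, key=lambda v: (-len(cover[v] - covered), v))
            A.append(v_star)
            covered |= cover[v_star]
        A = sorted(A)
        stage_log.append(StageRecord("greedy_grow", 1, (tuple(A),)))

    return _finalize(
        net, [tuple(A)], params, seed, exact_final, "semi_greedy", stage_log,
        compute_exact,
    )


def hub_fallback(
    net: Network,
    k: int,
    result: HeuristicResult,
    seed: int = 0,
    M: int | None = None,
) -> HeuristicResult:
    """Guard against rare cases where the plain top-k-hub set wins.

    Evaluates F for the k highest-degree vertices and returns whichever
    of {heuristic result, hub set} is smaller, compared with exact F when
    the result carries one, otherwise with a matched Monte Carlo budget.
    """
    hub_set = tuple(sorted(top_hubs(net, k)))
    if hub_set == result.A_hat.sorted():
        return result
    stage_log = result.stage_log + (StageRecord("hub_fallback", 1, (hub_set,)),)
    if result.F_exact is not None:
        F_hub = objective_F(net, hub_set)
        if F_hub >= result.F_exact:
            return result
        return HeuristicResult(
            A_hat=VertexSet.of(net, hub_set),
            C_value=farness(net, hub_set),
            F_estimate=None,
            F_exact=F_hub,
            stage_log=stage_log,
            method=result.method + "+hub_fallback",
        )
    M = result.F_estimate.M if M is None else M
    est_hub = estimate_F(net, hub_set, WalkConfig(M=M, seed=seed))
    if est_hub.F_M >= result.F_estimate.F_M:
        return result
    return HeuristicResult(
        A_hat=VertexSet.of(net, hub_set),
        C_value=farness(net, hub_set),
        F_estimate=est_hub,
        F_exact=None,
        stage_log=stage_log,
        method=result.method + "+hub_fallback",
    )
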