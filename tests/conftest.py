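"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's linear-algebra path: farness
is recomputed from networkx all-pairs BFS, and hitting times from a
truncated path-space dynamic program over plain adjacency dicts.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from firsthit import GraphSpec, generate, from_nx


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def path3():
    return generate(GraphSpec("path", 3))


@pytest.fixture(scope="session")
def k2():
    return generate(GraphSpec("complete", 2))


@pytest.fixture(scope="session")
def k3():
    return generate(GraphSpec("complete", 3))


@pytest.fixture(scope="session")
def k4():
    return generate(GraphSpec("complete", 4))


@pytest.fixture(scope="session")
def star6():
    """Star on 6 vertices; vertex 0 is the center."""
    return generate(GraphSpec("star", 6))


@pytest.fixture(scope="session")
def cycle6():
    return generate(GraphSpec("cycle", 6))


@pytest.fixture(scope="session")
def barbell13():
    """Two K_6 cliques joined through one path vertex."""
    return generate(GraphSpec("barbell", 13))


def random_connected_net(n: int, seed: int, p: float | None = None):
    """Seeded G(n, p) reduced to its largest connected component."""
    if p is None:
        p = min(1.0, 2.5 / n + 0.1)
    g = nx.gnp_random_graph(n, p, seed=seed)
    while g.number_of_edges() == 0 or max(
        (len(c) for c in nx.connected_components(g)), default=0
    ) < 2:
        seed += 10_007
        g = nx.gnp_random_graph(n, p, seed=seed)
    return from_nx(g)


@pytest.fixture
def random_net_factory():
    return random_connected_net


# ----------------------------------------------------------------- oracles

def farness_bruteforce(net, A) -> float:
    """Farness from networkx all-pairs shortest paths (independent route)."""
    A = set(A)
    dist = dict(nx.all_pairs_shortest_path_length(net.graph))
    return float(
        sum(min(dist[a][v] for a in A) for v in range(net.n) if v not in A)
    )


def hitting_times_dp(net, A, tol: float = 1e-9, horizon: int = 100_000):
    """Mean hitting times by truncated path-space dynamic programming.

    Propagates the probability mass of un-absorbed walks step by step over
    plain adjacency dicts and accumulates E[T] = sum_n P[T > n]; runs until
    the surviving mass from every start is below ``tol``.
    """
    A = set(A)
    adj = {v: sorted(net.graph.neighbors(v)) for v in range(net.n)}
    t = np.zeros(net.n)
    for start in range(net.n):
        if start in A:
            continue
        mass = {start: 1.0}
        expected = 0.0
        for _ in range(horizon):
            survival = sum(mass.values())
            if survival < tol:
                break
            expected += survival
            nxt: dict[int, float] = {}
            for v, pv in mass.items():
                share = pv / len(adj[v])
                for w in adj[v]:
                    if w not in A:
                        nxt[w] = nxt.get(w, 0.0) + share
            mass = nxt
        t[start] = expected
    return t


def random_proper_subset(n: int, rng: np.random.Generator) -> tuple:
    k = int(rng.integers(1, max(2, n)))
    return tuple(sorted(rng.choice(n, size=min(k, n - 1), replace=False)))


def exhaustive_min_F(net, k):
    """Brute-force optimum of F by direct enumeration (test-side oracle)."""
    from firsthit import objective_F

    best = None
    for S in itertools.combinations(range(net.n), k):
        F = objective_F(net, S)
        if best is None or F < best[1] - 1e-12:
            best = (S, F)
    return best
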