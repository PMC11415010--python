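"""Synthetic test networks: closed-form toy graphs and heavy-tailed families.

The deterministic families (path, cycle, star, complete, barbell) have
known hitting-time formulas and serve as analytic oracles; the random
families (preferential attachment, power-law configuration model)
emulate the heavy-tailed degree regimes — large max-degree over
mean-degree ratio — where hub heuristics are expected to shine.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import Network, from_nx
from .hitting_exact import HittingProfile

__all__ = ["GraphSpec", "generate", "closed_form_hitting"]

_FAMILIES = (
    "path",
    "cycle",
    "star",
    "complete",
    "barbell",
    "preferential_attachment",
    "configuration_powerlaw",
)


@dataclass(frozen=True)
class GraphSpec:
    """Recipe for a synthetic network.

    ``n`` is the requested vertex count (random families may lose a few
    vertices to simplification and largest-component extraction).
    ``m`` is the attachment count for preferential attachment; ``gamma``
    the power-law exponent for the configuration model.
    """

    family: str
    n: int
    m: int = 2
    gamma: float = 2.3
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.family == "preferential_attachment" and not 1 <= self.m < self.n:
            raise ValueError("need 1 <= m < n")
        if self.family == "configuration_powerlaw" and self.gamma <= 1:
            raise ValueError("gamma must be > 1")


def _powerlaw_degrees(n: int, gamma: float, rng: np.random.Generator) -> list[int]:
    # discrete power-law degrees in [2, n-1] via inverse-CDF sampling;
    # min degree 2 keeps the giant component close to size n
    u = rng.random(n)
    lo, hi = 2.0, float(n - 1)
    a = 1.0 - gamma
    deg = ((hi**a - lo**a) * u + lo**a) ** (1.0 / a)
    deg = deg.astype(int)
    if deg.sum() % 2:
        deg[int(rng.integers(n))] += 1
    return deg.tolist()


def generate(spec: GraphSpec) -> Network:
    """Generate the network described by ``spec``.

    Deterministic families are exact; random families are seeded, then
    simplified (multi-edges/self-loops dropped) and reduced to the
    largest connected component.
    """
    n, fam = spec.n, spec.family
    if fam == "path":
        g = nx.path_graph(n)
    elif fam == "cycle":
        g = nx.cycle_graph(n)
    elif fam == "star":
        g = nx.star_graph(n - 1)  # vertex 0 is the center
    elif fam == "complete":
        g = nx.complete_graph(n)
    elif fam == "barbell":
        if n < 6:
            raise ValueError("barbell needs n >= 6")
        clique = n // 2
        g = nx.barbell_graph(clique, n - 2 * clique)
    elif fam == "preferential_attachment":
        g = nx.barabasi_albert_graph(n, spec.m, seed=spec.seed)
    elif fam == "configuration_powerlaw":
        rng = np.random.default_rng(spec.seed)
        deg = _powerlaw_degrees(n, spec.gamma, rng)
        g = nx.configuration_model(deg, seed=spec.seed)
    return from_nx(g)


def closed_form_hitting(spec: GraphSpec, A) -> HittingProfile:
    """Known mean hitting times for single-vertex targets on toy families.

    path (target at an endpoint, index 0): t_i = i (2n - i - 2)
    cycle (any single target): t at hop distance d is d (n - d)
    star (target = center): every leaf hits in exactly 1 step
    complete (any single target): t = n - 1 for every other vertex

    Serves as an independent analytic oracle for the linear solver.
    """
    members = sorted(_as_members_safe(spec, A))
    n = spec.n
    if len(members) != 1:
        raise ValueError("closed forms cover single-vertex targets only")
    a = members[0]
    t = np.zeros(n)
    if spec.family == "path":
        if a != 0:
            raise ValueError("path closed form requires the endpoint target 0")
        for i in range(n):
            t[i] = i * (2 * n - i - 2)
    elif spec.family == "cycle":
        for i in range(n):
            d = min(abs(i - a), n - abs(i - a))
            t[i] = d * (n - d)
    elif spec.family == "star":
        if a != 0:
            raise ValueError("star closed form requires the center target 0")
        t[1:] = 1.0
    elif spec.family == "complete":
        t[:] = n - 1.0
        t[a] = 0.0
    else:
        raise ValueError(f"no closed form for family {spec.family!r}")
    return HittingProfile(t=t, F=float(t.sum()), t_star=float(t.max()))


def _as_members_safe(spec: GraphSpec, A):
    if hasattr(A, "members"):
        return A.members
    return frozenset(int(v) for v in A)
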