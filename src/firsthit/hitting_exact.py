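"""Exact absorbing-chain computations for hitting times and consensus.

For a target set A the walk restricted to A^c is governed by the
substochastic block P_A of the transition matrix.  Mean hitting times
solve the linear system (I - P_A) t = 1, the objective F(A) is the sum
of t over all start vertices, and the leader-driven consensus process
x_{n+1} = P_A x_n + c R_A 1 converges to c·1 at a rate controlled by the
tail of the hitting-time distribution:

    ||x* - x_n||_1 = sum_{i in A^c} P_i[T_A > n].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_core import Network, VertexSet, _as_members, farness, transition_matrix

__all__ = [
    "HittingProfile",
    "ConsensusState",
    "absorbing_blocks",
    "mean_hitting_times",
    "objective_F",
    "consensus_trajectory",
    "tail_probability",
    "exponential_bound_check",
    "profile_table",
    "profile_summary",
]

# below this complement size a dense solve beats sparse LU setup
_DENSE_CUTOFF = 500


@dataclass(frozen=True)
class HittingProfile:
    """Per-vertex expected hitting times to a target set A.

    ``t[i]`` is E_i[T_A] in walk steps (0 on A), ``F`` their sum over all
    vertices, ``t_star`` the worst-case start max_i E_i[T_A].
    """

    t: np.ndarray
    F: float
    t_star: float

    def __post_init__(self):
        assert np.all(self.t >= -1e-9)


@dataclass(frozen=True)
class ConsensusState:
    """Consensus iterate on A^c at step n; leader vertices hold value c."""

    x: np.ndarray
    c: float
    n: int


def absorbing_blocks(net: Network, A, lazy: bool = False):
    """Blocks (P_A, R_A) of P under the (A, A^c) ordering.

    P_A is P restricted to A^c x A^c (rows/cols in ascending dense index),
    R_A is P restricted to A^c x A.  Rows of [R_A | P_A] sum to 1.
    """
    members = _as_members(net, A)
    if len(members) >= net.n:
        raise ValueError("target set must be a proper subset of V")
    P = transition_matrix(net, lazy=lazy).P
    comp = np.array(sorted(set(range(net.n)) - members))
    targ = np.array(sorted(members))
    P_A = P[comp][:, comp]
    R_A = P[comp][:, targ]
    return sp.csr_matrix(P_A), sp.csr_matrix(R_A)


def _complement(net: Network, members) -> np.ndarray:
    return np.array(sorted(set(range(net.n)) - members))


def mean_hitting_times(net: Network, A, lazy: bool = False) -> HittingProfile:
    """Exact mean hitting times E_i[T_A] via the linear solve (I - P_A) t = 1.

    The lazy walk halves every off-diagonal transition rate, so its hitting
    times are exactly double the standard ones.
    """
    members = _as_members(net, A)
    P_A, _ = absorbing_blocks(net, members, lazy=lazy)
    nc = P_A.shape[0]
    system = sp.eye(nc, format="csc") - P_A
    rhs = np.ones(nc)
    if nc <= _DENSE_CUTOFF:
        t_comp = np.linalg.solve(system.toarray(), rhs)
    else:
        t_comp = spla.spsolve(sp.csc_matrix(system), rhs)
    t = np.zeros(net.n)
    t[_complement(net, members)] = t_comp
    return HittingProfile(t=t, F=float(t.sum()), t_star=float(t.max()))


def objective_F(net: Network, A, lazy: bool = False) -> float:
    """The influencer objective F(A) = sum_i E_i[T_A]."""
    return mean_hitting_times(net, A, lazy=lazy).F


def consensus_trajectory(net: Network, A, c: float, n_max: int) -> list[ConsensusState]:
    """Iterates of the leader-driven consensus process on A^c.

    x_0 = 0 and x_{n+1} = P_A x_n + c R_A 1; the states converge
    monotonically to the consensus vector c·1.
    """
    if c < 0:
        raise ValueError("leader value c must be >= 0")
    P_A, R_A = absorbing_blocks(net, A)
    drive = c * np.asarray(R_A.sum(axis=1)).ravel()
    x = np.zeros(P_A.shape[0])
    states = [ConsensusState(x=x.copy(), c=c, n=0)]
    for n in range(1, n_max + 1):
        x = P_A @ x + drive
        states.append(ConsensusState(x=x.copy(), c=c, n=n))
    return states


def tail_probability(net: Network, A, n: int) -> float:
    """Sum over starts i in A^c of P_i[T_A > n], i.e. ||P_A^n 1||_1.

    A sum over start vertices, so it can exceed 1; at n = 0 it equals
    |A^c|.  Identical to ||x* - x_n||_1 of the unit-leader consensus
    process.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    P_A, _ = absorbing_blocks(net, A)
    v = np.ones(P_A.shape[0])
    for _ in range(n):
        v = P_A @ v
    return float(v.sum())


def exponential_bound_check(
    net: Network, A, n: int, floor_exponent: bool = True
) -> bool:
    """Check the exponential tail bound P_mu[T_A > n] <= exp(-n / ceil(e t*)).

    mu is uniform over A^c.  With ``floor_exponent`` the exponent is the
    integer part floor(n / ceil(e t*)) (the weaker, always-safe reading);
    otherwise the raw ratio is used.
    """
    members = _as_members(net, A)
    nc = net.n - len(members)
    lhs = tail_probability(net, members, n) / nc
    t_star = mean_hitting_times(net, members).t_star
    denom = math.ceil(math.e * t_star)
    expo = math.floor(n / denom) if floor_exponent else n / denom
    return lhs <= math.exp(-expo) + 1e-12


def profile_table(net: Network, profile: HittingProfile) -> pd.DataFrame:
    """Tabular report of expected hitting times, in original vertex labels."""
    return pd.DataFrame(
        {"vertex": list(net.labels), "t": profile.t}
    )


def profile_summary(net: Network, A, profile: HittingProfile) -> str:
    """JSON summary {A, F, t_star, C} in original labels."""
    members = _as_members(net, A)
    return json.dumps(
        {
            "A": [str(l) for l in net.to_labels(sorted(members))],
            "F": profile.F,
            "t_star": profile.t_star,
            "C": farness(net, members),
        }
    )
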