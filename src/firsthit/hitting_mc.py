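"""Monte Carlo estimation of the hitting-time objective F(A).

One realization launches an independent uniform random walk from every
vertex outside the target set A and records the summed hitting time
H(omega^j, A).  The estimator

    F_M = (1/M) sum_j H(omega^j, A)

is unbiased for F(A); its spread across realizations gives the sample
standard deviation, a Student-t confidence interval, and a sample-size
rule M = ceil((s t_alpha / delta)^2) for a target half-width delta.

Walks are simulated in a vectorized batch: all M x |A^c| walks advance
in lock-step, drawing uniform neighbor choices from a single seeded
generator consumed in step-major order, so a fixed seed gives a
bit-identical estimate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats as st

from .graph_core import Network, _as_members

__all__ = [
    "WalkConfig",
    "McEstimate",
    "CensoredWalkError",
    "simulate_hitting_time",
    "estimate_F",
    "required_sample_size",
]


class CensoredWalkError(RuntimeError):
    """A walk exceeded its step cap before reaching the target set."""


@dataclass(frozen=True)
class WalkConfig:
    """Monte Carlo settings: M realizations, RNG seed, per-walk step cap.

    The default cap, 50 n^2 steps, is a crude cover-time scale: on a
    connected graph the probability of a walk lasting that long is
    astronomically small, so hitting it signals a bug rather than bad luck.
    """

    M: int
    seed: int = 0
    step_cap: int | None = None

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.step_cap is not None and self.step_cap < 1:
            raise ValueError("step_cap must be >= 1")

    def cap_for(self, net: Network) -> int:
        return self.step_cap if self.step_cap is not None else 50 * net.n**2


@dataclass(frozen=True)
class McEstimate:
    """Monte Carlo estimate of F(A) with realization bookkeeping.

    ``H`` holds the per-realization sums; ``ci`` is the level-(1-alpha)
    Student-t interval.  A non-zero ``censored_count`` poisons the
    estimate: the values are still reported but ``valid`` is False.
    """

    F_M: float
    H: np.ndarray
    s: float
    ci: tuple[float, float]
    alpha: float
    M: int
    seed: int
    censored_count: int = 0

    @property
    def valid(self) -> bool:
        return self.censored_count == 0

    def to_json(self, net: Network, A) -> str:
        members = _as_members(net, A)
        return json.dumps(
            {
                "A": [str(l) for l in net.to_labels(sorted(members))],
                "M": self.M,
                "seed": self.seed,
                "F_M": self.F_M,
                "s": self.s,
                "ci": list(self.ci),
                "censored_count": self.censored_count,
            }
        )


def _walk_arrays(net: Network):
    adj = net.adjacency_csr()
    return adj.indptr, adj.indices, net.degrees


def simulate_hitting_time(
    net: Network, A, start: int, rng: np.random.Generator, step_cap: int | None = None
) -> int:
    """Steps of one uniform random walk from ``start`` until it enters A.

    Returns 0 immediately if the start lies in A.  Raises
    :class:`CensoredWalkError` if the cap is reached first — a censored
    observation is never silently truncated.
    """
    members = _as_members(net, A)
    if not 0 <= start < net.n:
        raise ValueError(f"start {start} not a vertex index")
    if start in members:
        return 0
    indptr, indices, deg = _walk_arrays(net)
    cap = step_cap if step_cap is not None else 50 * net.n**2
    pos = start
    for step in range(1, cap + 1):
        pos = indices[indptr[pos] + int(rng.random() * deg[pos])]
        if pos in members:
            return step
    raise CensoredWalkError(f"walk from {start} not absorbed within {cap} steps")


def _batch_hitting_times(
    indptr: np.ndarray,
    indices: np.ndarray,
    deg: np.ndarray,
    starts: np.ndarray,
    in_A: np.ndarray,
    rng: np.random.Generator,
    step_cap: int,
):
    """Hitting times for a batch of independent walks, advanced in lock-step."""
    pos = starts.copy()
    steps = np.zeros(len(starts), dtype=np.int64)
    active = np.flatnonzero(~in_A[pos])
    step = 0
    while active.size and step < step_cap:
        step += 1
        cur = pos[active]
        nxt = indices[indptr[cur] + (rng.random(active.size) * deg[cur]).astype(np.int64)]
        pos[active] = nxt
        steps[active] = step
        active = active[~in_A[nxt]]
    censored = active  # still unabsorbed at the cap
    return steps, censored


def estimate_F(net: Network, A, cfg: WalkConfig, alpha: float = 0.05) -> McEstimate:
    """Monte Carlo estimate F_M of F(A) with a Student-t confidence interval.

    Each of the ``cfg.M`` realizations launches one walk from every vertex
    of A^c with independent draws; E[F_M] = F(A).  Requires M >= 2 for the
    sample standard deviation and interval.
    """
    members = _as_members(net, A)
    if len(members) >= net.n:
        raise ValueError("target set must be a proper subset of V")
    if cfg.M < 2:
        raise ValueError("M >= 2 required for a standard deviation and CI")
    indptr, indices, deg = _walk_arrays(net)
    comp = np.array(sorted(set(range(net.n)) - members))
    in_A = np.zeros(net.n, dtype=bool)
    in_A[sorted(members)] = True

    rng = np.random.default_rng(cfg.seed)
    starts = np.tile(comp, cfg.M)
    steps, censored = _batch_hitting_times(
        indptr, indices, deg, starts, in_A, rng, cfg.cap_for(net)
    )
    H = steps.reshape(cfg.M, comp.size).sum(axis=1).astype(float)
    F_M = float(H.mean())
    s = float(H.std(ddof=1))
    t_alpha = float(st.t.ppf(1 - alpha / 2, cfg.M - 1))
    half = s * t_alpha / math.sqrt(cfg.M)
    est = McEstimate(
        F_M=F_M,
        H=H,
        s=s,
        ci=(F_M - half, F_M + half),
        alpha=alpha,
        M=cfg.M,
        seed=cfg.seed,
        censored_count=int(censored.size),
    )
    if censored.size:
        warnings.warn(
            f"{censored.size} walks censored at the step cap; "
            "the F_M estimate is biased low",
            RuntimeWarning,
            stacklevel=2,
        )
    return est


def required_sample_size(s: float, t_alpha: float, delta: float) -> int:
    """Realizations needed for CI half-width delta: ceil((s t_alpha / delta)^2)."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if s < 0 or t_alpha <= 0:
        raise ValueError("s must be >= 0 and t_alpha > 0")
    if s == 0:
        return 1
    return max(1, math.ceil((s * t_alpha / delta) ** 2))
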