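"""Reproduction-number distributions at the cell level.

R is the number of target cells infected by the virions released from one
infected cell.  With a constant pool of T0 target cells (Case 1), each of
the B released virions independently infects with probability
theta = beta*T0/(c + beta*T0), and the p.m.f. of R equals the burst-size
p.m.f. with the release rate p replaced by theta*p.  When depletion of the
target pool by those same infections matters (Case 2), virions are thinned
sequentially with success probability xi_i = beta*(T0-i)/(beta*(T0-i)+c)
after i infections, and the p.m.f. of R mixes that Markov-chain kernel
over the burst-size distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .burst import (
    DEFAULT_HARD_CAP,
    DEFAULT_TAIL_TOL,
    burst_pmf,
    mean_burst,
)
from .params import ModelParams, derive
from .pmf import DiscretePMF

__all__ = [
    "DepletionChainSpec",
    "repnum_pmf_case1",
    "repnum_pmf_case2",
    "secondary_infection_kernel",
    "mean_repnum",
    "hellinger",
]


def repnum_pmf_case1(
    params: ModelParams,
    model: str,
    max_r: int | None = None,
    *,
    theta: float | None = None,
    tail_tol: float = DEFAULT_TAIL_TOL,
    hard_cap: int = DEFAULT_HARD_CAP,
) -> DiscretePMF:
    """P(R=r) with a constant target-cell pool: burst p.m.f. with p -> theta*p.

    ``theta`` defaults to beta*T0/(c + beta*T0) from the parameter set; it
    can be supplied directly when a scenario is specified by theta.
    """
    if theta is None:
        theta = derive(params).theta
    pmf = burst_pmf(
        params,
        model,
        max_r,
        p_eff=theta * params.p,
        tail_tol=tail_tol,
        hard_cap=hard_cap,
        label=f"repnum-case1-{model}",
    )
    return pmf


@dataclass
class DepletionChainSpec:
    """Sequential-thinning chain for Case 2.

    ``xi[i]`` is the probability that the next virion processed infects a
    cell given i infections so far; the chain absorbs at T0 infections.
    """

    T0: int
    xi: np.ndarray

    @classmethod
    def from_params(cls, params: ModelParams, max_states: int | None = None) -> "DepletionChainSpec":
        n = params.T0 if max_states is None else min(params.T0, max_states)
        i = np.arange(n)
        avail = params.beta * (params.T0 - i)
        with np.errstate(invalid="ignore"):
            xi = np.where(avail > 0, avail / (avail + params.c), 0.0)
        if params.c == 0:
            xi = np.where(avail > 0, 1.0, 0.0)
        return cls(params.T0, xi)

    def step(self, state: np.ndarray) -> np.ndarray:
        """One virion processed: advance the occupancy vector one step.

        ``state[r]`` is the probability of r infections so far; its length
        determines how many states are tracked (the last tracked state is
        treated as absorbing only if it is state T0).
        """
        new = state.copy()
        m = state.size - 1
        k = min(m, self.xi.size)
        new[:k] = state[:k] * (1.0 - self.xi[:k])
        new[1 : k + 1] += state[:k] * self.xi[:k]
        return new


def secondary_infection_kernel(b: int, chain: DepletionChainSpec) -> np.ndarray:
    """p_r[b]: probability of r secondary infections from b released virions.

    Recursion: p_0[0] = 1; p_0[b] = (1-xi_0)^b;
    p_r[b] = p_{r-1}[b-1] xi_{r-1} + p_r[b-1] (1-xi_r), 0 < r <= min(b, T0);
    zero above min(b, T0).  Returned vector has length min(b, T0) + 1 and
    sums to 1 up to round-off.
    """
    if b < 0:
        raise ValueError("b must be >= 0")
    m = min(b, chain.T0)
    state = np.zeros(m + 1)
    state[0] = 1.0
    for _ in range(b):
        state = chain.step(state)
    return state


def repnum_pmf_case2(
    params: ModelParams,
    model: str,
    max_r: int | None = None,
    *,
    burst: DiscretePMF | None = None,
    tail_tol: float = DEFAULT_TAIL_TOL,
    hard_cap: int = DEFAULT_HARD_CAP,
) -> DiscretePMF:
    """P(R=r) with target-cell depletion: kernel mixed over the burst p.m.f.

    The b-sum is truncated where the burst p.m.f. was; the chain occupancy
    vector is rolled forward one virion at a time so the total cost is
    O(b_max * min(b_max, T0)).
    """
    if burst is None:
        burst = burst_pmf(params, model, tail_tol=tail_tol, hard_cap=hard_cap)
    chain = DepletionChainSpec.from_params(params)
    b_max = burst.max_value
    m = min(b_max, params.T0)
    state = np.zeros(m + 1)
    state[0] = 1.0
    out = np.zeros(m + 1)
    out += burst.probs[0] * state
    for b in range(1, b_max + 1):
        state = chain.step(state)
        pb = burst.probs[b]
        if pb > 0:
            out += pb * state
    # burst tail mass is unassigned mass beyond the truncation point
    pmf = DiscretePMF(out, burst.tail_mass, f"repnum-case2-{model}")
    if max_r is not None and pmf.max_value > max_r:
        tail = float(pmf.probs[max_r + 1 :].sum()) + pmf.tail_mass
        pmf = DiscretePMF(pmf.probs[: max_r + 1], tail, pmf.label)
    return pmf


def mean_repnum(
    params: ModelParams, model: str, *, theta: float | None = None
) -> float:
    """Closed-form Case 1 mean reproduction number.

    budding:  r_E^{n_E} (1 - r_I^{n_I}) p theta / nu_I
              (limit r_E^{n_E} p tau_I theta as nu_I -> 0);
    bursting: r_E^{n_E} r_I^{n_I+1} p tau_I theta.
    """
    d = derive(params)
    if theta is None:
        theta = d.theta
    if model == "budding":
        return mean_burst(params, model, p_eff=theta * params.p)
    if model == "bursting":
        es = d.r_E**params.n_E
        return es * d.r_I ** (params.n_I + 1) * params.p * params.tau_I * theta
    raise ValueError(f"model must be 'budding' or 'bursting', got {model!r}")


def hellinger(P: DiscretePMF, Q: DiscretePMF, *, tail_limit: float = 1e-9) -> float:
    """Hellinger distance sqrt(0.5 * sum (sqrt(p_i) - sqrt(q_i))^2) in [0, 1].

    Supports are aligned by zero-padding; both truncation tails must be
    below ``tail_limit`` for the comparison to be meaningful.
    """
    if P.tail_mass > tail_limit or Q.tail_mass > tail_limit:
        raise ValueError(
            f"tail masses ({P.tail_mass:.3g}, {Q.tail_mass:.3g}) exceed "
            f"{tail_limit:.3g}; recompute with a tighter truncation"
        )
    a, b = P.aligned_with(Q)
    h2 = 0.5 * float(((np.sqrt(a) - np.sqrt(b)) ** 2).sum())
    return min(np.sqrt(h2), 1.0)
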