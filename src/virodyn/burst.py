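"""Exact burst-size distributions for budding and bursting viral release.

The burst size B is the total number of virions an infected cell releases
over its lifetime.  Conditioned on the number K of infectious stages the
cell survives, B is negative binomial: each virion release is a "success"
(probability p/(p + delta_I + nu_I) per embedded-chain step) and each stage
exit a "failure".  The unconditional p.m.f. is the K-mixture of these
negative binomials for budding, and a zero-inflated negative binomial for
bursting (immune killing destroys all intracellular virions, so only cells
that survive all stages release anything).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .params import ModelParams, derive
from .pmf import DiscretePMF, TruncationError

__all__ = [
    "StagePassagePMF",
    "stage_count_pmf",
    "nb_weight",
    "burst_pmf_budding",
    "burst_pmf_bursting",
    "mean_burst",
]

DEFAULT_TAIL_TOL = 1e-12
DEFAULT_HARD_CAP = 1_000_000


class StagePassagePMF(DiscretePMF):
    """Distribution of K, the number of infectious stages survived.

    Support is exactly {0, ..., n_I}; K = 0 means the cell was killed
    during the eclipse phase and releases nothing.
    """


def stage_count_pmf(params: ModelParams) -> StagePassagePMF:
    """P(K=k) for k in {0, ..., n_I} (closed form, sums to 1 exactly).

    P(K=0) = 1 - r_E^{n_E};
    P(K=k) = r_E^{n_E} r_I^{k-1} (1-r_I)  for 1 <= k <= n_I - 1;
    P(K=n_I) = r_E^{n_E} r_I^{n_I-1}.
    """
    d = derive(params)
    n_I = params.n_I
    es = d.r_E**params.n_E
    probs = np.empty(n_I + 1)
    probs[0] = 1.0 - es
    k = np.arange(1, n_I + 1)
    probs[1:] = es * d.r_I ** (k - 1) * (1.0 - d.r_I)
    probs[n_I] = es * d.r_I ** (n_I - 1)
    return StagePassagePMF(probs, 0.0, "stage-passage")


def nb_weight(b, k, p_eff: float, params: ModelParams):
    """The combinatorial factor f(b, k) = C(k+b-1, b) * q**b.

    Here q = p_eff/(p_eff + delta_I + nu_I) is the per-step probability
    that the next embedded-chain event is a virion release rather than a
    stage exit.  Evaluated in log space so b up to ~1e6 cannot overflow.
    """
    b = np.asarray(b)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    if np.any(np.asarray(k) < 1):
        raise ValueError("k must be >= 1")
    d = derive(params)
    denom = p_eff + d.delta_I + params.nu_I
    if p_eff == 0:
        return np.where(b == 0, 1.0, 0.0) if b.ndim else (1.0 if b == 0 else 0.0)
    log_q = np.log(p_eff) - np.log(denom)
    log_f = gammaln(k + b) - gammaln(k) - gammaln(b + 1) + b * log_q
    out = np.exp(log_f)
    return float(out) if out.ndim == 0 else out


def _nb_mixture_pmf(
    weights: np.ndarray,
    shapes: np.ndarray,
    zero_mass: float,
    p_eff: float,
    exit_rate: float,
    label: str,
    max_n: int | None,
    tail_tol: float,
    hard_cap: int,
) -> DiscretePMF:
    """Mixture sum_j weights[j] * NB(shapes[j], q) plus a point mass at 0.

    q = p_eff / (p_eff + exit_rate).  scipy's ``nbinom(n, pr)`` counts
    "failures" before the n-th "success" with success probability ``pr``;
    a stage exit is the success there, so pr = 1 - q.
    """
    if p_eff == 0 or weights.size == 0 or weights.sum() == 0:
        probs = np.zeros(1)
        probs[0] = zero_mass + weights.sum()
        return DiscretePMF(probs, 0.0, label)
    pr_exit = exit_rate / (p_eff + exit_rate)

    if max_n is None:
        # smallest support containing all but tail_tol of the mass, found by
        # growing from the widest mixture component's quantile
        k_big = int(shapes.max())
        cap = int(stats.nbinom.ppf(1.0 - tail_tol, k_big, pr_exit)) + 1
        cap = max(cap, 8)
        while True:
            cap = min(cap, hard_cap)
            b = np.arange(cap + 1)
            probs = zero_mass * (b == 0).astype(float)
            for w, k in zip(weights, shapes):
                probs += w * stats.nbinom.pmf(b, int(k), pr_exit)
            tail = max(1.0 - probs.sum(), 0.0)
            if tail <= tail_tol:
                break
            if cap >= hard_cap:
                raise TruncationError(
                    f"tail mass {tail:.3g} above tolerance {tail_tol:.3g} "
                    f"at hard cap {hard_cap}"
                )
            cap *= 2
    else:
        cap = int(max_n)
        if cap > hard_cap:
            raise TruncationError(f"requested support {cap} exceeds hard cap {hard_cap}")
        b = np.arange(cap + 1)
        probs = zero_mass * (b == 0).astype(float)
        for w, k in zip(weights, shapes):
            probs += w * stats.nbinom.pmf(b, int(k), pr_exit)
        tail = max(1.0 - probs.sum(), 0.0)
        if tail > tail_tol:
            raise TruncationError(
                f"tail mass {tail:.3g} above tolerance {tail_tol:.3g} at max {cap}"
            )
    return DiscretePMF(probs, tail, label)


def burst_pmf_budding(
    params: ModelParams,
    max_b: int | None = None,
    *,
    p_eff: float | None = None,
    tail_tol: float = DEFAULT_TAIL_TOL,
    hard_cap: int = DEFAULT_HARD_CAP,
    label: str = "burst-budding",
) -> DiscretePMF:
    """P(B=b) under continuous (budding) release.

    Mixture over K of NB(K, q) with an extra point mass at zero for death
    during eclipse; reduces to a plain negative binomial with shape n_I
    and success p/(p+delta_I) when nu_E = nu_I = 0.  ``p_eff`` overrides
    the release rate (used to turn this into the reproduction-number
    p.m.f. via p -> theta*p).
    """
    d = derive(params)
    if p_eff is None:
        p_eff = params.p
    kpmf = stage_count_pmf(params).probs
    weights = kpmf[1:]
    shapes = np.arange(1, params.n_I + 1)
    return _nb_mixture_pmf(
        weights,
        shapes,
        kpmf[0],
        p_eff,
        d.delta_I + params.nu_I,
        label,
        max_b,
        tail_tol,
        hard_cap,
    )


def burst_pmf_bursting(
    params: ModelParams,
    max_b: int | None = None,
    *,
    p_eff: float | None = None,
    tail_tol: float = DEFAULT_TAIL_TOL,
    hard_cap: int = DEFAULT_HARD_CAP,
    label: str = "burst-bursting",
) -> DiscretePMF:
    """P(B=b) under burst release: zero-inflated NB(n_I, q).

    A cell releases anything only if it survives the eclipse phase and all
    n_I infectious stages (probability r_E^{n_E} r_I^{n_I}); conditioned on
    bursting, B is NB with shape n_I and success p/(p+delta_I+nu_I).
    """
    d = derive(params)
    if p_eff is None:
        p_eff = params.p
    burst_prob = d.r_E**params.n_E * d.r_I**params.n_I
    weights = np.array([burst_prob])
    shapes = np.array([params.n_I])
    return _nb_mixture_pmf(
        weights,
        shapes,
        1.0 - burst_prob,
        p_eff,
        d.delta_I + params.nu_I,
        label,
        max_b,
        tail_tol,
        hard_cap,
    )


def burst_pmf(params: ModelParams, model: str, max_b: int | None = None, **kw) -> DiscretePMF:
    if model == "budding":
        return burst_pmf_budding(params, max_b, **kw)
    if model == "bursting":
        return burst_pmf_bursting(params, max_b, **kw)
    raise ValueError(f"model must be 'budding' or 'bursting', got {model!r}")


def mean_burst(params: ModelParams, model: str, *, p_eff: float | None = None) -> float:
    """Closed-form mean burst size.

    budding:  r_E^{n_E} (1 - r_I^{n_I}) p / nu_I, with the nu_I -> 0 limit
              r_E^{n_E} p tau_I handled as an explicit branch;
    bursting: r_E^{n_E} r_I^{n_I} p n_I / (delta_I + nu_I).
    """
    d = derive(params)
    if p_eff is None:
        p_eff = params.p
    es = d.r_E**params.n_E
    if model == "budding":
        # limit branch also taken for nu_I/delta_I below 1e-12, where the
        # exact expression differs from the limit by O(1e-12) relatively
        # but can no longer be evaluated without catastrophic cancellation
        if params.nu_I == 0 or params.nu_I < 1e-12 * d.delta_I:
            return es * p_eff * params.tau_I
        # 1 - r_I^{n_I} via expm1/log1p, stable for small nu_I/delta_I
        one_minus_rn = -np.expm1(-params.n_I * np.log1p(params.nu_I / d.delta_I))
        return es * one_minus_rn * p_eff / params.nu_I
    if model == "bursting":
        return es * d.r_I**params.n_I * p_eff * params.n_I / (d.delta_I + params.nu_I)
    raise ValueError(f"model must be 'budding' or 'bursting', got {model!r}")
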