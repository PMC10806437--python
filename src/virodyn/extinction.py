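"""Extinction probability of a viral lineage via branching processes.

With a constant target-cell pool the infected-cell lineage is a
Galton-Watson branching process whose offspring distribution is the
reproduction number R.  The probability that the lineage started by one
infected cell dies out is the smallest fixed point s* in [0, 1] of the
offspring probability generating function pi(s) = E[s^R]; with i
independent initial cells it is s*^i.

The p.g.f.s below are the closed forms of the Case 1 distributions; both
reduce to the same function when nu_I = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burst import mean_burst
from .params import ModelParams, derive
from .repnum import mean_repnum

__all__ = [
    "PGFSpec",
    "pgf_value",
    "extinction_prob_single",
    "extinction_prob_multi",
    "extinction_closed_form_n1",
    "extinction_curve",
    "FixedPointError",
]

_FP_TOL = 1e-14
_FP_MAX_ITER = 1_000_000


class FixedPointError(RuntimeError):
    """Raised when the fixed-point solver fails to converge."""


@dataclass(frozen=True)
class PGFSpec:
    """Offspring p.g.f. of R for one release model and parameter set.

    ``theta`` overrides the infection probability derived from
    (beta, c, T0) when a scenario is parameterised by theta directly.
    """

    model: str
    params: ModelParams
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("budding", "bursting"):
            raise ValueError(f"model must be 'budding' or 'bursting', got {self.model!r}")

    @property
    def theta_value(self) -> float:
        return derive(self.params).theta if self.theta is None else self.theta

    def __call__(self, s: float) -> float:
        return pgf_value(self, s)

    def mean(self) -> float:
        return mean_repnum(self.params, self.model, theta=self.theta)


def pgf_value(spec: PGFSpec, s: float) -> float:
    """Evaluate the offspring p.g.f. pi(s) for s in [0, 1].

    budding:
        pi(s) = 1 - r_E^{n_E} [ 1 - sum_{k=1}^{n_I} tau_I nu_I n_I^{k-1}/D^k
                                  - (n_I/D)^{n_I} ],
        D = n_I + tau_I nu_I + (1-s) tau_I theta p;
    bursting:
        pi(s) = 1 - r_E^{n_E} r_I^{n_I} [ 1 - ((n_I + tau_I nu_I)/D)^{n_I} ].
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0, 1], got {s}")
    p = spec.params
    d = derive(p)
    theta = spec.theta_value
    es = d.r_E**p.n_E
    D = p.n_I + p.tau_I * p.nu_I + (1.0 - s) * p.tau_I * theta * p.p
    if spec.model == "budding":
        ratio = p.n_I / D
        # geometric sum tau_I nu_I / D * sum_{k=0}^{n_I-1} (n_I/D)^k
        acc = 0.0
        term = p.tau_I * p.nu_I / D
        for _ in range(p.n_I):
            acc += term
            term *= ratio
        inner = 1.0 - acc - ratio**p.n_I
        return 1.0 - es * inner
    inner = 1.0 - ((p.n_I + p.tau_I * p.nu_I) / D) ** p.n_I
    return 1.0 - es * d.r_I**p.n_I * inner


def extinction_closed_form_n1(spec: PGFSpec) -> float:
    """Closed-form smallest fixed point for an exponential infectious period.

    For n_I = 1 the non-unit fixed points are
    s2_bud   = 1 - r_E^{n_E} (1 - 1/Rbar_bud),
    s2_burst = 1 - r_E^{n_E} r_I (1 - 1/Rbar_burst),
    and the extinction probability is min(s2, 1).
    """
    p = spec.params
    if p.n_I != 1:
        raise ValueError("closed form only valid for n_I = 1")
    d = derive(p)
    es = d.r_E**p.n_E
    rbar = spec.mean()
    if rbar <= 1.0:
        return 1.0
    if spec.model == "budding":
        return 1.0 - es * (1.0 - 1.0 / rbar)
    return 1.0 - es * d.r_I * (1.0 - 1.0 / rbar)


def extinction_prob_single(spec: PGFSpec) -> float:
    """Smallest fixed point of pi on [0, 1].

    Exactly 1 when the mean reproduction number is <= 1 (criticality is
    decided from the closed-form mean, not the solver).  Otherwise the
    fixed point is found by functional iteration s <- pi(s) from s=0,
    which converges monotonically to the smallest fixed point for p.g.f.s,
    with a bisection fallback if the iteration cap is reached.
    """
    if spec.mean() <= 1.0:
        return 1.0
    s = 0.0
    for _ in range(_FP_MAX_ITER):
        s_new = pgf_value(spec, s)
        if abs(s_new - s) < _FP_TOL:
            return s_new
        s = s_new
    # fall back to bisection on pi(s) - s, bracketing the smallest root
    lo, hi = s, 1.0 - 1e-12
    if pgf_value(spec, hi) - hi >= 0:
        raise FixedPointError(
            f"no sub-unit fixed point bracketed after {_FP_MAX_ITER} iterations "
            f"(s={s!r}, pi(s)-s={pgf_value(spec, s) - s!r})"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if pgf_value(spec, mid) - mid >= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < _FP_TOL:
            break
    return 0.5 * (lo + hi)


def extinction_prob_multi(spec: PGFSpec, i: int) -> float:
    """Extinction probability starting from i independent infected cells."""
    if i < 0 or i != int(i):
        raise ValueError(f"i must be a non-negative integer, got {i!r}")
    if i == 0:
        return 1.0
    return extinction_prob_single(spec) ** int(i)


def extinction_curve(
    params: ModelParams,
    model: str,
    *,
    theta_grid=None,
    n_I_grid=None,
    theta: float | None = None,
) -> pd.DataFrame:
    """Tabulate extinction probability over a theta sweep or an n_I sweep.

    Exactly one of ``theta_grid`` / ``n_I_grid`` must be given.  Sweeping
    n_I keeps tau_I fixed, so delta_I = n_I/tau_I is recomputed at every
    grid point; ``theta`` fixes the infection probability during an n_I
    sweep (defaults to the value derived from beta, c, T0).
    """
    if (theta_grid is None) == (n_I_grid is None):
        raise ValueError("exactly one of theta_grid or n_I_grid is required")
    rows = []
    if theta_grid is not None:
        for th in np.asarray(theta_grid, dtype=float):
            spec = PGFSpec(model, params, theta=float(th))
            rows.append(
                {
                    "theta": float(th),
                    "n_I": params.n_I,
                    "mean_repnum": spec.mean(),
                    "mean_burst": mean_burst(params, model),
                    "extinction_prob": extinction_prob_single(spec),
                }
            )
    else:
        for n in n_I_grid:
            pn = params.replace(n_I=int(n))
            spec = PGFSpec(model, pn, theta=theta)
            rows.append(
                {
                    "theta": spec.theta_value,
                    "n_I": int(n),
                    "mean_repnum": spec.mean(),
                    "mean_burst": mean_burst(pn, model),
                    "extinction_prob": extinction_prob_single(spec),
                }
            )
    return pd.DataFrame(rows)
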