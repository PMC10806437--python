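"""Model parameters for stochastic within-host viral dynamics.

A single infected cell passes through an eclipse phase (``n_E`` exponential
stages, mean ``tau_E`` absent immune killing) and an infectious phase
(``n_I`` stages, mean ``tau_I``).  During the infectious phase virions are
either released continuously at rate ``p`` (budding) or accumulated
intracellularly at rate ``p`` and released in a single burst at
virus-induced death (bursting).  The immune system removes eclipse cells at
rate ``nu_E`` and infectious cells at rate ``nu_I``.  Extracellular virions
are lost at rate ``c`` and infect target cells at rate ``beta`` per cell
per virion; ``T0`` is the initial number of target cells.

All rates are per day; durations are in days.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "ModelParams",
    "DerivedRates",
    "ParameterError",
    "derive",
    "load_params",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates the model's constraints."""


@dataclass(frozen=True)
class ModelParams:
    """A complete parameter set for the budding/bursting cell-level models.

    ``tau_E``/``n_E`` describe the eclipse phase; they only influence any
    implemented distribution through the eclipse survival probability
    ``r_E**n_E``, so ``tau_E`` may be omitted (``None``) whenever
    ``nu_E == 0`` (it is then inert).
    """

    p: float
    tau_I: float
    n_I: int
    beta: float
    c: float
    T0: int
    nu_I: float = 0.0
    nu_E: float = 0.0
    tau_E: float | None = None
    n_E: int = 1

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ParameterError(f"p must be >= 0, got {self.p}")
        if self.tau_I <= 0:
            raise ParameterError(f"tau_I must be > 0, got {self.tau_I}")
        for name in ("n_I", "n_E"):
            val = getattr(self, name)
            if not isinstance(val, (int,)) or val < 1:
                raise ParameterError(f"{name} must be an integer >= 1, got {val!r}")
        for name in ("nu_I", "nu_E", "beta", "c"):
            val = getattr(self, name)
            if val < 0:
                raise ParameterError(f"{name} must be >= 0, got {val}")
        if self.nu_E > 0 and (self.tau_E is None or self.tau_E <= 0):
            raise ParameterError(
                "tau_E must be a positive duration when nu_E > 0; "
                f"got tau_E={self.tau_E}"
            )
        if self.tau_E is not None and self.tau_E <= 0:
            raise ParameterError(f"tau_E must be > 0 when given, got {self.tau_E}")
        T0 = self.T0
        if T0 < 0 or T0 != int(T0):
            raise ParameterError(f"T0 must be a non-negative integer, got {T0!r}")
        object.__setattr__(self, "T0", int(T0))

    @property
    def eclipse_inert(self) -> bool:
        """True when the eclipse duration cannot affect any output (nu_E=0)."""
        return self.nu_E == 0

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DerivedRates:
    """Quantities derived from a :class:`ModelParams`.

    delta_E, delta_I
        Per-stage progression rates n/tau (``delta_E`` is None when tau_E
        is omitted).
    r_E, r_I
        Per-stage survival probabilities delta/(delta+nu): the chance a
        cell leaves a stage by progressing rather than by immune killing.
    theta
        Probability that a released virion infects a target cell rather
        than being cleared, beta*T0/(c + beta*T0).
    """

    delta_E: float | None
    delta_I: float
    r_E: float
    r_I: float
    theta: float


def derive(params: ModelParams) -> DerivedRates:
    """Compute per-stage rates, survival probabilities and theta.

    Handles every degenerate branch without division by zero: ``r_E = 1``
    exactly when ``nu_E = 0`` (whatever tau_E), ``theta = 0`` when
    ``beta*T0 = 0``.
    """
    delta_I = params.n_I / params.tau_I
    r_I = delta_I / (delta_I + params.nu_I)
    if params.nu_E == 0:
        delta_E = None if params.tau_E is None else params.n_E / params.tau_E
        r_E = 1.0
    else:
        delta_E = params.n_E / params.tau_E
        r_E = delta_E / (delta_E + params.nu_E)
    bt = params.beta * params.T0
    theta = 0.0 if bt == 0 else bt / (params.c + bt)
    return DerivedRates(delta_E=delta_E, delta_I=delta_I, r_E=r_E, r_I=r_I, theta=theta)


def eclipse_survival(params: ModelParams) -> float:
    """Probability r_E**n_E that an infected cell survives the eclipse phase."""
    return derive(params).r_E ** params.n_E


def theta_for(params: ModelParams) -> float:
    return derive(params).theta


def beta_for_theta(theta: float, T0: int, c: float) -> float:
    """Infection rate beta such that beta*T0/(c+beta*T0) equals ``theta``.

    Used when a scenario is specified by (theta, T0) rather than by beta.
    """
    if not 0 <= theta < 1:
        raise ParameterError(f"theta must be in [0, 1), got {theta}")
    if theta == 0:
        return 0.0
    if T0 <= 0:
        raise ParameterError("T0 must be positive to realise theta > 0")
    return c * theta / ((1.0 - theta) * T0)


_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def params_from_dict(d: dict) -> ModelParams:
    """Build a :class:`ModelParams` from a flat mapping; unknown keys rejected."""
    unknown = set(d) - _FIELDS
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = dict(d)
    for name in ("n_I", "n_E"):
        if name in kwargs and float(kwargs[name]).is_integer():
            kwargs[name] = int(kwargs[name])
    if "T0" in kwargs:
        t0 = float(kwargs["T0"])
        if t0.is_integer():
            kwargs["T0"] = int(t0)
    return ModelParams(**kwargs)


def load_params(path: str | Path) -> ModelParams:
    """Read a parameter set from a flat JSON or TOML file."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a flat table of parameters")
    return params_from_dict(data)


def params_to_dict(params: ModelParams) -> dict:
    d = dataclasses.asdict(params)
    return {k: v for k, v in d.items() if v is not None}
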