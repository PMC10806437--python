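"""Stochastic simulation oracle for the budding and bursting models.

Three levels of simulation, all sharing one master seed with per-replicate
streams derived by counter offset:

* per-cell burst-size sampling, via the embedded jump chain of the
  stage-structured lifetime (every stage exit is an exponential race
  between progression, immune killing and -- for budding -- release);
* thinning of a burst into secondary infections, binomial for a constant
  target pool (Case 1) or sequential over a depleting pool (Case 2);
* exact event-driven simulation (Gillespie direct method) of the full
  continuous-time Markov chain for the system state.

These paths deliberately avoid the closed-form mixture algebra used by the
analytic modules so they can serve as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams, derive

__all__ = [
    "SystemState",
    "SimOutcome",
    "sample_cell",
    "sample_burst_sizes",
    "thin_to_infections",
    "sample_secondary_infections",
    "run_ctmc",
    "extinction_frequency",
]


@dataclass
class SystemState:
    """Counts of virions, target cells and per-stage infected cells."""

    V: int
    T: int
    E: np.ndarray
    I: np.ndarray

    @classmethod
    def initial(cls, params: ModelParams, V: int = 0, infected: int = 1) -> "SystemState":
        """T0 target cells plus ``infected`` cells placed in eclipse stage 1."""
        E = np.zeros(params.n_E, dtype=np.int64)
        I = np.zeros(params.n_I, dtype=np.int64)
        E[0] = infected
        return cls(V=V, T=params.T0, E=E, I=I)

    @property
    def infected(self) -> int:
        return int(self.E.sum() + self.I.sum())


@dataclass
class SimOutcome:
    """Per-replicate summary record."""

    burst_size: int
    secondary_infections: int = 0
    extinct: bool = False
    final_time: float = 0.0


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# per-cell sampling
# ---------------------------------------------------------------------------


def sample_burst_sizes(
    params: ModelParams, model: str, n: int, rng_seed=0
) -> np.ndarray:
    """Vectorised burst sizes for n independent infected cells.

    Budding walks the embedded chain stage by stage: within a stage the
    number of releases before exit is geometric with release odds
    p/(delta_I+nu_I), and the exit is a kill with probability
    nu_I/(delta_I+nu_I).  Bursting draws the realised infectious lifetime
    as a sum of exponential stage times and, if every exit was a
    progression, a Poisson(p * lifetime) burst; immune killing at any
    stage yields zero.
    """
    rng = _rng(rng_seed)
    d = derive(params)
    exit_rate = d.delta_I + params.nu_I
    # eclipse survival: each of n_E stages independently won by progression
    alive = rng.random(n) < d.r_E**params.n_E
    out = np.zeros(n, dtype=np.int64)
    if model == "budding":
        pr_exit = exit_rate / (params.p + exit_rate) if params.p > 0 else 1.0
        for _ in range(params.n_I):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            if params.p > 0:
                out[idx] += rng.negative_binomial(1, pr_exit, idx.size)
            killed = rng.random(idx.size) < params.nu_I / exit_rate
            alive[idx[killed]] = False
        return out
    if model == "bursting":
        lifetime = np.zeros(n)
        for _ in range(params.n_I):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            lifetime[idx] += rng.exponential(1.0 / exit_rate, idx.size)
            killed = rng.random(idx.size) < params.nu_I / exit_rate
            alive[idx[killed]] = False
        idx = np.flatnonzero(alive)
        out[idx] = rng.poisson(params.p * lifetime[idx])
        return out
    raise ValueError(f"model must be 'budding' or 'bursting', got {model!r}")


def sample_cell(params: ModelParams, model: str, rng_seed=0) -> SimOutcome:
    """Burst size of a single infected cell (see :func:`sample_burst_sizes`)."""
    b = int(sample_burst_sizes(params, model, 1, rng_seed)[0])
    return SimOutcome(burst_size=b)


def thin_to_infections(burst: int, params: ModelParams, case: int, rng_seed=0) -> int:
    """Secondary infections caused by ``burst`` released virions.

    Case 1: binomial thinning with theta.  Case 2: virions are processed
    one at a time; the j-th infects with probability
    xi_i = beta*(T0-i)/(beta*(T0-i)+c) where i is the running infection
    count, absorbing at T0.
    """
    if burst < 0:
        raise ValueError("burst must be >= 0")
    rng = _rng(rng_seed)
    if case == 1:
        theta = derive(params).theta
        return int(rng.binomial(burst, theta))
    if case == 2:
        infections = 0
        for _ in range(burst):
            if infections >= params.T0:
                break
            avail = params.beta * (params.T0 - infections)
            xi = avail / (avail + params.c) if avail + params.c > 0 else 0.0
            if rng.random() < xi:
                infections += 1
        return infections
    raise ValueError(f"case must be 1 or 2, got {case!r}")


def sample_secondary_infections(
    params: ModelParams, model: str, n: int, case: int = 1, rng_seed=0
) -> np.ndarray:
    """n independent draws of R = thinned burst size."""
    rng = _rng(rng_seed)
    bursts = sample_burst_sizes(params, model, n, rng)
    if case == 1:
        theta = derive(params).theta
        return rng.binomial(bursts, theta)
    return np.array(
        [thin_to_infections(int(b), params, 2, rng) for b in bursts], dtype=np.int64
    )


# ---------------------------------------------------------------------------
# full event-driven CTMC
# ---------------------------------------------------------------------------


def run_ctmc(
    params: ModelParams,
    model: str,
    initial: SystemState,
    t_max: float,
    *,
    stop_on_extinction: bool = True,
    rng_seed=0,
    record: bool = False,
    establishment_threshold: int | None = None,
):
    """Exact stochastic simulation of the system-level Markov chain.

    Events (budding): infection beta*T*V; eclipse progression delta_E*E_i;
    eclipse killing nu_E*E_i; infectious progression delta_I*I_i; immune
    killing nu_I*I_i; death at the last stage (delta_I+nu_I)*I_{n_I};
    budding release p*sum(I); virion loss c*V.  In the bursting model each
    infectious cell is an agent carrying its infectious-phase entry time;
    at a virus-induced exit from stage n_I it releases a
    Poisson(p * realised infectious lifetime) burst in a single state
    jump, and immune killing releases nothing.

    Returns ``(trajectory, outcome)``; the trajectory DataFrame is empty
    unless ``record`` is set.  ``establishment_threshold`` stops the run
    (as non-extinct) once cumulative cell infections reach that count,
    which keeps supercritical lineages desk-scale.
    """
    if t_max <= 0:
        raise ValueError(f"t_max must be > 0, got {t_max}")
    if model not in ("budding", "bursting"):
        raise ValueError(f"model must be 'budding' or 'bursting', got {model!r}")
    rng = _rng(rng_seed)
    d = derive(params)
    delta_E = d.delta_E
    if params.n_E > 0 and delta_E is None:
        # inert eclipse (nu_E = 0, tau_E omitted): use a unit-mean stage so
        # the embedded probabilities are unaffected (r_E = 1 regardless)
        delta_E = float(params.n_E)
    delta_I = d.delta_I

    V, T = int(initial.V), int(initial.T)
    E = initial.E.astype(np.int64).copy()
    I = initial.I.astype(np.int64).copy()
    bursting = model == "bursting"
    # bursting agents: infectious-phase entry time per cell, per stage
    agents: list[list[float]] = [[] for _ in range(params.n_I)] if bursting else []
    if bursting and I.sum():
        for i, cnt in enumerate(I):
            agents[i] = [0.0] * int(cnt)

    t = 0.0
    released = 0
    infections = 0
    rows = []
    if record:
        rows.append(_snapshot(t, V, T, E, I))

    while True:
        infected = int(E.sum() + I.sum())
        if stop_on_extinction and V == 0 and infected == 0:
            return _finish(rows, t, released, infections, True)
        if establishment_threshold is not None and infections >= establishment_threshold:
            return _finish(rows, t, released, infections, False)

        rate_inf = params.beta * T * V
        rate_E_prog = delta_E * E if params.n_E else np.zeros(0)
        rate_E_kill = params.nu_E * E
        rate_I_prog = delta_I * I
        rate_I_kill = params.nu_I * I
        rate_release = 0.0 if bursting else params.p * I.sum()
        rate_loss = params.c * V
        total = (
            rate_inf
            + rate_E_prog.sum()
            + rate_E_kill.sum()
            + rate_I_prog.sum()
            + rate_I_kill.sum()
            + rate_release
            + rate_loss
        )
        if total == 0:
            extinct = V == 0 and infected == 0
            return _finish(rows, t, released, infections, extinct)
        t += rng.exponential(1.0 / total)
        if t > t_max:
            extinct = V == 0 and infected == 0
            return _finish(rows, min(t, t_max), released, infections, extinct)

        u = rng.random() * total
        if u < rate_inf:
            V -= 1
            T -= 1
            E[0] += 1
            infections += 1
        else:
            u -= rate_inf
            if u < rate_E_prog.sum():
                i = _pick(u, rate_E_prog)
                E[i] -= 1
                if i + 1 < params.n_E:
                    E[i + 1] += 1
                else:
                    I[0] += 1
                    if bursting:
                        agents[0].append(t)
            else:
                u -= rate_E_prog.sum()
                if u < rate_E_kill.sum():
                    E[_pick(u, rate_E_kill)] -= 1
                else:
                    u -= rate_E_kill.sum()
                    if u < rate_I_prog.sum():
                        i = _pick(u, rate_I_prog)
                        I[i] -= 1
                        if bursting:
                            j = rng.integers(len(agents[i]))
                            entry = agents[i].pop(j)
                        if i + 1 < params.n_I:
                            I[i + 1] += 1
                            if bursting:
                                agents[i + 1].append(entry)
                        else:
                            # virus-induced death at the last stage
                            if bursting:
                                n_rel = int(rng.poisson(params.p * (t - entry)))
                                V += n_rel
                                released += n_rel
                    else:
                        u -= rate_I_prog.sum()
                        if u < rate_I_kill.sum():
                            i = _pick(u, rate_I_kill)
                            I[i] -= 1
                            if bursting:
                                agents[i].pop(rng.integers(len(agents[i])))
                        else:
                            u -= rate_I_kill.sum()
                            if u < rate_release:
                                V += 1
                                released += 1
                            else:
                                V -= 1
        if record:
            rows.append(_snapshot(t, V, T, E, I))


def _pick(u: float, rates: np.ndarray) -> int:
    return int(np.searchsorted(np.cumsum(rates), u, side="right"))


def _snapshot(t, V, T, E, I):
    row = {"time": t, "V": V, "T": T}
    row.update({f"E{i+1}": int(v) for i, v in enumerate(E)})
    row.update({f"I{i+1}": int(v) for i, v in enumerate(I)})
    return row


def _finish(rows, t, released, infections, extinct):
    traj = pd.DataFrame(rows)
    return traj, SimOutcome(
        burst_size=released,
        secondary_infections=infections,
        extinct=extinct,
        final_time=t,
    )


def extinction_frequency(
    params: ModelParams,
    model: str,
    n_lineages: int,
    *,
    t_max: float = 1000.0,
    establishment_threshold: int = 150,
    rng_seed=0,
) -> float:
    """Fraction of single-cell lineages that go extinct in the full CTMC.

    Each lineage starts from one cell in eclipse stage 1 and runs until
    extinction, t_max, or ``establishment_threshold`` cumulative
    infections (counted as survival).
    """
    master = np.random.default_rng(rng_seed)
    seeds = master.integers(0, 2**31, size=n_lineages)
    extinct = 0
    for s in seeds:
        _, out = run_ctmc(
            params,
            model,
            SystemState.initial(params),
            t_max,
            rng_seed=int(s),
            establishment_threshold=establishment_threshold,
        )
        extinct += out.extinct
    return extinct / n_lineages
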