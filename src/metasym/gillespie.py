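"""Exact event-driven stochastic simulation (Gillespie's direct method).

Each step draws an exponential waiting time from the total event rate and a
categorical event identity proportional to the per-channel rates, so the
simulation is statistically exact for the continuous-time Markov chain whose
mean-field limit is the corresponding ODE model.

Event channels, per patch:

* horizontal infection — S -> I_A, S -> I_B, and the secondary infections
  I_A -> X, I_B -> X (rates follow the frequency-dependent forces of
  infection, including the ``q`` and ``psi`` modifiers);
* birth — total rate ``nu_b * N``; the mother's class is drawn proportional
  to class counts and the offspring class by the vertical-transmission split
  (phi; (1-phi) c_A; (1-phi) c_B; (1-phi)(1-c_A-c_B)) at event time;
* death — per-class rate ``nu_d * count``;
* migration — per-class rate ``m * count``, destination drawn from the
  routing matrix column of the source patch.

Counts remain non-negative integers throughout; with a zero total rate the
system is absorbing and the simulation ends early.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams
from .simulate import MODEL_TAGS, Trajectory
from .state import MetacommunityState

__all__ = ["event_rates", "gillespie_simulate"]


def event_rates(model_tag: str, params: ModelParams, y: np.ndarray) -> np.ndarray:
    """Per-channel event rates for state ``y`` of shape (J, 4).

    Channel layout per patch i (column-major over patches):
    0: S->I_A, 1: S->I_B, 2: I_A->X, 3: I_B->X, 4: birth, 5..8: deaths of
    (S, I_A, I_B, X), 9..12: emigrations of (S, I_A, I_B, X).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    J = y.shape[0]
    s = params.symbiont
    d = params.demography
    mig = params.migration

    S, I_A, I_B, X = y[:, 0], y[:, 1], y[:, 2], y[:, 3]
    N = y.sum(axis=1)
    safe = np.where(N > 0, N, 1.0)
    foi_A = np.where(N > 0, s.beta_A * (I_A + s.q * X) / safe, 0.0)
    foi_B = np.where(N > 0, s.beta_B * (I_B + s.q * X) / safe, 0.0)

    rates = np.zeros((J, 13))
    rates[:, 0] = foi_A * S
    rates[:, 1] = foi_B * S
    rates[:, 2] = s.psi * foi_B * I_A
    rates[:, 3] = s.psi * foi_A * I_B
    if model_tag == "full_metacommunity":
        rates[:, 4] = d.nu_b * N
        rates[:, 5:9] = d.nu_d * y
        if J > 1:
            rates[:, 9:13] = mig.m * y
    return rates


# state deltas for the four infection channels, indexed by channel id
_INFECTION_DELTA = {
    0: (0, 1),  # S -> I_A
    1: (0, 2),  # S -> I_B
    2: (1, 3),  # I_A -> X
    3: (2, 3),  # I_B -> X
}


def gillespie_simulate(
    model_tag: str,
    params: ModelParams,
    init: MetacommunityState | np.ndarray,
    t_max: float,
    seed: int | np.random.SeedSequence,
    record_events: bool = True,
) -> Trajectory:
    """Simulate the requested model exactly with Gillespie's direct method.

    Parameters
    ----------
    init : integer counts, shape (J, 4)
        Initial host counts; non-integer values are rejected.
    t_max : float
        Simulation horizon in days (> 0).
    seed : int or numpy SeedSequence
        Reproducibility seed; identical inputs and seed give an identical
        event sequence.
    record_events : bool
        If True the returned trajectory holds the state after every event
        (plus t=0 and t=t_max); otherwise only the initial and final states.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model_tag {model_tag!r}; choose from {MODEL_TAGS}")
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    y0 = init.to_array() if isinstance(init, MetacommunityState) else np.atleast_2d(
        np.asarray(init, dtype=float))
    if np.any(y0 != np.round(y0)) or np.any(y0 < 0):
        raise ValueError("initial state must hold non-negative integer counts")
    y = y0.astype(np.int64).copy()
    J = y.shape[0]

    rng = np.random.default_rng(seed)
    d = params.demography
    rho = np.asarray(params.migration.rho, dtype=float)

    t = 0.0
    times = [0.0]
    states = [y.copy()]

    while True:
        rates = event_rates(model_tag, params, y)
        total = rates.sum()
        if total <= 0:
            break  # absorbing state: nothing can happen any more
        t += rng.exponential(1.0 / total)
        if t >= t_max:
            break
        # categorical event draw over the flattened (patch, channel) grid
        flat = rates.ravel()
        k = int(np.searchsorted(np.cumsum(flat), rng.random() * total, side="right"))
        k = min(k, flat.size - 1)
        patch, chan = divmod(k, rates.shape[1])

        if chan in _INFECTION_DELTA:
            src, dst = _INFECTION_DELTA[chan]
            y[patch, src] -= 1
            y[patch, dst] += 1
        elif chan == 4:  # birth: mother class then vertical split
            mother = _categorical(rng, y[patch] / y[patch].sum())
            if mother == 0:
                child = 0
            else:
                u = rng.random()
                if u < d.phi:
                    child = 0
                elif mother in (1, 2):
                    child = mother
                else:  # coinfected mother transmitting
                    v = rng.random()
                    if v < d.c_A:
                        child = 1
                    elif v < d.c_A + d.c_B:
                        child = 2
                    else:
                        child = 3
            y[patch, child] += 1
        elif 5 <= chan <= 8:  # death
            y[patch, chan - 5] -= 1
        else:  # migration of class (chan - 9) out of `patch`
            cls = chan - 9
            dest = _categorical(rng, rho[:, patch])
            y[patch, cls] -= 1
            y[dest, cls] += 1

        if record_events:
            times.append(t)
            states.append(y.copy())

    times.append(t_max)
    states.append(y.copy())
    return Trajectory(np.array(times), np.stack(states).astype(float), model_tag,
                      stochastic=True)


def _categorical(rng: np.random.Generator, p: np.ndarray) -> int:
    c = np.cumsum(p)
    return int(np.searchsorted(c, rng.random() * c[-1], side="right").clip(0, p.size - 1))
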