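"""Deterministic simulation of the transmission models.

:func:`integrate` wraps an adaptive explicit Runge-Kutta solver
(``scipy.integrate.solve_ivp``, RK45, rtol 1e-8 / atol 1e-10) for all three
model variants and returns a :class:`Trajectory`.  Tiny negative excursions
from the solver are clipped to zero; anything below ``-1e-6`` is treated as
an integration fault.

For the SI model the solution is logistic and available in closed form
(:func:`logistic_solution`), which serves as an exact oracle for the solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import _experiment_rhs_flat, _metacommunity_rhs_arr
from .params import ModelParams
from .state import CLASSES, MetacommunityState

__all__ = [
    "MODEL_TAGS",
    "Trajectory",
    "IntegrationError",
    "logistic_solution",
    "integrate",
]

MODEL_TAGS = ("si_single", "experiment_two_symbiont", "full_metacommunity")

_NEG_TOL = 1e-6  # below this, a negative class is an integration fault


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last successfully reached state."""

    def __init__(self, message: str, last_time: float, last_state: np.ndarray):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed model states.

    ``states`` has shape ``(T, J, 4)`` in class order ``(S, I_A, I_B, X)``;
    the SI model is stored with the infected class in the I_A slot.
    """

    times: np.ndarray
    states: np.ndarray
    model_tag: str
    stochastic: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if times.ndim != 1 or np.any(np.diff(times) < 0):
            raise ValueError("times must be a non-decreasing 1-d sequence")
        if not self.stochastic and np.any(np.diff(times) <= 0):
            raise ValueError("deterministic trajectories need strictly increasing times")
        if states.shape[0] != times.size or states.ndim != 3 or states.shape[2] != 4:
            raise ValueError("states must have shape (len(times), J, 4)")

    @property
    def J(self) -> int:
        return self.states.shape[1]

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """State at time(s) t: linear interpolation for ODE trajectories,
        piecewise-constant (last event) for stochastic ones."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("requested time outside trajectory span")
        if self.stochastic:
            idx = np.searchsorted(self.times, t, side="right") - 1
            return self.states[idx]
        flat = self.states.reshape(self.times.size, -1)
        out = np.stack([np.interp(t, self.times, flat[:, j]) for j in range(flat.shape[1])], axis=-1)
        return out.reshape(t.shape + self.states.shape[1:])

    def fractions(self, classes: Sequence[str] = CLASSES) -> np.ndarray:
        """Per-time, per-patch class fractions (T, J, len(classes))."""
        N = self.states.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(N > 0, self.states / np.where(N > 0, N, 1.0), 0.0)
        idx = [CLASSES.index(c) for c in classes]
        return frac[:, :, idx]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame: time, patch, S, I_A, I_B, X."""
        T, J, _ = self.states.shape
        rows = {
            "time": np.repeat(self.times, J),
            "patch": np.tile(np.arange(J), T),
        }
        for k, c in enumerate(CLASSES):
            rows[c] = self.states[:, :, k].ravel()
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def logistic_solution(
    t: float | np.ndarray, beta: float, N: float, I0: float
) -> float | np.ndarray:
    """Closed-form SI solution ``I(t) = N I0 e^{beta t} / (N + I0 (e^{beta t} - 1))``."""
    t = np.asarray(t, dtype=float)
    # computed on the log scale to stay finite for large beta*t
    with np.errstate(over="ignore"):
        e = np.exp(beta * t)
        out = np.where(
            np.isfinite(e),
            N * I0 * e / (N + I0 * (e - 1.0)),
            N if I0 > 0 else 0.0,
        )
    return out if out.ndim else float(out)


def _si_infected(beta: float, N: float, I0: float, times: np.ndarray,
                 rtol: float, atol: float) -> np.ndarray:
    """Solve the scalar SI ODE at the requested times."""
    sol = solve_ivp(
        lambda _t, y: beta * y * (N - y) / N,
        (times[0], times[-1]),
        [I0],
        t_eval=times,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if sol.t.size else times[0],
                               sol.y[:, -1] if sol.y.size else np.array([I0]))
    return sol.y[0]


def integrate(
    model_tag: str,
    params: ModelParams,
    init: MetacommunityState | np.ndarray,
    times: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the requested model variant and sample it at ``times``.

    Parameters
    ----------
    model_tag : {"si_single", "experiment_two_symbiont", "full_metacommunity"}
        Which right-hand side to integrate.  ``si_single`` reads the infected
        count from the I_A slot of a single patch and holds S = N - I.
    params : ModelParams
        Only the relevant process blocks are consulted (e.g. the SI model
        uses ``params.symbiont.beta_A`` as its beta).
    init : MetacommunityState or (J, 4) array
        Initial class densities.
    times : increasing sequence of days
        Output grid; ``times[0]`` is the initial time.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-d sequence")
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model_tag {model_tag!r}; choose from {MODEL_TAGS}")

    y0 = init.to_array() if isinstance(init, MetacommunityState) else np.atleast_2d(
        np.asarray(init, dtype=float))
    J = y0.shape[0]

    if model_tag == "si_single":
        if J != 1:
            raise ValueError("the SI model is a single-patch model")
        N = y0.sum()
        I0 = y0[0, 1] + y0[0, 2] + y0[0, 3]
        if times.size == 1:
            infected = np.array([I0])
        else:
            infected = _si_infected(params.symbiont.beta_A, N, I0, times, rtol, atol)
        infected = np.clip(infected, 0.0, N)
        states = np.zeros((times.size, 1, 4))
        states[:, 0, 0] = N - infected
        states[:, 0, 1] = infected
        return Trajectory(times, states, model_tag)

    if model_tag == "experiment_two_symbiont":
        sym = params.symbiont
        rhs = lambda _t, y: _experiment_rhs_flat(y, J, sym)
    else:
        if params.migration.J != J:
            raise ValueError(f"init has {J} patches, migration parameters expect "
                             f"{params.migration.J}")
        rhs = lambda _t, y: _metacommunity_rhs_arr(y.reshape(J, 4), params).ravel()

    if times.size == 1:
        return Trajectory(times, y0[None, :, :], model_tag)

    sol = solve_ivp(rhs, (times[0], times[-1]), y0.ravel(), t_eval=times,
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        last_t = float(sol.t[-1]) if sol.t.size else times[0]
        last = sol.y[:, -1].reshape(J, 4) if sol.y.size else y0
        raise IntegrationError(sol.message, last_t, last)
    states = sol.y.T.reshape(times.size, J, 4)
    neg_tol = max(_NEG_TOL, _NEG_TOL * y0.sum())  # solver-noise scale grows with N
    if states.min() < -neg_tol:
        raise IntegrationError(
            f"class went negative below tolerance ({states.min():.3e})",
            float(times[states.min(axis=(1, 2)).argmin()]),
            states[states.min(axis=(1, 2)).argmin()],
        )
    return Trajectory(times, np.clip(states, 0.0, None), model_tag)
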