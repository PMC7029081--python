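"""Right-hand sides of the three model variants.

* :func:`si_rhs` — the single-symbiont SI model ``I' = beta I (N - I) / N``
  used to estimate a transmission rate from a release experiment.
* :func:`experiment_rhs` — the closed two-symbiont coinfection system (no
  demography, no migration), the model of a multisymbiont lab experiment.
* :func:`metacommunity_rhs` — the full J-patch model adding host demography,
  vertical transmission and migration.

Horizontal transmission is frequency-dependent throughout: forces of
infection divide by the patch- and time-specific population size ``N_it``
(defined as 0 in an empty patch — no hosts, no contacts).
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, SymbiontParams
from .state import MetacommunityState, PatchState

__all__ = ["si_rhs", "experiment_rhs", "metacommunity_rhs"]


def si_rhs(I: float, N: float, beta: float) -> float:
    """Rate of change of the infected class in the SI model.

    ``I' = beta * I * (N - I) / N`` — frequency-dependent transmission in a
    closed population of constant size N.  Zero at both boundaries (no
    infectives, or no susceptibles left).
    """
    if N <= 0:
        raise ValueError(f"population size must be positive, got N={N}")
    if not 0 <= I <= N:
        raise ValueError(f"infected count I={I} outside [0, N={N}]")
    if beta < 0:
        raise ValueError(f"transmission rate must be >= 0, got beta={beta}")
    return beta * I * (N - I) / N


def _experiment_rhs_arr(y: np.ndarray, p: SymbiontParams) -> np.ndarray:
    """Vectorized core: y is (..., 4) in class order (S, I_A, I_B, X)."""
    S, I_A, I_B, X = y[..., 0], y[..., 1], y[..., 2], y[..., 3]
    N = S + I_A + I_B + X
    with np.errstate(divide="ignore", invalid="ignore"):
        foi_A = np.where(N > 0, p.beta_A * (I_A + p.q * X) / np.where(N > 0, N, 1.0), 0.0)
        foi_B = np.where(N > 0, p.beta_B * (I_B + p.q * X) / np.where(N > 0, N, 1.0), 0.0)
    dS = -foi_A * S - foi_B * S
    dI_A = foi_A * S - p.psi * foi_B * I_A
    dI_B = foi_B * S - p.psi * foi_A * I_B
    dX = p.psi * foi_B * I_A + p.psi * foi_A * I_B
    return np.stack([dS, dI_A, dI_B, dX], axis=-1)


def _experiment_rhs_flat(y_flat: np.ndarray, J: int, p: SymbiontParams) -> np.ndarray:
    """Allocation-lean variant of :func:`_experiment_rhs_arr` for solver loops."""
    y = y_flat.reshape(J, 4)
    S, I_A, I_B, X = y[:, 0], y[:, 1], y[:, 2], y[:, 3]
    N = S + I_A + I_B + X
    pos = N > 0
    inv = pos / np.where(pos, N, 1.0)
    a = p.beta_A * (I_A + p.q * X) * inv
    b = p.beta_B * (I_B + p.q * X) * inv
    out = np.empty_like(y)
    out[:, 0] = -(a + b) * S
    out[:, 1] = a * S - p.psi * b * I_A
    out[:, 2] = b * S - p.psi * a * I_B
    out[:, 3] = p.psi * (b * I_A + a * I_B)
    return out.ravel()


def experiment_rhs(state: PatchState, params: SymbiontParams) -> np.ndarray:
    """Derivatives (S', I_A', I_B', X') of the closed coinfection system.

    Susceptibles are infected by singly infected and (modulated by ``q``)
    coinfected hosts; singly infected hosts acquire the second symbiont at a
    susceptibility ``psi`` times the corresponding force of infection.  The
    population is closed, so the four derivatives sum to exactly zero.  An
    empty patch (N = 0) has all derivatives zero.
    """
    return _experiment_rhs_arr(state.to_array(), params)


def metacommunity_rhs(state: MetacommunityState, params: ModelParams) -> np.ndarray:
    """Per-patch, per-class derivatives (J, 4) of the full metacommunity model.

    Adds to the within-patch horizontal transmission of
    :func:`experiment_rhs`:

    * demography and vertical transmission — every class reproduces at
      ``nu_b`` and dies at ``nu_d``; offspring of infected mothers are
      symbiont-free with probability ``phi``, and a vertically transmitting
      coinfected mother produces I_A / I_B / X offspring with conditional
      probabilities ``c_A`` / ``c_B`` / ``1 - (c_A + c_B)``;
    * migration — each class emigrates at per-capita rate ``m`` and is routed
      to destination patches by ``rho[destination, source]``.  Migration only
      redistributes hosts: summed over patches its terms cancel.
    """
    y = state.to_array()
    J = y.shape[0]
    if params.migration.J != J:
        raise ValueError(
            f"state has {J} patches but migration parameters expect {params.migration.J}"
        )
    return _metacommunity_rhs_arr(y, params)


def _metacommunity_rhs_arr(y: np.ndarray, params: ModelParams) -> np.ndarray:
    d = params.demography
    mig = params.migration
    out = _experiment_rhs_arr(y, params.symbiont)

    S, I_A, I_B, X = y[:, 0], y[:, 1], y[:, 2], y[:, 3]
    infected_mothers = I_A + I_B + X
    out[:, 0] += d.nu_b * (d.phi * infected_mothers + S) - d.nu_d * S
    out[:, 1] += d.nu_b * (1 - d.phi) * (d.c_A * X + I_A) - d.nu_d * I_A
    out[:, 2] += d.nu_b * (1 - d.phi) * (d.c_B * X + I_B) - d.nu_d * I_B
    out[:, 3] += d.nu_b * (1 - d.phi) * (1 - (d.c_A + d.c_B)) * X - d.nu_d * X

    if mig.m > 0 and y.shape[0] > 1:
        emig = mig.m * y                      # (J, 4) outflow per class
        out += np.asarray(mig.rho) @ emig - emig
    elif mig.m > 0 and y.shape[0] == 1:
        pass  # a single patch has nowhere to send emigrants; rho is all-zero
    return out
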