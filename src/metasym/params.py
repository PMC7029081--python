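"""Model parameters for the symbiont metacommunity models.

Parameters are partitioned by process, mirroring the model's decomposition of
each patch's dynamics into demography + vertical transmission (D), horizontal
transmission (T), and host migration (M):

* :class:`SymbiontParams` — horizontal transmission (beta_A, beta_B, q, psi);
* :class:`DemographyParams` — births, deaths and vertical transmission
  (nu_b, nu_d, phi, c_A, c_B);
* :class:`MigrationParams` — per-capita emigration rate m and the routing
  matrix rho over the J patches.

All rates are per day.  Validation is diagnostic: :func:`validate_params`
returns machine-readable violation codes instead of raising, so a CLI or a
sampler can report every problem at once.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "SymbiontParams",
    "DemographyParams",
    "MigrationParams",
    "ModelParams",
    "Violation",
    "validate_params",
    "build_migration_matrix",
]

#: tolerance for the row-stochasticity check on the routing matrix
_RHO_TOL = 1e-12


@dataclass(frozen=True)
class SymbiontParams:
    """Horizontal-transmission parameters of the two symbionts.

    Attributes
    ----------
    beta_A, beta_B : float
        Frequency-dependent transmission rates (day^-1) of symbionts A and B.
    q : float
        Transmissibility modifier of coinfected hosts: the infectious pool for
        symbiont A is ``I_A + q * X``.  ``q = 1`` means a coinfected host
        transmits each of its symbionts exactly like a singly infected host.
    psi : float
        Susceptibility of singly infected hosts to a secondary infection;
        multiplies the whole secondary-infection term.
    """

    beta_A: float = 0.5
    beta_B: float = 0.5
    q: float = 1.0
    psi: float = 1.0


@dataclass(frozen=True)
class DemographyParams:
    """Birth/death rates and the vertical-transmission split.

    ``phi`` is the probability that a birth from an *infected* mother is fully
    symbiont-free; ``1 - phi`` is the probability of vertical transmission.
    For a coinfected mother that does transmit, ``c_A`` / ``c_B`` are the
    conditional probabilities of producing offspring singly infected with A
    or B, and ``1 - (c_A + c_B)`` the probability of coinfected offspring.
    Infection is assumed not to alter ``nu_b`` or ``nu_d``.
    """

    nu_b: float = 0.0
    nu_d: float = 0.0
    phi: float = 1.0
    c_A: float = 0.0
    c_B: float = 0.0


@dataclass(frozen=True)
class MigrationParams:
    """Per-capita emigration rate and the patch-routing matrix.

    ``rho[i, l]`` is the probability that an emigrant leaving patch ``l``
    arrives in patch ``i`` (destination-row, source-column convention).  Every
    emigrant must land somewhere, so each source column sums to 1 over the
    other patches and the diagonal is zero.
    """

    m: float = 0.0
    rho: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))
    J: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the metacommunity model, grouped by process."""

    symbiont: SymbiontParams = field(default_factory=SymbiontParams)
    demography: DemographyParams = field(default_factory=DemographyParams)
    migration: MigrationParams = field(default_factory=MigrationParams)

    def to_dict(self) -> dict[str, Any]:
        """Flat ``group.name`` key-value mapping (rho as nested lists)."""
        out: dict[str, Any] = {}
        for group in ("symbiont", "demography", "migration"):
            obj = getattr(self, group)
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, np.ndarray):
                    v = v.tolist()
                out[f"{group}.{f.name}"] = v
        return out

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        types = {"symbiont": SymbiontParams, "demography": DemographyParams,
                 "migration": MigrationParams}
        groups: dict[str, dict[str, Any]] = {g: {} for g in types}
        for key, v in d.items():
            group, _, name = key.partition(".")
            if group not in groups or name not in {f.name for f in dataclasses.fields(types[group])}:
                raise KeyError(f"unknown parameter key: {key!r}")
            groups[group][name] = v
        return cls(
            symbiont=SymbiontParams(**groups["symbiont"]),
            demography=DemographyParams(**groups["demography"]),
            migration=MigrationParams(**groups["migration"]),
        )


@dataclass(frozen=True)
class Violation:
    """One violated parameter invariant."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


def validate_params(params: ModelParams) -> list[Violation]:
    """Check every parameter invariant; return all violations (empty if valid)."""
    v: list[Violation] = []
    s, d, mig = params.symbiont, params.demography, params.migration

    for name in ("beta_A", "beta_B", "q", "psi"):
        if getattr(s, name) < 0:
            v.append(Violation(f"negative_{name}", f"{name} must be >= 0"))
    for name in ("nu_b", "nu_d", "c_A", "c_B"):
        if getattr(d, name) < 0:
            v.append(Violation(f"negative_{name}", f"{name} must be >= 0"))
    if not 0.0 <= d.phi <= 1.0:
        v.append(Violation("phi_out_of_range", "phi must lie in [0, 1]"))
    if d.c_A + d.c_B > 1.0:
        v.append(Violation("c_sum_exceeds_one", f"c_A+c_B = {d.c_A + d.c_B} > 1"))
    if mig.m < 0:
        v.append(Violation("negative_m", "m must be >= 0"))

    rho = np.asarray(mig.rho, dtype=float)
    if rho.shape != (mig.J, mig.J):
        v.append(Violation("rho_shape", f"rho must be {mig.J}x{mig.J}, got {rho.shape}"))
        return v
    if mig.J < 1:
        v.append(Violation("bad_patch_count", "J must be a positive integer"))
        return v
    if np.any(np.diag(rho) != 0):
        v.append(Violation("rho_diagonal", "rho must have a zero diagonal"))
    if np.any(rho < 0):
        v.append(Violation("rho_negative", "rho entries must be >= 0"))
    if mig.J > 1:
        colsums = rho.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _RHO_TOL):
            v.append(Violation(
                "rho_not_normalized",
                "each source's destination probabilities must sum to 1 "
                f"(column sums {colsums.tolist()})",
            ))
    return v


_KERNELS = {
    "exponential": lambda d, scale: np.exp(-d / scale),
    "gaussian": lambda d, scale: np.exp(-(d / scale) ** 2),
}


def build_migration_matrix(
    distances: np.ndarray,
    kernel_scale: float,
    kernel: str = "exponential",
) -> np.ndarray:
    """Distance-kernel routing matrix.

    ``rho[i, l]`` is proportional to ``kernel(d_{i,l} / kernel_scale)`` for
    ``i != l`` and normalized so each source column sums to 1; the diagonal is
    zero (nobody "migrates" to their own patch).

    Parameters
    ----------
    distances : (J, J) array
        Symmetric pairwise distances with a zero diagonal.
    kernel_scale : float
        Length scale of the dispersal kernel (> 0).
    kernel : {"exponential", "gaussian"}
        Kernel family; exponential decay ``exp(-d / scale)`` is the default.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distances must be a square matrix")
    J = d.shape[0]
    if J < 2:
        raise ValueError("need at least 2 patches to route migration")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    if np.any(d < 0) or np.any(np.diag(d) != 0) or not np.allclose(d, d.T):
        raise ValueError("distances must be symmetric, non-negative, zero-diagonal")
    if kernel_scale <= 0:
        raise ValueError("kernel_scale must be > 0")
    try:
        kfun = _KERNELS[kernel]
    except KeyError:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(_KERNELS)}") from None

    w = kfun(d, kernel_scale)
    np.fill_diagonal(w, 0.0)
    rho = w / w.sum(axis=0, keepdims=True)
    return rho
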