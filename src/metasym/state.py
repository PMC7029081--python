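"""Host-population state containers.

A patch holds four host classes: susceptible (S), singly infected with
symbiont A or B (I_A, I_B), and coinfected (X).  States are continuous
densities for ODE work; the stochastic simulator enforces integer counts.

Internally all numerics run on a ``(J, 4)`` array in the fixed class order
``(S, I_A, I_B, X)``; the dataclasses here are the user-facing view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CLASSES", "PatchState", "MetacommunityState"]

#: canonical class order used by every array-valued routine
CLASSES = ("S", "I_A", "I_B", "X")


@dataclass(frozen=True)
class PatchState:
    """Host counts (or densities) of one patch."""

    S: float
    I_A: float = 0.0
    I_B: float = 0.0
    X: float = 0.0

    def __post_init__(self) -> None:
        if min(self.S, self.I_A, self.I_B, self.X) < 0:
            raise ValueError("host classes must be non-negative")

    @property
    def N(self) -> float:
        """Total patch population."""
        return self.S + self.I_A + self.I_B + self.X

    def to_array(self) -> np.ndarray:
        return np.array([self.S, self.I_A, self.I_B, self.X], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray) -> "PatchState":
        return cls(*np.asarray(a, dtype=float))


@dataclass(frozen=True)
class MetacommunityState:
    """States of all J patches at one time point."""

    patches: tuple[PatchState, ...]
    t: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "patches", tuple(self.patches))
        if self.t < 0:
            raise ValueError("time must be non-negative")

    @property
    def J(self) -> int:
        return len(self.patches)

    def to_array(self) -> np.ndarray:
        """(J, 4) array in class order (S, I_A, I_B, X)."""
        return np.stack([p.to_array() for p in self.patches])

    @classmethod
    def from_array(cls, a: np.ndarray, t: float = 0.0) -> "MetacommunityState":
        a = np.atleast_2d(np.asarray(a, dtype=float))
        return cls(tuple(PatchState.from_array(row) for row in a), t=t)
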