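"""Binomial observation of simulated prevalence, and the two experiment protocols.

A release experiment is emulated by solving the model deterministically and
then assaying ``n_assayed`` hosts at each sampling time.  Observed class
counts are drawn multinomially over the host classes with probabilities equal
to the model's class fractions, so each class count is marginally
``Binomial(n_assayed, fraction)`` and the counts can never exceed the number
of hosts assayed.

Two canned protocols are provided:

* :func:`generate_single_release_dataset` — one infected host released into
  49 susceptibles (N = 50), replicated across three populations, sampled
  every 2 days; the default transmission rate is 0.50 day^-1.
* :func:`generate_coinfection_dataset` — four populations of 100 hosts
  started from four different (S0, I_A0, I_B0, X0) mixtures of singly and
  coinfected hosts, observed on all three infected classes.  Varying the
  initial conditions is what gives the data power to identify all four
  transmission parameters.

Replicate k draws from its own RNG substream keyed by (seed, k), so its data
do not depend on how many replicates are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .params import ModelParams, SymbiontParams
from .simulate import Trajectory, integrate
from .state import CLASSES

__all__ = [
    "ObservationSchedule",
    "PrevalenceSeries",
    "observe",
    "generate_single_release_dataset",
    "generate_coinfection_dataset",
    "COINFECTION_INITIAL_CONDITIONS",
]

#: the four (S0, I_A0, I_B0, X0) mixtures of the coinfection experiment design
COINFECTION_INITIAL_CONDITIONS = (
    (90, 0, 0, 10),
    (90, 5, 5, 0),
    (88, 10, 0, 2),
    (88, 0, 10, 2),
)

_COLUMNS = ["replicate", "time", "class", "count", "n_assayed"]


@dataclass(frozen=True)
class ObservationSchedule:
    """When, how many, and how often hosts are assayed."""

    times: np.ndarray
    n_assayed: int
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("times must be non-negative and increasing")
        if self.n_assayed < 1 or self.n_replicates < 1:
            raise ValueError("n_assayed and n_replicates must be >= 1")


@dataclass
class PrevalenceSeries:
    """Observed infection-class counts: the data the likelihood sees.

    ``data`` is a tidy frame with columns (replicate, time, class, count,
    n_assayed); ``metadata`` records how the data were generated (model tag,
    population size, initial conditions per replicate, seed) and is carried
    through CSV round trips.
    """

    data: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data, columns=_COLUMNS).reset_index(drop=True)
        if len(self.data):
            self.validate()

    def validate(self) -> None:
        df = self.data
        if (df["count"] < 0).any() or (df["count"] > df["n_assayed"]).any():
            bad = df.index[(df["count"] < 0) | (df["count"] > df["n_assayed"])][0]
            raise ValueError(f"record {bad}: count outside [0, n_assayed]")
        if df.duplicated(["replicate", "time", "class"]).any():
            raise ValueError("duplicate (replicate, time, class) records")
        sums = df.groupby(["replicate", "time"])[["count", "n_assayed"]].agg(
            {"count": "sum", "n_assayed": "first"})
        if (sums["count"] > sums["n_assayed"]).any():
            raise ValueError("class counts at one time exceed n_assayed")

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique().tolist())

    @property
    def classes(self) -> list[str]:
        return sorted(self.data["class"].unique().tolist())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PrevalenceSeries):
            return NotImplemented
        return self.data.equals(other.data) and self.metadata == other.metadata

    def to_csv(self, path) -> None:
        from .io import write_prevalence_csv

        write_prevalence_csv(self, path)


def observe(
    trajectory: Trajectory,
    schedule: ObservationSchedule,
    classes: Sequence[str] | None = None,
    replicate_ids: Sequence | None = None,
    substream_offset: int = 0,
) -> PrevalenceSeries:
    """Assay a simulated population at the scheduled times.

    At each sampling time the observed counts of the requested classes are a
    multinomial draw of size ``n_assayed`` over the model's class fractions
    (the remainder being assayed as susceptible).  Every replicate is an
    independent, seeded observation of the same trajectory.
    """
    if schedule.times[0] < trajectory.times[0] or schedule.times[-1] > trajectory.times[-1]:
        raise ValueError("schedule times outside trajectory span")
    if trajectory.J != 1:
        raise ValueError("observation applies to single-population trajectories")
    if classes is None:
        classes = ["infected"] if trajectory.model_tag == "si_single" else ["I_A", "I_B", "X"]

    fracs = _class_fractions(trajectory, schedule.times, classes)
    if fracs.min() < -1e-9 or fracs.sum(axis=1).max() > 1 + 1e-9:
        raise ValueError("class fractions outside [0, 1]; upstream integration fault")
    fracs = np.clip(fracs, 0.0, 1.0)

    ids = list(replicate_ids) if replicate_ids is not None else list(range(schedule.n_replicates))
    records = []
    for k, rid in enumerate(ids):
        rng = np.random.default_rng(
            np.random.SeedSequence((int(schedule.seed), int(substream_offset + k))))
        for j, t in enumerate(schedule.times):
            p = np.append(fracs[j], max(0.0, 1.0 - fracs[j].sum()))
            counts = rng.multinomial(schedule.n_assayed, p / p.sum())
            for c, cls in enumerate(classes):
                records.append((rid, float(t), cls, int(counts[c]), schedule.n_assayed))
    return PrevalenceSeries(pd.DataFrame(records, columns=_COLUMNS))


def _class_fractions(traj: Trajectory, times: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    states = traj.at(times)  # (T, 1, 4)
    N = states.sum(axis=2)
    cols = []
    for cls in classes:
        if cls == "infected":
            num = states[:, 0, 1] + states[:, 0, 2] + states[:, 0, 3]
        else:
            num = states[:, 0, CLASSES.index(cls)]
        cols.append(np.where(N[:, 0] > 0, num / np.where(N[:, 0] > 0, N[:, 0], 1.0), 0.0))
    return np.stack(cols, axis=1)


def generate_single_release_dataset(
    beta: float = 0.50,
    seed: int = 0,
    n_hosts: int = 50,
    n_infected_released: int = 1,
    n_replicates: int = 3,
    t_max: float = 20.0,
    sampling_interval: float = 2.0,
    n_assayed: int | None = None,
) -> PrevalenceSeries:
    """Synthetic single-symbiont release experiment.

    One infected host (by default) is released into ``n_hosts - 1``
    susceptibles; the epidemic follows the SI model and each of the
    ``n_replicates`` populations is assayed every ``sampling_interval`` days
    with binomial observation error.  By default every host is assayed
    (full census, ``n_assayed = n_hosts``).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    times = np.arange(0.0, t_max + 1e-9, sampling_interval)
    params = ModelParams(symbiont=SymbiontParams(beta_A=beta, beta_B=0.0))
    init = np.array([[n_hosts - n_infected_released, n_infected_released, 0, 0]], dtype=float)
    traj = integrate("si_single", params, init, times)
    schedule = ObservationSchedule(times, n_assayed or n_hosts, n_replicates, seed)
    series = observe(traj, schedule)
    series.metadata = {
        "model_tag": "si_single",
        "n_hosts": n_hosts,
        "beta_true": beta,
        "seed": seed,
        "initial_conditions": [[n_hosts - n_infected_released, n_infected_released, 0, 0]
                               for _ in range(n_replicates)],
    }
    return series


def generate_coinfection_dataset(
    params: SymbiontParams,
    seed: int = 0,
    initial_conditions: Sequence[Sequence[int]] = COINFECTION_INITIAL_CONDITIONS,
    t_max: float = 20.0,
    sampling_interval: float = 2.0,
    n_assayed: int | None = None,
) -> PrevalenceSeries:
    """Synthetic multisymbiont experiment over several initial mixtures.

    Each population evolves deterministically under the closed two-symbiont
    coinfection model from its own (S0, I_A0, I_B0, X0) vector and is assayed
    on all three infected classes with multinomial observation error.
    """
    times = np.arange(0.0, t_max + 1e-9, sampling_interval)
    model_params = ModelParams(symbiont=params)
    frames = []
    inits = [list(map(int, ic)) for ic in initial_conditions]
    for k, ic in enumerate(inits):
        n = int(sum(ic))
        traj = integrate("experiment_two_symbiont", model_params,
                         np.array([ic], dtype=float), times)
        schedule = ObservationSchedule(times, n_assayed or n, 1, seed)
        # population k keeps substream k regardless of how many populations run
        sub = observe(traj, schedule, replicate_ids=[k], substream_offset=k)
        frames.append(sub.data)
    data = pd.concat(frames, ignore_index=True)
    series = PrevalenceSeries(data)
    series.metadata = {
        "model_tag": "experiment_two_symbiont",
        "seed": seed,
        "params_true": {"beta_A": params.beta_A, "beta_B": params.beta_B,
                        "q": params.q, "psi": params.psi},
        "initial_conditions": inits,
    }
    return series
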