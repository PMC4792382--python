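"""Demographic models for the coalescent training simulations.

Five single-population histories are provided:

* ``equilibrium`` — constant size N (default 10,000).
* ``african_growth`` — the published African human model: ancestral size
  7,310, stepping to 14,474 at 148 kya, then exponential growth beginning
  ~5.1 kya to a present-day size of 424,000.
* ``european_tennessen`` — the published European human model: the same deep
  history, an out-of-Africa contraction to 1,861 at 51 kya, a second
  contraction to 1,032 at 23 kya followed by slow exponential growth to
  9,300 by ~5.1 kya, then accelerated growth to 512,000 today.
* ``bottleneck_mild`` / ``bottleneck_severe`` — three-epoch bottlenecks in
  which the population contracts to 29% (mild) or 2.9% (severe) of its
  ancestral size 0.044 x 2N generations ago and recovers 0.0084 x 2N
  generations ago.

Times are stored in generations before present (generation time 25 years for
the human models).  Epochs are ordered from the present into the past; within
an epoch the size at time t is ``size * exp(-growth_rate * (t - start))`` so
a positive growth rate means forward-in-time exponential growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import msprime
import numpy as np

__all__ = [
    "Epoch",
    "DemographicModel",
    "equilibrium",
    "african_growth",
    "european_tennessen",
    "bottleneck_mild",
    "bottleneck_severe",
    "get_model",
    "MODEL_NAMES",
]

GENERATION_TIME_YEARS = 25.0


@dataclass(frozen=True)
class Epoch:
    start_time: float  # generations before present
    size: float  # diploid size at start_time
    growth_rate: float = 0.0  # per generation, forward-time exponential


@dataclass(frozen=True)
class DemographicModel:
    """Ordered single-population size history.

    ``reference_size`` is the diploid N used to scale alpha = 2Ns, the
    standing-variant frequency bound 2/(2N) and the locus-wide theta/rho.
    """

    label: str
    epochs: tuple[Epoch, ...]
    reference_size: float

    def __post_init__(self) -> None:
        times = [e.start_time for e in self.epochs]
        if not times or times[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("epoch times must be strictly increasing into the past")
        if any(e.size <= 0 for e in self.epochs):
            raise ValueError("population sizes must be positive")

    def _epoch_at(self, t: float) -> Epoch:
        current = self.epochs[0]
        for e in self.epochs:
            if e.start_time <= t:
                current = e
            else:
                break
        return current

    def size_at(self, t: float) -> float:
        """Diploid population size t generations before present."""
        e = self._epoch_at(t)
        return e.size * math.exp(-e.growth_rate * (t - e.start_time))

    def harmonic_mean_size(self, t0: float, t1: float, n_grid: int = 256) -> float:
        """Harmonic mean of N(t) over [t0, t1] (the coalescent-relevant mean)."""
        if t1 <= t0:
            return self.size_at(t0)
        ts = np.linspace(t0, t1, n_grid)
        inv = np.array([1.0 / self.size_at(t) for t in ts])
        return float(1.0 / inv.mean())

    def to_msprime(
        self, freeze: tuple[float, float, float] | None = None
    ) -> msprime.Demography:
        """Build the msprime demography, optionally flattening an interval.

        ``freeze=(t0, t1, size)`` holds the population at a constant ``size``
        on [t0, t1], dropping any size changes scheduled inside the interval
        and resuming the true history at t1.  Used to satisfy msprime's
        restriction that the population size may not change during a sweep
        model epoch.
        """
        d = msprime.Demography()
        first = self.epochs[0]
        d.add_population(
            name="pop0", initial_size=first.size, growth_rate=first.growth_rate
        )
        if freeze is None:
            for e in self.epochs[1:]:
                d.add_population_parameters_change(
                    time=e.start_time, initial_size=e.size, growth_rate=e.growth_rate
                )
            return d
        t0, t1, frozen_size = freeze
        for e in self.epochs[1:]:
            if e.start_time < t0:
                d.add_population_parameters_change(
                    time=e.start_time, initial_size=e.size, growth_rate=e.growth_rate
                )
        d.add_population_parameters_change(
            time=t0, initial_size=frozen_size, growth_rate=0.0
        )
        resume = self._epoch_at(t1)
        d.add_population_parameters_change(
            time=t1, initial_size=self.size_at(t1), growth_rate=resume.growth_rate
        )
        for e in self.epochs[1:]:
            if e.start_time > t1:
                d.add_population_parameters_change(
                    time=e.start_time, initial_size=e.size, growth_rate=e.growth_rate
                )
        return d


def equilibrium(N: float = 10_000) -> DemographicModel:
    """Constant population size."""
    return DemographicModel("equilibrium", (Epoch(0.0, N),), N)


def _years(y: float) -> float:
    return y / GENERATION_TIME_YEARS


def african_growth() -> DemographicModel:
    """African human model: exponential growth from ~5.1 kya to N = 424,000."""
    t_growth = _years(5115.0)
    g = math.log(424_000 / 14_474) / t_growth
    return DemographicModel(
        "african_growth",
        (
            Epoch(0.0, 424_000, g),
            Epoch(t_growth, 14_474),
            Epoch(_years(148_000.0), 7_310),
        ),
        424_000,
    )


def european_tennessen() -> DemographicModel:
    """European human model: two contractions then two-phase growth."""
    t_fast = _years(5115.0)
    t_slow = _years(23_000.0)
    t_ooa = _years(51_000.0)
    t_af = _years(148_000.0)
    g_fast = math.log(512_000 / 9_300) / t_fast
    g_slow = math.log(9_300 / 1_032) / (t_slow - t_fast)
    return DemographicModel(
        "european_tennessen",
        (
            Epoch(0.0, 512_000, g_fast),
            Epoch(t_fast, 9_300, g_slow),
            Epoch(t_slow, 1_861),
            Epoch(t_ooa, 14_474),
            Epoch(t_af, 7_310),
        ),
        512_000,
    )


def _bottleneck(label: str, severity: float, N: float) -> DemographicModel:
    return DemographicModel(
        label,
        (
            Epoch(0.0, N),
            Epoch(0.0084 * 2 * N, severity * N),
            Epoch(0.044 * 2 * N, N),
        ),
        N,
    )


def bottleneck_mild(N: float = 10_000) -> DemographicModel:
    """Contraction to 29% of the ancestral size."""
    return _bottleneck("bottleneck_mild", 0.29, N)


def bottleneck_severe(N: float = 10_000) -> DemographicModel:
    """Contraction to 2.9% of the ancestral size."""
    return _bottleneck("bottleneck_severe", 0.029, N)


_FACTORIES = {
    "equilibrium": equilibrium,
    "african_growth": african_growth,
    "european_tennessen": european_tennessen,
    "bottleneck_mild": bottleneck_mild,
    "bottleneck_severe": bottleneck_severe,
}

MODEL_NAMES = tuple(_FACTORIES)


def get_model(name: str) -> DemographicModel:
    """Look up a preset demographic model by label."""
    try:
        return _FACTORIES[name]()
    except KeyError:
        raise ValueError(f"unknown demographic model {name!r}; choose from {MODEL_NAMES}")
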