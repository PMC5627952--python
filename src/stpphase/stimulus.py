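"""Sinusoidally rate-modulated presynaptic Poisson spike trains.

The presynaptic drive is an inhomogeneous Poisson process with rate

    lambda_S(t) = A + B * sin(2 * pi * f * t)   [Hz]

shared by all M input neurons; individual trains are statistically
independent.  Spike times are produced by thinning a homogeneous Poisson
process of rate A + B (a tight dominating bound) and each accepted spike is
followed by a dead time (default 2 ms) during which candidate spikes are
deleted.

All times are seconds internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import thin_with_refractory
from ._rng import as_seedseq, generator_from

__all__ = [
    "StimulusParams",
    "SpikeTrain",
    "modulated_rate",
    "generate_spike_train",
    "generate_population",
    "write_spike_trains",
    "read_spike_trains",
]


@dataclass(frozen=True)
class StimulusParams:
    """Parameters of the modulated presynaptic drive.

    A : mean rate (Hz); B : peak modulation depth (Hz); f : modulation
    frequency (Hz); refractory : dead time after each spike (s);
    duration : total simulated time (s).
    """

    A: float = 30.0
    B: float = 20.0
    f: float = 1.0
    refractory: float = 0.002
    duration: float = 23.0

    def __post_init__(self) -> None:
        if self.A - self.B <= 0:
            raise ValueError("require A - B > 0 so the rate stays positive")
        if self.f <= 0:
            raise ValueError("modulation frequency must be positive")
        if self.refractory < 0:
            raise ValueError("refractory period must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class SpikeTrain:
    """One presynaptic spike train: integer id plus sorted spike times (s)."""

    neuron_id: int
    times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))

    def __len__(self) -> int:
        return self.times.size


def modulated_rate(t, p: StimulusParams):
    """Instantaneous input rate lambda_S(t) = A + B sin(2 pi f t), in Hz."""
    return p.A + p.B * np.sin(2.0 * np.pi * p.f * np.asarray(t, dtype=float))


def generate_spike_train(p: StimulusParams, rng: np.random.Generator,
                         neuron_id: int = 0) -> SpikeTrain:
    """Draw one spike train by thinning, with refractory deletion.

    Candidate events are a homogeneous Poisson process at rate A + B on
    [0, duration); each candidate is deleted if it falls within the
    refractory window of the last accepted spike, otherwise accepted with
    probability lambda_S(t)/(A + B).  Deterministic given rng state.
    """
    bound = p.A + p.B
    # Draw candidate times in blocks of cumulative exponential gaps; the
    # expected count is bound*duration, padded by 6 sigma.
    n_guess = int(bound * p.duration + 6.0 * np.sqrt(bound * p.duration) + 20)
    times = np.cumsum(rng.exponential(1.0 / bound, size=n_guess))
    while times.size and times[-1] < p.duration:
        extra = np.cumsum(rng.exponential(1.0 / bound, size=n_guess)) + times[-1]
        times = np.concatenate([times, extra])
    candidates = times[times < p.duration]
    u = rng.random(candidates.size)
    accepted = thin_with_refractory(candidates, u, p.A, p.B,
                                    2.0 * np.pi * p.f, p.refractory)
    return SpikeTrain(neuron_id=neuron_id, times=accepted)


def generate_population(M: int, p: StimulusParams,
                        rng: np.random.Generator | int | np.random.SeedSequence,
                        ) -> list[SpikeTrain]:
    """Generate M independent spike trains on per-neuron sub-streams.

    Sub-streams are spawned from a SeedSequence so that a neuron's train
    depends only on the master seed and its id, not on M.
    """
    if M < 1:
        raise ValueError("population size M must be >= 1")
    children = as_seedseq(rng).spawn(M)
    return [
        generate_spike_train(p, generator_from(child), neuron_id=i)
        for i, child in enumerate(children)
    ]


def write_spike_trains(path, trains: list[SpikeTrain],
                       p: StimulusParams | None = None) -> None:
    """Write spike trains as two-column text: neuron_id<TAB>time_s."""
    with open(path, "w") as fh:
        if p is not None:
            fh.write(f"# A={p.A} B={p.B} f={p.f} refractory={p.refractory} "
                     f"duration={p.duration}\n")
        fh.write("# neuron_id\ttime_s\n")
        for tr in trains:
            for t in tr.times:
                fh.write(f"{tr.neuron_id}\t{t:.9f}\n")


def read_spike_trains(path) -> list[SpikeTrain]:
    """Read spike trains written by :func:`write_spike_trains`."""
    ids: list[int] = []
    ts: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            i, t = line.split("\t")
            ids.append(int(i))
            ts.append(float(t))
    ids_arr = np.asarray(ids)
    ts_arr = np.asarray(ts)
    return [SpikeTrain(int(i), np.sort(ts_arr[ids_arr == i]))
            for i in np.unique(ids_arr)]
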