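"""Conductance-based postsynaptic neuron models driven by vesicle release.

Vesicle releases enter a difference-of-exponentials synaptic conductance

    dg/dt = -g/tau_d + x ,    tau_rise * dx/dt = -x + r(t)

where r(t) is the release count process; tau_rise = 0 is the delta-synapse
limit x(t) = r(t) in which g jumps by the released count.  The synaptic
current I = gbar * g * (v - E_syn) is applied depolarisingly to one of two
single-compartment membranes integrated by forward Euler:

* a two-gate Hodgkin-Huxley variant with gK * n^2 and gNa * m^2 * h
  kinetics, logistic steady-state activations and fixed gate time
  constants (class-II excitability);
* a leaky integrate-and-fire neuron with hard reset and refractory clamp.

Membrane equations use mV / ms / uF.cm^-2 / mS.cm^-2 units internally;
public spike times and time grids are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import integrate_hh, integrate_lif
from .release import ReleaseTrain

__all__ = [
    "SynapseParams",
    "MembraneParams",
    "NeuronTrace",
    "timestep_for",
    "conductance_step",
    "peak_conductance",
    "synaptic_current",
    "bin_release_counts",
    "run_hh",
    "run_lif",
    "detect_spikes",
    "PEAK_WEIGHTS",
    "RISE_SCALE_S",
    "DELTA_SCALE_S",
]

#: Dimensionless peak-conductance weights w_M calibrated per synaptic
#: configuration so that all M give similar low postsynaptic rates.
PEAK_WEIGHTS = {1: 0.12, 2: 0.17, 4: 0.23, 8: 0.29, 16: 0.32,
                32: 0.35, 64: 0.38, 128: 0.4, 256: 0.41, 512: 0.42}

#: Calibration scale (S) multiplying w_M for tau_rise = 0.1 ms.  It equals
#: 1 nS divided by the peak of the unit double-exponential response
#: (tau_rise/tau_d)**(tau_rise/(tau_d - tau_rise)) ~= 0.7743, so a unitary
#: release peaks at w_M nanosiemens for either rise time.
RISE_SCALE_S = 1.2915e-9
#: Calibration scale (S) for the delta synapse (tau_rise = 0).
DELTA_SCALE_S = 1.0e-9

SPIKE_THRESHOLD_MV = 10.0  # HH spike detection: upward crossing of +10 mV


@dataclass(frozen=True)
class SynapseParams:
    """Synaptic conductance kinetics and strength.

    tau_rise, tau_d in ms (0 <= tau_rise < tau_d); g_peak in siemens;
    E_synapse in mV (0 for AMPA-like excitation).
    """

    tau_rise: float = 0.1
    tau_d: float = 1.0
    g_peak: float = PEAK_WEIGHTS[1] * RISE_SCALE_S
    E_synapse: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_rise < self.tau_d:
            raise ValueError("require 0 <= tau_rise < tau_d")
        if self.g_peak <= 0:
            raise ValueError("g_peak must be positive")


@dataclass(frozen=True)
class MembraneParams:
    """Single-compartment membrane constants (cylinder 20 um x 20 um).

    Conductances are S.cm^-2 as tabulated, capacitance uF.cm^-2, voltages
    mV, gate time constants ms, area cm^2.  v_thresh / v_reset / t_refrac
    apply to the integrate-and-fire model only.
    """

    C_m: float = 1.0
    g_l: float = 2e-4
    g_K: float = 0.030
    g_Na: float = 0.025
    E_l: float = -66.0
    E_K: float = -95.0
    E_Na: float = 50.0
    tau_m: float = 0.05
    tau_h: float = 0.5
    tau_n: float = 2.0
    v_thresh: float = -51.5
    v_reset: float = -80.0
    t_refrac: float = 1.8
    area: float = 1.2566e-5
    v_init: float = -66.0

    def __post_init__(self) -> None:
        if self.C_m <= 0 or self.g_l <= 0 or self.area <= 0:
            raise ValueError("C_m, g_l and area must be positive")
        if self.v_reset >= self.v_thresh:
            raise ValueError("require v_reset < v_thresh")


@dataclass(frozen=True)
class NeuronTrace:
    """Simulated membrane trajectory on a uniform grid (times in s)."""

    t: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    g: np.ndarray = field(repr=False)
    spike_times: np.ndarray = field(repr=False)
    dt_ms: float = 0.05
    model: str = "hh"
    m: np.ndarray | None = field(default=None, repr=False)
    h: np.ndarray | None = field(default=None, repr=False)
    n: np.ndarray | None = field(default=None, repr=False)


def timestep_for(f: float) -> float:
    """Euler step (ms) as a function of modulation frequency.

    0.05 ms for f <= 1 Hz, shrinking as 0.05/f above so that one
    modulation cycle always spans the same number of steps.
    """
    if f <= 0:
        raise ValueError("modulation frequency must be positive")
    return 0.05 if f <= 1.0 else 0.05 / f


def peak_conductance(M: int, tau_rise: float = 0.1,
                     w: float | None = None) -> float:
    """Peak synaptic conductance gbar (S) for a synaptic configuration.

    gbar = w_M * scale, where w_M is the tabulated calibration weight and
    scale is RISE_SCALE_S (tau_rise = 0.1 ms) or DELTA_SCALE_S
    (tau_rise = 0).  A custom weight `w` overrides the table.
    """
    if w is None:
        try:
            w = PEAK_WEIGHTS[M]
        except KeyError:
            raise ValueError(
                f"no calibrated weight for M={M}; supply w explicitly"
            ) from None
    scale = DELTA_SCALE_S if tau_rise == 0.0 else RISE_SCALE_S
    return w * scale


def synaptic_current(g, v, p: SynapseParams):
    """Synaptic current I = gbar * g * (v - E_syn), in amperes.

    As written this is negative for v < E_syn; the membrane integrators
    apply it with the sign that depolarises the cell toward E_syn
    (excitatory AMPA convention).
    """
    return p.g_peak * np.asarray(g) * (np.asarray(v) - p.E_synapse) * 1e-3


def conductance_step(g: float, x: float, r_count: float, p: SynapseParams,
                     dt: float) -> tuple[float, float]:
    """One Euler step of the synaptic conductance (dt in ms).

    Releases are impulses: with a finite rise time x jumps by
    r_count/tau_rise; in the delta limit the injection r_count/dt acts for
    a single step, making the conductance increment dt-invariant.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if p.tau_rise == 0.0:
        x_eff = r_count / dt
        return g + dt * (-g / p.tau_d + x_eff), 0.0
    x = x + r_count / p.tau_rise
    g_new = g + dt * (-g / p.tau_d + x)
    x_new = x + dt * (-x / p.tau_rise)
    return g_new, x_new


def bin_release_counts(release: ReleaseTrain, duration: float,
                       dt_ms: float) -> np.ndarray:
    """Assign release counts to Euler steps (right-aligned binning).

    Step i spans ((i-1)*dt, i*dt]; an event strictly between grid points is
    injected at the next grid point.  Returns a float array of per-step
    counts whose sum equals the total released count inside [0, duration].
    """
    dt_s = dt_ms * 1e-3
    nsteps = int(round(duration / dt_s))
    r = np.zeros(nsteps, dtype=np.float64)
    if len(release):
        idx = np.ceil(release.event_times / dt_s - 1e-9).astype(np.int64) - 1
        idx = np.clip(idx, 0, nsteps - 1)
        np.add.at(r, idx, release.counts.astype(np.float64))
    return r


def _trace_times(nsteps: int, dt_ms: float) -> np.ndarray:
    return (np.arange(1, nsteps + 1)) * dt_ms * 1e-3


def run_hh(release: ReleaseTrain, syn: SynapseParams, mem: MembraneParams,
           f: float, duration: float, dt_ms: float | None = None,
           ) -> NeuronTrace:
    """Integrate the HH membrane over [0, duration] s driven by `release`.

    Initial conditions v = -66 mV, m = h = n = 0 (the startup transient is
    meant to fall inside the discarded opening cycles of an experiment).
    """
    if dt_ms is None:
        dt_ms = timestep_for(f)
    r_steps = bin_release_counts(release, duration, dt_ms)
    syn_scale = syn.g_peak * 1e3 / mem.area
    v, m, h, n, g = integrate_hh(
        r_steps, dt_ms, mem.C_m, mem.g_l * 1e3, mem.g_K * 1e3,
        mem.g_Na * 1e3, mem.E_l, mem.E_K, mem.E_Na,
        mem.tau_m, mem.tau_h, mem.tau_n, syn_scale, syn.E_synapse,
        syn.tau_rise, syn.tau_d, mem.v_init)
    if np.max(np.abs(v)) > 200.0:
        raise RuntimeError("membrane potential exceeded 200 mV; "
                           "reduce the integration step")
    t = _trace_times(r_steps.size, dt_ms)
    cross = np.flatnonzero((v[:-1] < SPIKE_THRESHOLD_MV)
                           & (v[1:] > SPIKE_THRESHOLD_MV)) + 1
    return NeuronTrace(t=t, v=v, g=g, spike_times=t[cross], dt_ms=dt_ms,
                       model="hh", m=m, h=h, n=n)


def run_lif(release: ReleaseTrain, syn: SynapseParams, mem: MembraneParams,
            f: float, duration: float, dt_ms: float | None = None,
            ) -> NeuronTrace:
    """Integrate the LIF membrane; spikes are threshold crossings with a
    reset to v_reset held for t_refrac ms."""
    if dt_ms is None:
        dt_ms = timestep_for(f)
    r_steps = bin_release_counts(release, duration, dt_ms)
    syn_scale = syn.g_peak * 1e3 / mem.area
    v, g, spike_idx = integrate_lif(
        r_steps, dt_ms, mem.C_m, mem.g_l * 1e3, mem.E_l, syn_scale,
        syn.E_synapse, syn.tau_rise, syn.tau_d, mem.v_thresh,
        mem.v_reset, mem.t_refrac, mem.v_init)
    if np.max(np.abs(v)) > 200.0:
        raise RuntimeError("membrane potential exceeded 200 mV; "
                           "reduce the integration step")
    t = _trace_times(r_steps.size, dt_ms)
    return NeuronTrace(t=t, v=v, g=g, spike_times=t[spike_idx], dt_ms=dt_ms,
                       model="lif")


def detect_spikes(trace: NeuronTrace, model: str | None = None) -> np.ndarray:
    """Output spike times (s) of a trace.

    HH: upward crossings of +10 mV, v(t - dt) < 10 < v(t).  LIF: the
    threshold-crossing times recorded during integration.
    """
    model = model or trace.model
    if model == "lif":
        return trace.spike_times
    if model != "hh":
        raise ValueError("model must be 'hh' or 'lif'")
    v = trace.v
    cross = np.flatnonzero((v[:-1] < SPIKE_THRESHOLD_MV)
                           & (v[1:] > SPIKE_THRESHOLD_MV)) + 1
    return trace.t[cross]
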