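"""Analytical theory of depression-induced phase shifts.

Conditional vesicle availability P_A|S(t) (probability that a release site
is occupied given a presynaptic spike at t) obeys

    dP/dt = (1 - P)/tau_rec - P_v * lambda_S(t) * P

whose steady state under sinusoidal drive is, to first order in the
modulation,

    P(t) ~ (kappa/tau_rec) * (1 + B*P_v*kappa/sqrt(1 + w^2 k^2)
                                  * cos(w t + arctan(1/(w kappa))))

with w = 2*pi*f and kappa = 1/(1/tau_rec + P_v*A) the effective depression
time constant.  Relative to lambda_S the availability is shifted by
Theta = pi - arctan(w * kappa), approaching anti-phase as f -> 0.

The release-rate proxy c(t) = N_M * P_v * P(t) * ceil(tau_p*M*lambda_S(t))
captures how the phase of the postsynaptic drive interpolates between the
availability phase (few active zones: coincidence detection) and the phase
of P(t)*lambda_S(t) (many zones: temporal integration).  The latter has a
phase lead arctan(w*tau_rec) - arctan(w*kappa), maximised at
w* = 1/sqrt(tau_rec*kappa) — a resonance in modulation frequency.

Phases returned by this module are sine-phase offsets relative to
lambda_S(t), positive = lead, computed by dividing out the first Fourier
coefficient of lambda_S on the same grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

__all__ = [
    "TheoryParams",
    "AvailabilityTrace",
    "solve_availability_ode",
    "availability_phase_numeric",
    "availability_approx",
    "availability_phase",
    "expected_arrivals",
    "quantized_arrivals",
    "release_rate_proxy",
    "theta_Mf",
    "theta_hat",
    "resonance_frequency",
]


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the analytical model (rates Hz, times s)."""

    A: float = 30.0
    B: float = 20.0
    f: float = 1.0
    P_v: float = 0.25
    tau_rec: float = 0.5
    tau_p: float = 0.03
    N: int = 512

    def __post_init__(self) -> None:
        if self.A - self.B <= 0:
            raise ValueError("require A - B > 0")
        if self.f <= 0 or self.tau_rec <= 0 or self.tau_p <= 0:
            raise ValueError("f, tau_rec and tau_p must be positive")
        if not 0.0 <= self.P_v <= 1.0:
            raise ValueError("P_v must lie in [0, 1]")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.f

    @property
    def kappa(self) -> float:
        """Effective depression time constant 1/(1/tau_rec + P_v*A), s."""
        return 1.0 / (1.0 / self.tau_rec + self.P_v * self.A)

    @property
    def gamma(self) -> float:
        return self.B * self.P_v / self.omega

    def rate(self, t):
        return self.A + self.B * np.sin(self.omega * np.asarray(t, float))


@dataclass(frozen=True)
class AvailabilityTrace:
    """Numerical availability solution on a uniform time grid."""

    t: np.ndarray = field(repr=False)
    P: np.ndarray = field(repr=False)


def solve_availability_ode(p: TheoryParams, n_cycles: int = 10,
                           dt: float = 1e-4) -> AvailabilityTrace:
    """Integrate the availability ODE from P(0) = 1 over n_cycles cycles.

    Uses an adaptive high-order solver sampled on a uniform grid of step
    dt; the transient decays on the scale of kappa, well inside the first
    cycle for the default parameters.
    """
    T = n_cycles / p.f
    t_eval = np.linspace(0.0, T, int(round(T / dt)) + 1)

    def rhs(t, P):
        return (1.0 - P) / p.tau_rec - p.P_v * p.rate(t) * P

    sol = solve_ivp(rhs, (0.0, T), [1.0], t_eval=t_eval,
                    rtol=1e-10, atol=1e-12, max_step=min(1e-2, 0.05 / p.f))
    return AvailabilityTrace(t=sol.t, P=sol.y[0])


def _relative_phase(x, t, p: TheoryParams) -> float:
    """Sine-phase of x(t) relative to lambda_S over whole cycles (rad)."""
    w = p.omega
    zx = np.trapezoid(x * np.exp(-1j * w * t), t)
    zl = np.trapezoid(np.sin(w * t) * np.exp(-1j * w * t), t)
    return float(np.angle(zx / zl)) % (2.0 * np.pi)


def availability_phase_numeric(p: TheoryParams, n_cycles: int = 12,
                               discard_cycles: int = 4,
                               dt: float = 1e-4) -> float:
    """Steady-state phase (rad) of the ODE availability w.r.t. lambda_S."""
    trace = solve_availability_ode(p, n_cycles=n_cycles, dt=dt)
    mask = trace.t >= discard_cycles / p.f
    return _relative_phase(trace.P[mask], trace.t[mask], p)


def availability_approx(t, p: TheoryParams):
    """First-order steady-state availability (small-modulation closed form)."""
    t = np.asarray(t, dtype=float)
    w, k = p.omega, p.kappa
    depth = p.B * p.P_v * k / np.sqrt(1.0 + w * w * k * k)
    return (k / p.tau_rec) * (1.0 + depth
                              * np.cos(w * t + np.arctan(1.0 / (w * k))))


def availability_phase(f: float, p: TheoryParams) -> float:
    """Closed-form availability phase Theta = pi - arctan(w*kappa), rad.

    Theta -> pi as f -> 0 (anti-phase with the drive) and decreases with
    increasing modulation frequency.
    """
    if f < 0:
        raise ValueError("frequency must be non-negative")
    w = 2.0 * np.pi * f
    return np.pi - np.arctan(w * p.kappa)


def _check_tau_p(tau_p: float, f: float) -> None:
    if tau_p * f >= 0.5:
        warnings.warn("tau_p is not small compared to the modulation "
                      "period; the arrival-count approximation degrades",
                      stacklevel=3)


def expected_arrivals(t, M: int, p: TheoryParams, tau_p: float | None = None):
    """Expected presynaptic arrivals a(t) = M*tau_p*lambda_S(t) in tau_p."""
    tau_p = p.tau_p if tau_p is None else tau_p
    _check_tau_p(tau_p, p.f)
    return M * tau_p * p.rate(t)


def quantized_arrivals(t, M: int, p: TheoryParams,
                       tau_p: float | None = None):
    """Integer arrival count b(t) = ceil(a(t)) >= 1."""
    return np.ceil(expected_arrivals(t, M, p, tau_p))


def release_rate_proxy(t, M: int, p: TheoryParams,
                       tau_p: float | None = None):
    """Postsynaptic drive proxy c(t) = N_M*P_v*P(t)*ceil(tau_p*M*lambda).

    Without the ceiling this is configuration-independent (N_M*M = N); the
    quantisation is what makes small-M pathways behave as coincidence
    detectors.
    """
    n_m = p.N // M
    return (n_m * p.P_v * availability_approx(t, p)
            * quantized_arrivals(t, M, p, tau_p))


def theta_Mf(M: int, f: float, tau_p: float | None = None,
             p: TheoryParams | None = None) -> float:
    """Phase (rad) of the release-rate proxy relative to lambda_S.

    Numerically evaluates the first Fourier coefficient of c(t) over one
    cycle on a grid fine enough to resolve the ceiling discontinuities
    (step <= tau_p/10) and divides out the coefficient of lambda_S, so the
    no-ceiling limit reproduces the closed-form availability phase
    combination exactly.
    """
    p = TheoryParams() if p is None else p
    if f != p.f:
        p = TheoryParams(A=p.A, B=p.B, f=f, P_v=p.P_v,
                         tau_rec=p.tau_rec, tau_p=p.tau_p, N=p.N)
    tau_p = p.tau_p if tau_p is None else tau_p
    T = 1.0 / f
    dt = min(tau_p / 10.0, T / 2000.0)
    t = np.arange(0.0, T, dt)
    c = release_rate_proxy(t, M, p, tau_p)
    return _relative_phase(c, t, p)


def theta_hat(omega: float, p: TheoryParams) -> float:
    """Large-M phase expression arctan(w*tau_rec) - arctan(w*kappa) - pi/2.

    The first two terms are the sine-phase lead of P(t)*lambda_S(t)
    relative to lambda_S; the constant offset does not move the argmax.
    """
    return (np.arctan(omega * p.tau_rec) - np.arctan(omega * p.kappa)
            - 0.5 * np.pi)


def resonance_frequency(p: TheoryParams, numeric: bool = False) -> float:
    """Modulation frequency (Hz) maximising the large-M phase lead.

    Closed form: w* = 1/sqrt(tau_rec*kappa).  With numeric=True the argmax
    of theta_hat over omega is located by bounded scalar optimisation
    instead (cross-check path).
    """
    if numeric:
        res = minimize_scalar(lambda w: -theta_hat(w, p),
                              bounds=(1e-6, 1e3), method="bounded",
                              options={"xatol": 1e-10})
        return float(res.x) / (2.0 * np.pi)
    return 1.0 / (2.0 * np.pi * np.sqrt(p.tau_rec * p.kappa))
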