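"""Mean-field analysis of pulse-gated graded current propagation.

Units convention (used across the whole package): time is in seconds,
membrane voltage is in reduced units with ``V_thres - V_leak = 1``, and
synaptic currents / couplings are dimensionless reduced quantities.

A graded population is "gated" for a window of length ``T``; successive
layers are gated with an offset ``T0 <= T``, so integration windows of
consecutive layers overlap when ``eta = T / T0 > 1``.  While a population
is gated its firing rate equals its synaptic current (thresholded-linear
transfer with the gate holding the population exactly at threshold); after
the gate closes the current decays exponentially with the synaptic
timescale ``tau``.

The central object is the linear window-to-window propagation operator:
the downstream current starts at zero when its own gate opens (one offset
``T0`` after the upstream gate), integrates the upstream waveform through

    tau dI_d/dt = -I_d + S * I_u(t)

for the duration of its gate, and decays afterwards.  Graded transfer is
exact (amplitude-preserving) when the coupling ``S`` makes the dominant
eigenvalue of this operator equal to one; that coupling is ``S_exact``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PulseSchedule",
    "GradedWaveform",
    "OperatingPoint",
    "MeanFieldCircuit",
    "GridMismatchError",
    "ConvergenceError",
    "BracketingError",
    "RangeError",
    "InstabilityError",
    "FitError",
    "propagate_window",
    "layer_gain",
    "find_S_exact",
    "s_exact_curve",
    "alpha_of",
    "eta_solution_shape",
    "simulate_meanfield",
    "fit_meanfield",
    "AlphaCurve",
    "eta_from_alpha",
]

TAIL_TAUS = 5.0  # waveform tail length in units of tau; exp(-5) ~ 0.7% of peak
_GRID_ATOL = 1e-9  # seconds; tolerance for "dt divides T0 / T1"


class GridMismatchError(ValueError):
    """Raised when waveform grids are inconsistent with a schedule."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries the last two ratios."""

    def __init__(self, msg: str, last_ratios: tuple[float, float]):
        super().__init__(msg)
        self.last_ratios = last_ratios


class BracketingError(ValueError):
    """Root bracket does not straddle unit gain."""


class RangeError(ValueError):
    """Requested value outside the range of a computed curve."""


class InstabilityError(RuntimeError):
    """Mean-field integration blew up."""

    def __init__(self, msg: str, population: int, time: float):
        super().__init__(msg)
        self.population = population
        self.time = time


class FitError(RuntimeError):
    """Optimizer failed; carries the last iterate."""

    def __init__(self, msg: str, last_iterate):
        super().__init__(msg)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class PulseSchedule:
    """Gating timing triple (T, T0, tau), all in seconds.

    Derived quantities: overlap ratio ``eta = T/T0 >= 1``, its integer
    part ``n``, and the remainder ``T1 = T - n*T0`` with ``0 <= T1 < T0``.
    """

    T: float
    T0: float
    tau: float

    def __post_init__(self):
        if not (self.T > 0 and self.tau > 0):
            raise ValueError("T and tau must be positive")
        if not (0 < self.T0 <= self.T * (1 + 1e-12)):
            raise ValueError("require 0 < T0 <= T")

    @classmethod
    def from_ratios(cls, T0_over_tau: float, eta: float, tau: float = 0.005) -> "PulseSchedule":
        T0 = T0_over_tau * tau
        return cls(T=eta * T0, T0=T0, tau=tau)

    @property
    def eta(self) -> float:
        return self.T / self.T0

    @property
    def n(self) -> int:
        # guard against 2.9999999 floor artifacts
        return int(math.floor(self.eta + 1e-9))

    @property
    def T1(self) -> float:
        return max(self.T - self.n * self.T0, 0.0)

    def grid_step(self, target_dt: float | None = None) -> float:
        """A uniform step that divides both T0 and T (hence T1) exactly.

        Defaults to approximately tau/200.  Works for any ``eta`` that is
        (close to) a rational with a moderate denominator, which covers
        every schedule constructed from ratio parameters.
        """
        if target_dt is None:
            target_dt = self.tau / 200.0
        frac = Fraction(self.eta).limit_denominator(4000)
        if abs(float(frac) - self.eta) * self.T0 > _GRID_ATOL:
            raise GridMismatchError(
                f"eta={self.eta} has no rational grid within {_GRID_ATOL} s"
            )
        q = frac.denominator
        k0 = max(1, math.ceil(self.T0 / target_dt / q)) * q
        return self.T0 / k0

    def steps(self, dt: float) -> tuple[int, int]:
        """(steps per T0, steps per T); errors unless dt divides both."""
        k0 = round(self.T0 / dt)
        kT = round(self.T / dt)
        if abs(k0 * dt - self.T0) > _GRID_ATOL or abs(kT * dt - self.T) > _GRID_ATOL:
            raise GridMismatchError(
                f"dt={dt} does not divide T0={self.T0} and T={self.T} "
                f"to within {_GRID_ATOL} s"
            )
        return k0, kT

    def to_dict(self) -> dict:
        return {"T": self.T, "T0": self.T0, "tau": self.tau}

    @classmethod
    def from_dict(cls, d: dict) -> "PulseSchedule":
        return cls(T=float(d["T"]), T0=float(d["T0"]), tau=float(d["tau"]))


@dataclass
class GradedWaveform:
    """A synaptic-current time course over one gating window plus tail.

    ``values[0:gate_steps+1]`` covers the gating window [0, T]; the rest is
    the exponential decay tail.  The grid step is ``dt``.
    """

    dt: float
    values: np.ndarray
    gate_steps: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("waveform values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")
        if self.gate_steps >= self.values.size:
            raise ValueError("gate extends past the sampled grid")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    @property
    def T(self) -> float:
        return self.gate_steps * self.dt

    @property
    def tail_steps(self) -> int:
        return self.values.size - 1 - self.gate_steps

    @property
    def amplitude(self) -> float:
        return float(np.max(self.values))

    def tail_is_exponential(self, tau: float, rtol: float = 1e-6) -> bool:
        """Check the decay-tail invariant: values(T+s) = values(T) e^(-s/tau)."""
        tail = self.values[self.gate_steps:]
        ref = tail[0] * np.exp(-np.arange(tail.size) * self.dt / tau)
        scale = max(abs(tail[0]), 1e-300)
        return bool(np.max(np.abs(tail - ref)) <= rtol * scale)

    def scaled(self, a: float) -> "GradedWaveform":
        return GradedWaveform(self.dt, self.values * a, self.gate_steps)


@dataclass(frozen=True)
class OperatingPoint:
    """A coupling strength with its overlap ratio and alpha value."""

    S: float
    eta: float
    alpha: float


def alpha_of(S: float, T0: float, tau: float) -> float:
    """The operating parameter ``alpha = S * (T0/tau) * exp(-T0/tau)``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    r = T0 / tau
    return S * r * math.exp(-r)


def eta_solution_shape(sched: PulseSchedule, dt: float | None = None) -> GradedWaveform:
    """The non-overlapping (eta = 1) invariant shape, t/tau * exp(-t/tau).

    Used as the seed waveform for power iteration; unit amplitude.
    """
    if dt is None:
        dt = sched.grid_step()
    k0, kT = sched.steps(dt)
    n_tail = int(math.ceil(TAIL_TAUS * sched.tau / dt))
    t_gate = np.arange(kT + 1) * dt
    vals = np.empty(kT + 1 + n_tail)
    vals[: kT + 1] = (t_gate / sched.tau) * np.exp(-t_gate / sched.tau)
    vals[kT:] = vals[kT] * np.exp(-np.arange(n_tail + 1) * dt / sched.tau)
    w = GradedWaveform(dt, vals, kT)
    a = w.amplitude
    return w.scaled(1.0 / a) if a > 0 else w


def propagate_window(
    upstream: GradedWaveform, sched: PulseSchedule, S: float
) -> GradedWaveform:
    """One layer-to-layer transfer of a graded waveform.

    The downstream gate opens ``T0`` after the upstream gate.  The
    downstream current starts at exactly zero at its own gate onset and,
    while its gate is open, obeys ``tau dI/dt = -I + S * I_u`` where
    ``I_u`` is the upstream waveform (gated-linear during the upstream
    gate, exponential tail after).  After the downstream gate closes the
    current decays with timescale ``tau``.  The map is linear in the
    upstream waveform; negative ``S`` is allowed.
    """
    dt = upstream.dt
    k0, kT = sched.steps(dt)
    if upstream.gate_steps != kT:
        raise GridMismatchError(
            f"upstream gate covers {upstream.gate_steps} steps, schedule needs {kT}"
        )
    if upstream.tail_steps < k0:
        raise GridMismatchError("upstream tail shorter than one pulse offset T0")

    # Upstream samples seen by the downstream gate: t in [T0, T0 + T].
    u = upstream.values[k0 : k0 + kT + 1]

    # Exact exponential integrator for piecewise-linear input.
    h = dt / sched.tau
    a = math.exp(-h)
    phi1 = 1.0 - a
    phi2 = 1.0 - phi1 / h
    c0 = S * (phi1 - phi2)
    c1 = S * phi2

    gate = np.empty(kT + 1)
    gate[0] = 0.0
    acc = 0.0
    # small loop (a few hundred steps); numpy recurrence not vectorizable
    for i in range(kT):
        acc = a * acc + c0 * u[i] + c1 * u[i + 1]
        gate[i + 1] = acc

    n_tail = int(math.ceil(TAIL_TAUS * sched.tau / dt))
    vals = np.empty(kT + 1 + n_tail)
    vals[: kT + 1] = gate
    vals[kT:] = gate[kT] * np.exp(-np.arange(n_tail + 1) * dt / sched.tau)
    return GradedWaveform(dt, vals, kT)


def layer_gain(
    sched: PulseSchedule,
    S: float,
    tol: float = 1e-10,
    dt: float | None = None,
    max_iter: int = 1000,
    return_shape: bool = False,
):
    """Asymptotic per-layer amplitude gain of repeated gated transfer.

    Power iteration on the linear propagation operator: repeatedly apply
    :func:`propagate_window`, renormalizing to unit amplitude, until the
    amplitude ratio stabilizes to ``tol``.  Returns the gain, or
    ``(gain, shape)`` with the converged unit-amplitude invariant waveform
    when ``return_shape`` is true.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if S == 0.0:
        if return_shape:
            return 0.0, eta_solution_shape(sched, dt).scaled(0.0)
        return 0.0
    w = eta_solution_shape(sched, dt)
    gain_prev = math.nan
    gain = math.nan
    for _ in range(max_iter):
        w2 = propagate_window(w, sched, S)
        gain = w2.amplitude
        if gain <= 0.0:
            break
        w = w2.scaled(1.0 / gain)
        if abs(gain - gain_prev) < tol:
            if return_shape:
                return gain, w
            return gain
        gain_prev = gain
    if gain <= 0.0:  # operator annihilated the waveform (e.g. S < 0 extremes)
        if return_shape:
            return 0.0, w
        return 0.0
    raise ConvergenceError(
        f"layer gain did not stabilize to {tol} in {max_iter} iterations",
        (gain_prev, gain),
    )


def find_S_exact(
    sched: PulseSchedule,
    bracket: tuple[float, float] = (0.5, 3.5),
    tol: float = 1e-4,
    dt: float | None = None,
) -> OperatingPoint:
    """Smallest coupling in ``bracket`` at which the layer gain is one.

    Bisection on ``layer_gain(S) - 1``; the gain is strictly increasing
    in S (the operator is linear and positive), so the smallest root in a
    straddling bracket is the unique one.
    """
    lo, hi = bracket
    if not (0 <= lo < hi):
        raise ValueError("invalid bracket")
    if dt is None:
        dt = sched.grid_step()
    # gain is linear in S: gain(S) = S * gain(1).  Use that for speed but
    # keep the bisection contract (bracket check + tolerance).
    g1 = layer_gain(sched, 1.0, dt=dt)
    g_lo, g_hi = lo * g1, hi * g1
    if (g_lo - 1.0) * (g_hi - 1.0) > 0:
        raise BracketingError(
            f"gain at bracket ends ({g_lo:.4f}, {g_hi:.4f}) does not straddle 1"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mid * g1 < 1.0:
            lo = mid
        else:
            hi = mid
    S = 0.5 * (lo + hi)
    return OperatingPoint(S=S, eta=sched.eta, alpha=alpha_of(S, sched.T0, sched.tau))


def s_exact_curve(
    T0_over_tau: float,
    eta_values: Sequence[float],
    tau: float = 0.005,
    bracket: tuple[float, float] = (0.05, 30.0),
    dt_per_tau: float = 1.0 / 200.0,
) -> list[OperatingPoint]:
    """(eta, S_exact, alpha_exact) triples along an overlap sweep."""
    out = []
    for eta in eta_values:
        if eta < 1.0 - 1e-12:
            raise ValueError("eta must be >= 1")
        sched = PulseSchedule.from_ratios(T0_over_tau, eta, tau)
        dt = sched.grid_step(tau * dt_per_tau)
        out.append(find_S_exact(sched, bracket=bracket, dt=dt))
    return out


class AlphaCurve:
    """Monotone interpolant of alpha_exact as a function of eta."""

    def __init__(
        self,
        T0_over_tau: float,
        eta_grid: np.ndarray | None = None,
        tau: float = 0.005,
    ):
        if eta_grid is None:
            eta_grid = np.r_[1.0, np.arange(1.05, 4.01, 0.05)]
        pts = s_exact_curve(T0_over_tau, list(eta_grid), tau=tau)
        self.eta = np.array([p.eta for p in pts])
        self.alpha = np.array([p.alpha for p in pts])
        self.S = np.array([p.S for p in pts])
        if not np.all(np.diff(self.alpha) < 0):
            raise RuntimeError("alpha_exact(eta) is not monotone on the grid")

    def alpha_at(self, eta: float) -> float:
        if not (self.eta[0] - 1e-12 <= eta <= self.eta[-1] + 1e-12):
            raise RangeError(f"eta={eta} outside curve range")
        return float(np.interp(eta, self.eta, self.alpha))

    def eta_at(self, alpha: float) -> float:
        a_rev, e_rev = self.alpha[::-1], self.eta[::-1]
        if not (a_rev[0] - 1e-12 <= alpha <= a_rev[-1] + 1e-12):
            raise RangeError(
                f"alpha={alpha:.4f} outside curve range "
                f"[{a_rev[0]:.4f}, {a_rev[-1]:.4f}]"
            )
        return float(np.interp(alpha, a_rev, e_rev))


def eta_from_alpha(
    alpha_sim: float,
    T0_over_tau: float,
    curve: AlphaCurve | None = None,
) -> float:
    """Invert the alpha_exact(eta) curve by monotone interpolation."""
    if curve is None:
        curve = AlphaCurve(T0_over_tau)
    return curve.eta_at(alpha_sim)


@dataclass
class MeanFieldCircuit:
    """A thresholded-linear rate network with square gating pulses.

    Dynamics: ``tau dI/dt = -I + S K m + drive`` with the rate vector
    ``m = [I + g0 * p(t) - g0]_+`` where ``p(t)`` is the per-population
    binary gate (unions of half-open [on, off) intervals).
    """

    n_pops: int
    K: np.ndarray
    S: float
    tau: float = 0.005
    g0: float = 50.0
    pulses: list[list[tuple[float, float]]] = field(default_factory=list)
    drive: Callable[[float], np.ndarray] | None = None

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if self.K.shape != (self.n_pops, self.n_pops):
            raise ValueError("K must be square and match the population count")
        if not self.pulses:
            self.pulses = [[] for _ in range(self.n_pops)]
        if len(self.pulses) != self.n_pops:
            raise ValueError("one pulse schedule per population required")

    def gate_vector(self, t: float) -> np.ndarray:
        g = np.zeros(self.n_pops)
        for j, ivals in enumerate(self.pulses):
            for on, off in ivals:
                if on <= t < off:
                    g[j] = 1.0
                    break
        return g


def simulate_meanfield(
    circuit: MeanFieldCircuit,
    duration: float,
    dt: float | None = None,
    I0: np.ndarray | None = None,
):
    """Integrate the gated rate network; returns (times, currents, rates).

    ``currents`` and ``rates`` have shape (n_pops, n_steps + 1).  Uses an
    exponential-Euler step (exact for the decay, piecewise-constant rate
    input over a step).  Raises :class:`InstabilityError` if any current
    exceeds 1e6.
    """
    tau = circuit.tau
    if dt is None:
        dt = tau / 200.0
    if dt > tau / 50.0 + 1e-15:
        raise ValueError("dt must be <= tau/50")
    n_steps = int(round(duration / dt))
    n = circuit.n_pops
    times = np.arange(n_steps + 1) * dt
    I = np.zeros(n) if I0 is None else np.array(I0, dtype=float)
    currents = np.empty((n, n_steps + 1))
    rates = np.empty((n, n_steps + 1))
    a = math.exp(-dt / tau)
    SK = circuit.S * circuit.K

    # precompute gate booleans on the grid (cheap, avoids per-step interval scan)
    gates = np.zeros((n, n_steps + 1))
    for j, ivals in enumerate(circuit.pulses):
        for on, off in ivals:
            i0 = int(math.ceil((on - 1e-12) / dt))
            i1 = int(math.ceil((off - 1e-12) / dt))
            gates[j, max(i0, 0) : min(i1, n_steps + 1)] = 1.0

    for k in range(n_steps + 1):
        t = times[k]
        m = I + circuit.g0 * (gates[:, k] - 1.0)
        np.maximum(m, 0.0, out=m)
        currents[:, k] = I
        rates[:, k] = m
        if k == n_steps:
            break
        target = SK @ m
        if circuit.drive is not None:
            target = target + circuit.drive(t)
        I = a * I + (1.0 - a) * target
        if np.any(np.abs(I) > 1e6):
            j = int(np.argmax(np.abs(I)))
            raise InstabilityError(
                f"current blow-up in population {j} at t={t + dt:.6f}", j, t + dt
            )
    return times, currents, rates


def _fit_design(eta, alpha, sched0, T0, tau, dt, n_layers, n_t, onset_idx):
    """Predicted unit-scale traces for each layer at one (eta, alpha)."""
    sched = PulseSchedule.from_ratios(T0 / tau, eta, tau)
    grid_dt = sched.grid_step(dt)
    gain1, shape = layer_gain(sched, 1.0, dt=grid_dt, return_shape=True)
    g = alpha * math.exp(T0 / tau) / (T0 / tau) * gain1
    # resample the invariant shape onto the trace grid
    t_shape = shape.times
    k0 = round(T0 / dt)
    pred = np.zeros((n_layers, n_t))
    tgrid = np.arange(n_t) * dt
    for j in range(n_layers):
        tj = tgrid - onset_idx * dt - j * T0
        pred[j] = (g ** j) * np.interp(tj, t_shape, shape.values, left=0.0, right=0.0)
    return pred


def fit_meanfield(
    traces: np.ndarray,
    T0: float,
    tau: float,
    dt: float,
    layer0_onset: float = 0.0,
    eta_bounds: tuple[float, float] = (1.05, 4.0),
    x0: tuple[float, float] | None = None,
    fit_onset: bool = False,
):
    """Best-fit (eta, alpha) of the invariant-waveform family to traces.

    ``traces`` has shape (n_amplitudes, n_layers, n_time) on a uniform grid
    of step ``dt``; layer j of each trace is modelled as
    ``a_i * gain(eta, alpha)**j * W_eta(t - onset - j*T0)`` with one free
    positive scale ``a_i`` per amplitude trace and a single (eta, alpha)
    shared across all traces.  Returns
    ``(eta_fit, alpha_fit, fitted, residual)`` where ``fitted`` matches the
    shape of ``traces`` and ``residual`` is the sum of squared errors.
    """
    from scipy.optimize import minimize

    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 3:
        raise ValueError("traces must have shape (n_amp, n_layers, n_time)")
    n_amp, n_layers, n_t = traces.shape
    onset_idx0 = layer0_onset / dt

    def sse(params):
        eta = params[0]
        alpha = params[1]
        oidx = params[2] if fit_onset else onset_idx0
        if not (eta_bounds[0] <= eta <= eta_bounds[1]) or alpha <= 0:
            return 1e30
        try:
            pred = _fit_design(eta, alpha, None, T0, tau, dt, n_layers, n_t, oidx)
        except (GridMismatchError, ConvergenceError):
            return 1e30
        total = 0.0
        for i in range(n_amp):
            num = float(np.sum(pred * traces[i]))
            den = float(np.sum(pred * pred))
            a_i = max(num / den, 0.0) if den > 0 else 0.0
            total += float(np.sum((traces[i] - a_i * pred) ** 2))
        return total

    if x0 is None:
        x0 = (2.0, 0.55)
    p0 = list(x0) + ([onset_idx0] if fit_onset else [])
    res = minimize(sse, p0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 2000})
    if not res.success:
        raise FitError("mean-field fit did not converge", res.x)
    eta_fit, alpha_fit = float(res.x[0]), float(res.x[1])
    oidx = float(res.x[2]) if fit_onset else onset_idx0
    pred = _fit_design(eta_fit, alpha_fit, None, T0, tau, dt, n_layers, n_t, oidx)
    fitted = np.empty_like(traces)
    for i in range(n_amp):
        num = float(np.sum(pred * traces[i]))
        den = float(np.sum(pred * pred))
        a_i = max(num / den, 0.0) if den > 0 else 0.0
        fitted[i] = a_i * pred
    residual = float(np.sum((traces - fitted) ** 2))
    return eta_fit, alpha_fit, fitted, residual
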