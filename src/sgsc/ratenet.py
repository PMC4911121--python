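"""Rate-network (mean-field) execution of circuit blueprints.

Runs the same :class:`~sgsc.circuits.CircuitBlueprint` objects as the
spiking simulator, but at the firing-rate level with idealized,
stereotyped gating pulses:

* a **graded**-class population fires thresholded-linearly,
  ``m = [I + drive - g0]_+`` (its gate current arrives through the
  connectivity like any other input);
* a **gating**-class population is a pulse generator: when its total
  input crosses ``g0`` (and it is not refractory) it emits a square rate
  pulse of amplitude ``r_gate`` and duration ``T_pulse``, after which it
  is refractory -- the rate-level idealization of an attractor synfire
  volley, which has stereotyped amplitude and width no matter how it was
  ignited.

Couplings: a block (source -> target, strength S, entry K) contributes
``S * K * m_source`` to the target's current drive; this matches the
population-mean current of the spiking model, where the per-spike
increment ``S K / (p N tau)`` summed over the expected ``p N`` inputs
integrates to ``S K`` times the per-neuron source rate.

Time in seconds, currents in reduced units, rates in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .circuits import CircuitBlueprint

__all__ = ["RateRun", "simulate_blueprint_rates", "calibrate_rate_gain"]

G0 = 50.0  # threshold current in reduced units: g_leak * (V_thres - V_leak)
R_GATE = 300.0  # stereotyped pulse rate (~1 spike per neuron per ~3.3 ms)


@dataclass
class RateRun:
    """Result of a rate-level blueprint run."""

    t: np.ndarray
    currents: np.ndarray  # (n_pops, n_t) synaptic currents
    rates: np.ndarray  # (n_pops, n_t) firing rates (Hz)
    pop_names: list[str]
    pulses: dict[str, list[float]] = field(default_factory=dict)  # trigger times

    def idx(self, name: str) -> int:
        return self.pop_names.index(name)

    def amplitude(self, name: str, t0: float, t1: float) -> float:
        m = (self.t >= t0) & (self.t < t1)
        return float(self.currents[self.idx(name)][m].max()) if m.any() else 0.0

    def pulse_times(self, name: str) -> list[float]:
        return self.pulses.get(name, [])


def simulate_blueprint_rates(
    bp: CircuitBlueprint,
    duration: float,
    dt: float = 5e-5,
    T_pulse: float = 0.0075,
    refractory: float = 0.0075,
    g0: float = G0,
    r_gate: float = R_GATE,
    record: bool = True,
) -> RateRun:
    """Integrate the blueprint as a gated rate network.

    Gating-class populations trigger on input crossing ``g0`` and emit
    square ``r_gate`` pulses of length ``T_pulse``; they are refractory
    for ``T_pulse + refractory`` after triggering.  Graded-class
    populations fire ``[I + drive - g0]_+``.  External stimuli /
    sinusoids from the blueprint act as injected current drive.
    """
    bp.validate()
    names = bp.pop_names()
    n = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    is_gating = np.array([p.cls == "gating" for p in bp.populations])
    n_steps = int(round(duration / dt))
    tau = np.array([p.tau for p in bp.populations])
    a = np.exp(-dt / tau)

    # gating -> graded blocks deliver the gate as a square term directly in
    # the rate argument (the idealized pulse of the mean-field equations);
    # all other blocks are synaptic currents filtered through tau.
    W = np.zeros((n, n))
    W_gate = np.zeros((n, n))
    src_gating = {p.name: p.cls == "gating" for p in bp.populations}
    tgt_gating = {p.name: p.cls == "gating" for p in bp.populations}
    for b in bp.blocks:
        if src_gating[b.source] and not tgt_gating[b.target]:
            W_gate[idx[b.target], idx[b.source]] += b.S * b.K
        else:
            W[idx[b.target], idx[b.source]] += b.S * b.K

    drive = bp.drive_matrix(n_steps, dt)

    I = np.zeros(n)
    pulse_until = np.full(n, -1.0)
    refr_until = np.full(n, -1.0)
    pulses: dict[str, list[float]] = {nm: [] for nm in names}

    currents = np.zeros((n, n_steps)) if record else None
    rates = np.zeros((n, n_steps)) if record else None
    t_grid = (np.arange(n_steps) + 1) * dt

    m = np.zeros(n)
    gate_in = np.zeros(n)
    for k in range(n_steps):
        t = k * dt
        x = I + gate_in + drive[:, k] - g0
        # graded populations: thresholded-linear
        m[:] = np.where(~is_gating, np.maximum(x, 0.0), 0.0)
        # gating populations: stereotyped pulse generators
        trig = is_gating & (x >= 0.0) & (t >= refr_until)
        for j in np.nonzero(trig)[0]:
            pulse_until[j] = t + T_pulse
            refr_until[j] = t + T_pulse + refractory
            pulses[names[j]].append(t)
        active = is_gating & (t < pulse_until)
        m[active] = r_gate
        # a population is either gated or not: overlapping pulses do not
        # stack (binary diagonal gate matrix), so saturate at g0
        gate_in = np.clip(W_gate @ m, 0.0, g0)
        target = W @ m
        I = a * I + (1.0 - a) * target
        if record:
            currents[:, k] = I
            rates[:, k] = m
    return RateRun(t=t_grid, currents=currents, rates=rates,
                   pop_names=names, pulses=pulses)


def calibrate_rate_gain(
    W12: float,
    T0: float = 0.004,
    tau: float = 0.005,
    T_pulse: float = 0.0075,
    w_range: tuple[float, float] = (0.1, 10.0),
    tol: float = 1e-3,
) -> float:
    """Graded-graded coupling with unit amplitude gain on the rate backend.

    Builds a minimal gated three-layer chain (pulse generators driving
    the gates of three graded populations, offset by ``T0``) and bisects
    the graded coupling until the layer-2 to layer-3 amplitude gain is
    one.  ``W12`` is the gate-delivery coupling (S*K per unit rate).
    """
    from .spiking import PopulationSpec, ConnectivityBlock
    from .circuits import Stimulus

    def gain(w: float) -> float:
        pops = (
            [PopulationSpec(f"s{j}", 1, cls="gating", tau=tau) for j in (1, 2, 3)]
            + [PopulationSpec(f"g{j}", 1, cls="graded", tau=tau) for j in (1, 2, 3)]
        )
        # chain coupling tuned so the pulse delay is exactly T0
        w22 = (G0 / (1.0 - math.exp(-T0 / tau))) / R_GATE
        blocks = [ConnectivityBlock("s1", "s2", S=w22),
                  ConnectivityBlock("s2", "s3", S=w22)]
        for j in (1, 2, 3):
            blocks.append(ConnectivityBlock(f"s{j}", f"g{j}", S=W12))
        blocks.append(ConnectivityBlock("g1", "g2", S=w))
        blocks.append(ConnectivityBlock("g2", "g3", S=w))
        bp = CircuitBlueprint(
            populations=pops, blocks=blocks,
            stimuli=[Stimulus("s1", 0.0, 0.001, 2 * G0 / 0.001 * 0.001),
                     Stimulus("g1", 0.0, T_pulse, 30.0)],
        )
        # ignition: brief super-threshold kick to s1
        bp.stimuli[0] = Stimulus("s1", 0.0, 0.002, 3 * G0)
        run = simulate_blueprint_rates(bp, duration=6 * T0 + 6 * tau)
        a2 = run.amplitude("g2", 0.0, run.t[-1])
        a3 = run.amplitude("g3", 0.0, run.t[-1])
        return a3 / a2 if a2 > 0 else 0.0

    lo, hi = w_range
    g_lo, g_hi = gain(lo), gain(hi)
    if not (g_lo < 1.0 < g_hi):
        raise RuntimeError(f"rate gain not bracketed: {g_lo:.3f}, {g_hi:.3f}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gain(mid) < 1.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _rate_apply_map(K: np.ndarray, x: np.ndarray, W11: float = 1.743,
                    T0: float = 0.004, tau: float = 0.005) -> np.ndarray:
    """Downstream amplitude vector after one gated linear-map transfer."""
    from .circuits import Stimulus
    from .spiking import ConnectivityBlock, PopulationSpec

    K = np.asarray(K, dtype=float)
    n_up, n_dn = K.shape[1], K.shape[0]
    w22 = (G0 / (1.0 - math.exp(-T0 / tau))) / R_GATE
    pops = ([PopulationSpec("s1", 1, cls="gating", tau=tau),
             PopulationSpec("s2", 1, cls="gating", tau=tau)]
            + [PopulationSpec(f"u{i}", 1, cls="graded", tau=tau)
               for i in range(n_up)]
            + [PopulationSpec(f"d{i}", 1, cls="graded", tau=tau)
               for i in range(n_dn)])
    blocks = [ConnectivityBlock("s1", "s2", S=w22)]
    for i in range(n_up):
        blocks.append(ConnectivityBlock("s1", f"u{i}", S=G0 / R_GATE))
    for i in range(n_dn):
        blocks.append(ConnectivityBlock("s2", f"d{i}", S=G0 / R_GATE))
        for j in range(n_up):
            if K[i, j] != 0.0:
                blocks.append(ConnectivityBlock(f"u{j}", f"d{i}",
                                                S=W11, K=float(K[i, j])))
    stimuli = [Stimulus("s1", 0.0, 0.002, 3 * G0)]
    for j in range(n_up):
        stimuli.append(Stimulus(f"u{j}", 0.0, 0.0075, float(x[j])))
    bp = CircuitBlueprint(populations=pops, blocks=blocks, stimuli=stimuli)
    rr = simulate_blueprint_rates(bp, duration=T0 + 0.0075 + 6 * tau)
    return np.array([rr.currents[rr.idx(f"d{i}")].max() for i in range(n_dn)])


def rate_linear_map_check(K: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One gated transfer of ``K`` applied to amplitudes ``x``, rescaled
    by an identity-map reference so the result is directly comparable to
    ``K @ x``.  Oracle harness for linear-map blocks."""
    K = np.asarray(K, dtype=float)
    x = np.asarray(x, dtype=float)
    down = _rate_apply_map(K, x)
    ref = _rate_apply_map(np.eye(x.size), x)
    scale = float(np.sum(ref * x) / np.sum(x * x))
    return down / scale


def rate_hadamard_check(x: np.ndarray, scale: float = 0.25) -> np.ndarray:
    """Sign-split Hadamard outputs for amplitudes ``x`` on the rate
    backend, rescaled like :func:`rate_linear_map_check`."""
    from .circuits import hadamard4

    H = hadamard4()
    K = np.vstack([scale * H, -scale * H])
    x = np.asarray(x, dtype=float)
    down = _rate_apply_map(K, x)
    ref = _rate_apply_map(np.eye(4), x)
    s = float(np.sum(ref * x) / np.sum(x * x))
    return down / (s * scale) * scale  # keep the 'scale' factor in outputs
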