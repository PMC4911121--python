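"""Trial statistics and robustness experiments for graded transfer.

Amplitude is defined as the peak of the population-mean synaptic current
within a layer's gating window; per-layer means and standard deviations
are computed across independently seeded trials.  Perturbation
experiments resample couplings per trial or jitter gate-delivery times
in a hybrid mode where the gate schedule is imposed as injected current.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .circuits import CircuitBlueprint, graded_windows, layer_amplitudes
from .spiking import SpikeRecord, run

__all__ = [
    "TransferStats",
    "trial_mean_currents",
    "snr_experiment",
    "smooth_rates",
    "pulse_firing_rate",
    "volley_window",
    "PERTURBATIONS",
]

PERTURBATIONS = ("none", "coupling_S11_uniform_5pct", "coupling_S12_uniform_5pct",
                 "pulse_jitter_10pct", "resize_N")


@dataclass
class TransferStats:
    """Per-layer amplitude statistics over seeded trials."""

    mean: np.ndarray  # per-layer mean amplitude (reduced current units)
    std: np.ndarray  # per-layer standard deviation
    trials: int
    amplitude: float  # probe input amplitude
    fingerprint: str = ""

    def __post_init__(self):
        if self.trials < 2:
            raise ValueError("need at least two trials")
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be nonnegative")


def _fingerprint(bp: CircuitBlueprint, extra: dict) -> str:
    payload = json.dumps({"bp": bp.to_dict(), **extra}, sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def probe_drive(bp: CircuitBlueprint, amplitude: float):
    """Drive functions injecting a square probe into the first graded layer."""
    T0 = bp.meta["T0"]
    t1 = bp.meta["t_first"]
    gate_len = bp.meta.get("gate_len", 3 * T0)
    drv = dict(bp.drive_functions())
    g1 = bp.groups["graded"][0]
    base = drv.get(g1, lambda t: 0.0)
    t_on = t1 - 0.5 * T0
    drv[g1] = (lambda t, b=base: b(t)
               + (amplitude if t_on <= t < t_on + gate_len else 0.0))
    return drv


def _collect_amplitudes(bp: CircuitBlueprint, net, amplitude: float,
                        trials: int, seed: int, dt: float,
                        jitter_frac: float = 0.0,
                        seed_list=None) -> np.ndarray:
    """(trials, n_layers) window-peak amplitudes of the graded chain."""
    graded_names = bp.groups["graded"]
    n_layers = len(graded_names)
    T0 = bp.meta["T0"]
    t1 = bp.meta["t_first"]
    duration = t1 + (n_layers + 1.5) * T0
    gi = [net.name_to_idx[nm] for nm in graded_names]
    out = np.zeros((trials, n_layers))
    rng = np.random.default_rng(seed + 777)
    if seed_list is None:
        seed_list = [seed + 1000 + k for k in range(trials)]
    for k in range(trials):
        if jitter_frac > 0.0:
            drv, wins = _jittered_gate_drive(bp, net, amplitude, jitter_frac,
                                             rng)
        else:
            drv = probe_drive(bp, amplitude)
            wins = graded_windows(t1, T0, n_layers)
        _, tr = run(net, duration, dt=dt, drive=drv, seed=seed_list[k])
        out[k] = layer_amplitudes(tr, n_layers, gi, wins)
    return out


def trial_mean_currents(bp: CircuitBlueprint, amplitudes, trials: int,
                        seed: int, dt: float = 2e-5,
                        seed_list=None) -> list[TransferStats]:
    """Seeded-trial amplitude statistics for each probe amplitude.

    The probe is a square current injected into the first graded layer
    during its gating window; the per-layer amplitude is the peak of the
    population-mean synaptic current within that layer's gating window.
    """
    if trials < 2:
        raise ValueError("need at least two trials")
    net = bp.build()
    stats = []
    for a in amplitudes:
        amps = _collect_amplitudes(bp, net, a, trials, seed, dt,
                                   seed_list=seed_list)
        stats.append(TransferStats(
            mean=amps.mean(axis=0), std=amps.std(axis=0, ddof=1),
            trials=trials, amplitude=a,
            fingerprint=_fingerprint(bp, {"amplitude": a, "seed": seed}),
        ))
    return stats


def _perturbed_blueprint(bp: CircuitBlueprint, which: str,
                         rng: np.random.Generator) -> CircuitBlueprint:
    """Resample block strengths from a uniform 5%-half-width distribution."""
    graded = set(bp.groups["graded"])
    gating = set(bp.groups.get("gating", []))
    blocks = []
    for b in bp.blocks:
        hit = (
            which == "S11" and b.source in graded and b.target in graded
        ) or (
            which == "S12" and b.source in gating and b.target in graded
        )
        if hit:
            blocks.append(replace(b, S=b.S * rng.uniform(0.95, 1.05),
                                  seed=b.seed))
        else:
            blocks.append(b)
    return CircuitBlueprint(populations=bp.populations, blocks=blocks,
                            groups=bp.groups, stimuli=bp.stimuli,
                            sinusoids=bp.sinusoids, seed=bp.seed,
                            meta=dict(bp.meta))


def _gate_template(bp: CircuitBlueprint, dt: float):
    """Mean gate-current bump of a mid-chain layer from a reference run."""
    net = bp.build()
    graded_names = bp.groups["graded"]
    T0, t1 = bp.meta["T0"], bp.meta["t_first"]
    n_layers = len(graded_names)
    duration = t1 + (n_layers + 1.5) * T0
    _, tr = run(net, duration, dt=dt, drive=bp.drive_functions(),
                seed=bp.seed + 31)
    j = n_layers // 2
    i = net.name_to_idx[graded_names[j]]
    bump = tr["gating"][i].copy()
    t = tr["t"]
    onset = t1 + j * T0 - 1.5 * T0
    sel = (t >= onset) & (t < onset + 4 * T0)
    template = bump[sel]
    lead = 1.5 * T0  # template starts this long before the nominal window
    return template, lead


def _jittered_gate_drive(bp: CircuitBlueprint, net, amplitude: float,
                         jitter_frac: float, rng: np.random.Generator):
    """Hybrid-mode drive: imposed per-layer gate bumps at jittered times.

    The gating chain is bypassed (its couplings are absent from the hybrid
    blueprint); each graded layer instead receives the recorded mean gate
    bump as injected current, delayed by U(-jitter, +jitter) * T0.
    """
    template = bp.meta["_gate_template"]
    lead = bp.meta["_gate_lead"]
    tdt = bp.meta["_gate_dt"]
    T0, t1 = bp.meta["T0"], bp.meta["t_first"]
    graded_names = bp.groups["graded"]
    n_layers = len(graded_names)
    tt = np.arange(template.size) * tdt
    drv = {}
    wins = []
    for j, nm in enumerate(graded_names):
        delay = rng.uniform(-jitter_frac, jitter_frac) * T0
        onset = t1 + j * T0 - lead + delay
        fns = [lambda t, on=onset: float(np.interp(t - on, tt, template,
                                                   left=0.0, right=0.0))]
        if j == 0:
            t_on = t1 - 0.5 * T0
            gl = bp.meta.get("gate_len", 3 * T0)
            fns.append(lambda t: amplitude if t_on <= t < t_on + gl else 0.0)
        drv[nm] = (lambda t, fns=fns: sum(f(t) for f in fns))
        halfwin = 1.5 * T0
        wins.append((t1 + j * T0 + delay - halfwin / 2,
                     t1 + j * T0 + delay + 1.5 * halfwin))
    return drv, wins


def snr_experiment(bp: CircuitBlueprint, trials: int = 1000,
                   perturbation: str = "none", seed: int = 0,
                   amplitude: float | None = None, dt: float = 2e-5,
                   N1: int | None = None) -> TransferStats:
    """Per-layer (mean, std) of transfer amplitude under a perturbation.

    Coupling perturbations resample each affected block strength per
    trial from a uniform distribution of half-width 5% around its
    calibrated value; ``pulse_jitter_10pct`` shifts each layer's imposed
    gate-delivery time by U(-10%, +10%) of T0 per layer per trial;
    ``resize_N`` rebuilds the circuit with ``N1`` neurons per graded
    layer.
    """
    if perturbation not in PERTURBATIONS:
        raise ValueError(f"unknown perturbation {perturbation!r}; "
                         f"choose from {PERTURBATIONS}")
    if amplitude is None:
        amplitude = bp.meta.get("probe_amplitudes", [50.0])[-1] \
            if isinstance(bp.meta.get("probe_amplitudes"), list) \
            else 50.0
    rng = np.random.default_rng(seed)
    if perturbation == "resize_N":
        if N1 is None:
            raise ValueError("resize_N needs N1")
        from .presets import build_fig1_sgsc
        bp = build_fig1_sgsc(N1=N1, seed=bp.seed,
                             S11=bp.meta.get("S11"))
    n_layers = len(bp.groups["graded"])

    if perturbation == "pulse_jitter_10pct":
        template, lead = _gate_template(bp, dt)
        hybrid = CircuitBlueprint(
            populations=[p for p in bp.populations
                         if p.name in bp.groups["graded"]],
            blocks=[b for b in bp.blocks
                    if b.source in bp.groups["graded"]
                    and b.target in bp.groups["graded"]],
            groups={"graded": bp.groups["graded"]},
            seed=bp.seed, meta=dict(bp.meta),
        )
        hybrid.meta.update(_gate_template=template, _gate_lead=lead,
                           _gate_dt=dt)
        net = hybrid.build()
        amps = _collect_amplitudes(hybrid, net, amplitude, trials, seed, dt,
                                   jitter_frac=0.10)
    elif perturbation in ("coupling_S11_uniform_5pct",
                          "coupling_S12_uniform_5pct"):
        which = "S11" if "S11" in perturbation else "S12"
        amps = np.zeros((trials, n_layers))
        graded_names = bp.groups["graded"]
        T0, t1 = bp.meta["T0"], bp.meta["t_first"]
        duration = t1 + (n_layers + 1.5) * T0
        wins = graded_windows(t1, T0, n_layers)
        base_net = bp.build()  # assigns block seeds once
        for k in range(trials):
            pbp = _perturbed_blueprint(
                CircuitBlueprint(populations=bp.populations,
                                 blocks=base_net.blocks, groups=bp.groups,
                                 stimuli=bp.stimuli, sinusoids=bp.sinusoids,
                                 seed=bp.seed, meta=dict(bp.meta)),
                which, rng)
            net = pbp.build()
            gi = [net.name_to_idx[nm] for nm in graded_names]
            drv = probe_drive(pbp, amplitude)
            _, tr = run(net, duration, dt=dt, drive=drv, seed=seed + 1000 + k)
            amps[k] = layer_amplitudes(tr, n_layers, gi, wins)
    else:
        net = bp.build()
        amps = _collect_amplitudes(bp, net, amplitude, trials, seed, dt)

    return TransferStats(mean=amps.mean(axis=0), std=amps.std(axis=0, ddof=1),
                         trials=trials, amplitude=amplitude,
                         fingerprint=_fingerprint(bp, {
                             "perturbation": perturbation, "seed": seed}))


def smooth_rates(record: SpikeRecord, window: float = 0.002,
                 bin_width: float = 5e-4):
    """Population firing-rate time series with a centered moving average.

    Returns ``(t, rates)`` where ``rates[pop]`` is spikes per bin divided
    by ``N * bin_width`` then smoothed over ``window``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_bins = max(int(math.ceil(record.duration / bin_width)), 1)
    edges = np.arange(n_bins + 1) * bin_width
    t = 0.5 * (edges[:-1] + edges[1:])
    k = max(int(round(window / bin_width)), 1)
    kernel = np.ones(k) / k
    rates = {}
    for i, name in enumerate(record.pop_names):
        m = record.pop_index == i
        counts, _ = np.histogram(record.time[m], bins=edges)
        N = record.pop_sizes[i] if record.pop_sizes else 1
        r = counts / (N * bin_width)
        rates[name] = np.convolve(r, kernel, mode="same")
    return t, rates


def volley_window(record: SpikeRecord, pop: str, N: int,
                  t_ref: float | None = None,
                  halfwin: float = 0.008) -> tuple[float, float]:
    """The pulse window of a volley: median +- 2 sigma of its spike times.

    Covers ~95% of a Gaussian volley, the natural "duration of the
    pulse" over which per-neuron rates are quoted.
    """
    i = record.pop_names.index(pop)
    times = record.time[record.pop_index == i]
    if times.size == 0:
        return (0.0, 0.0)
    center = np.median(times) if t_ref is None else t_ref
    sel = times[np.abs(times - center) < halfwin]
    mu, sd = float(np.median(sel)), float(np.std(sel))
    return (mu - 2 * sd, mu + 2 * sd)


def pulse_firing_rate(record: SpikeRecord, pop: str,
                      window: tuple[float, float]) -> float:
    """Mean single-neuron rate (Hz) of ``pop`` within a gating window."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty window")
    i = record.pop_names.index(pop)
    m = record.pop_index == i
    times = record.time[m]
    n_spk = int(np.sum((times >= t0) & (times < t1)))
    N = record.pop_sizes[i] if record.pop_sizes else 1
    return n_spk / (N * (t1 - t0))
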