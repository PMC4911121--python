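"""Fitting the mean-field theory to spiking transfer runs.

Produces the (eta_fit, alpha_fit) best-fitting invariant-waveform family
for trial-averaged synaptic current traces, and the (eta_sim, alpha_sim)
operating point implied by the simulational coupling, for comparison.

The mean-field rate variable is in current units (rate equals current at
the gated-linear operating point); the spiking population obeys
``tau dI/dt = -I + S11 * r`` with ``r`` in Hz, so the effective
mean-field coupling is ``S_eff = S11 * (r/I)`` with the rate-per-current
slope measured at the simulation's operating point (mid-chain peak rate
over peak current).  ``alpha_sim`` is computed from ``S_eff``.
"""

from __future__ import annotations

import numpy as np

from .analysis import probe_drive, smooth_rates
from .circuits import CircuitBlueprint, graded_windows
from .meanfield import AlphaCurve, RangeError, eta_from_alpha, fit_meanfield
from .spiking import run

__all__ = ["collect_transfer_traces", "fit_spiking_run"]


def collect_transfer_traces(bp: CircuitBlueprint, amplitudes, trials: int,
                            seed: int, dt: float = 2e-5):
    """Trial-averaged per-layer mean-current traces plus rate metadata.

    Returns a dict with the trace tensor (n_amp, n_layers-1, n_t) for
    graded layers 2..L (layer 1 carries no synaptic graded current), the
    time grid, the measured pulse offset T0, and the mid-chain
    rate-per-current slope.
    """
    net = bp.build()
    graded_names = bp.groups["graded"]
    n_layers = len(graded_names)
    T0 = bp.meta["T0"]
    t1 = bp.meta["t_first"]
    duration = t1 + (n_layers + 1.5) * T0
    gi = [net.name_to_idx[nm] for nm in graded_names]
    n_steps = int(round(duration / dt))
    acc = np.zeros((len(amplitudes), n_layers, n_steps))
    slope_samples = []
    volley_t0 = []
    wins = graded_windows(t1, T0, n_layers)
    for ai, a in enumerate(amplitudes):
        drv = probe_drive(bp, a)
        for k in range(trials):
            rec, tr = run(net, duration, dt=dt, drive=drv,
                          seed=seed + 1000 * (ai + 1) + k)
            acc[ai] += tr["graded"][gi, :]
            if ai == len(amplitudes) - 1 and k < max(trials // 2, 1):
                ts, rates = smooth_rates(rec, window=0.002, bin_width=2.5e-4)
                for j in range(3, n_layers - 1):
                    w0, w1 = wins[j]
                    # time-resolved regression of the layer's firing rate
                    # on its input current over the gated window (the
                    # thresholded-linear claim is r(t) = I(t) while gated)
                    msel = (tr["t"] >= w0) & (tr["t"] < w1)
                    cseg = np.interp(ts, tr["t"], tr["graded"][gi[j]])
                    rsel = (ts >= w0) & (ts < w1)
                    I_w = cseg[rsel]
                    r_w = rates[graded_names[j]][rsel]
                    keep = I_w > 0.2 * I_w.max() if I_w.max() > 1.0 else None
                    if keep is not None and keep.sum() >= 5:
                        slope_samples.append(
                            float(np.dot(r_w[keep], I_w[keep])
                                  / np.dot(I_w[keep], I_w[keep])))
            # measured pulse offset from the gating chain volleys
            if ai == 0 and k == 0 and "gating" in bp.groups:
                from .circuits import volley_stats
                tms = []
                for nm in bp.groups["gating"][3:11]:
                    N2 = bp.pop(nm).N
                    _, tmed, _ = volley_stats(rec, nm, N2)
                    tms.append(tmed)
                volley_t0.append(float(np.nanmean(np.diff(tms))))
    acc /= trials
    T0_meas = volley_t0[0] if volley_t0 else T0
    return {
        "traces": acc[:, 1:, :],  # layers 2..L
        "t": (np.arange(n_steps) + 1) * dt,
        "dt": dt,
        "T0": T0_meas,
        "layer2_onset": t1 + 0.5 * T0,
        "slope": float(np.median(slope_samples)) if slope_samples else 1.0,
    }


def fit_spiking_run(T0: float | None = None, trials: int = 20, seed: int = 0,
                    bp: CircuitBlueprint | None = None,
                    amplitudes=None, dt: float = 2e-5,
                    eta_grid_max: float = 6.0) -> dict:
    """End-to-end fit of the mean-field family to a spiking transfer run.

    Builds (or accepts) the graded-transfer circuit, collects
    trial-averaged traces, fits (eta_fit, alpha_fit), and computes
    (eta_sim, alpha_sim) from the effective simulational coupling.
    ``T0`` defaults to the circuit's measured pulse offset.
    """
    if bp is None:
        from .presets import build_fig1_sgsc
        bp = build_fig1_sgsc(seed=seed)
    if amplitudes is None:
        amplitudes = bp.meta.get("probe_amplitudes", [46.0, 54.0, 62.0])
    data = collect_transfer_traces(bp, amplitudes, trials, seed, dt=dt)
    T0_use = T0 if T0 is not None else data["T0"]
    tau = bp.pop(bp.groups["graded"][0]).tau

    eta_fit, alpha_fit, fitted, residual = fit_meanfield(
        data["traces"], T0=T0_use, tau=tau, dt=data["dt"],
        layer0_onset=data["layer2_onset"],
        eta_bounds=(1.05, eta_grid_max), fit_onset=True,
    )

    S11 = bp.meta.get("S11", 0.0)
    S_eff = S11 * data["slope"]
    r = T0_use / tau
    alpha_sim = S_eff * r * np.exp(-r)
    curve = AlphaCurve(r, eta_grid=np.r_[1.0, np.arange(1.05, eta_grid_max
                                                        + 1e-9, 0.05)],
                       tau=tau)
    try:
        eta_sim = eta_from_alpha(alpha_sim, r, curve=curve)
    except RangeError:
        eta_sim = float("nan")
    return {
        "eta_fit": float(eta_fit),
        "alpha_fit": float(alpha_fit),
        "eta_sim": float(eta_sim),
        "alpha_sim": float(alpha_sim),
        "T0": float(T0_use),
        "slope": data["slope"],
        "S_eff": float(S_eff),
        "residual": float(residual),
    }
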