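"""Configuration, blueprint I/O, fixtures and experiment orchestration.

Everything on disk is plain text: blueprints and configs are YAML, spike
records and traces are delimited text with headers.  Time is seconds,
currents reduced units, throughout.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .circuits import CircuitBlueprint
from .spiking import SpikeRecord, run

__all__ = [
    "ExperimentConfig",
    "load_blueprint",
    "save_blueprint",
    "make_fixture",
    "run_experiment",
    "write_spikes",
    "write_traces",
    "write_curve",
    "FIXTURES",
]

log = logging.getLogger("sgsc")

FIXTURES = ("two_layer_toy", "gating_only", "hadamard_toy", "sine_drive")


@dataclass
class ExperimentConfig:
    """A fully reproducible experiment description."""

    blueprint: str  # path or shipped-preset name
    backend: str = "spiking"  # spiking | meanfield
    duration: float = 0.06
    dt: float = 2e-5
    trials: int = 1
    seed: int = 0
    out_dir: str = "results"
    perturbation: str = "none"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def save_blueprint(bp: CircuitBlueprint, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(bp.to_dict(), sort_keys=False))


def load_blueprint(path: str | Path) -> CircuitBlueprint:
    """Load and validate a blueprint file; unknown keys are rejected."""
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"blueprint file {path} is empty")
    try:
        d = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ValueError(f"blueprint parse error in {path}: {e}") from e
    if not isinstance(d, dict):
        raise ValueError(f"blueprint file {path} does not hold a mapping")
    return CircuitBlueprint.from_dict(d)


def make_fixture(name: str, seed: int = 0):
    """Small deterministic configurations used throughout the test suite.

    Returns ``(blueprint, drive)`` where ``drive`` maps population names
    to injected-current functions (may be empty).
    """
    from .circuits import (GATING_DEFAULTS, make_gating_chain,
                           make_graded_chain, make_hadamard_block, make_sgsc)
    from .spiking import PopulationSpec

    if name == "two_layer_toy":
        graded = make_graded_chain(2, 200, S11=0.42)
        gating = make_gating_chain(2, 50, GATING_DEFAULTS["S22"])
        bp = make_sgsc(graded, gating, S12=0.8, seed=seed)
        bp.meta.update(T0=0.0035, t_first=0.0035, gate_len=0.0105,
                       name="two_layer_toy")
        drive = {"g1": lambda t: 50.0 if 0.0018 <= t < 0.012 else 0.0}
        return bp, drive
    if name == "gating_only":
        bp = make_gating_chain(12, 100, GATING_DEFAULTS["S22"])
        bp.seed = seed
        bp.meta["name"] = "gating_only"
        return bp, {}
    if name == "hadamard_toy":
        ups = [f"u{i}" for i in range(1, 5)]
        downs = [f"d{i}" for i in range(1, 9)]
        bp = CircuitBlueprint(
            populations=[PopulationSpec(nm, 1, cls="graded")
                         for nm in ups + downs],
            blocks=make_hadamard_block(ups, downs, scale=0.25, S=1.743),
            groups={"upstream": ups, "downstream": downs},
            seed=seed, meta={"name": "hadamard_toy"},
        )
        return bp, {}
    if name == "sine_drive":
        from .circuits import sinusoid_input
        bp = CircuitBlueprint(
            populations=[PopulationSpec("input", 100, cls="graded")],
            sinusoids=[sinusoid_input(62.5, 20.0, phase=0.0, onset=0.01,
                                      offset=25.0)],
            groups={"input": ["input"]},
            seed=seed, meta={"name": "sine_drive"},
        )
        return bp, {}
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")


def write_spikes(record: SpikeRecord, path: str | Path) -> None:
    """Spike record as delimited text: population, neuron, time_s."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["population", "neuron", "time_s"])
        for p, n, t in zip(record.pop_index, record.neuron, record.time):
            w.writerow([record.pop_names[p], int(n), f"{t:.6f}"])


def write_traces(t: np.ndarray, traces: dict[str, np.ndarray],
                 path: str | Path) -> None:
    """Wide delimited time series: time_s then one column per population."""
    names = list(traces)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s"] + names)
        for i, ti in enumerate(t):
            w.writerow([f"{ti:.6f}"] + [f"{traces[nm][i]:.6g}" for nm in names])


def write_curve(rows, header, path: str | Path) -> None:
    """Delimited text with header columns (e.g. eta, S_exact, alpha_exact)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow([f"{x:.6g}" if isinstance(x, float) else x for x in row])


def _resolve_blueprint(ref: str, seed: int) -> CircuitBlueprint:
    if Path(ref).exists():
        return load_blueprint(ref)
    shipped = Path(__file__).parent / "blueprints" / f"{ref}.yaml"
    if shipped.exists():
        bp = load_blueprint(shipped)
        bp.seed = seed
        return bp
    if ref in FIXTURES:
        return make_fixture(ref, seed)[0]
    if ref == "fig1_sgsc":
        from .presets import build_fig1_sgsc
        return build_fig1_sgsc(seed=seed)
    if ref == "fig4_snr":
        from .presets import build_fig4_snr
        return build_fig4_snr(seed=seed)
    if ref == "fig5_decision":
        from .decision import make_decision_circuit
        return make_decision_circuit(seed=seed)
    raise ValueError(f"cannot resolve blueprint {ref!r}")


def run_experiment(config: ExperimentConfig):
    """Run one experiment and write all artifacts to the output directory.

    Writes the config, the resolved blueprint, spikes / traces (spiking
    backend) or rate traces and a pulse log (mean-field backend), and a
    provenance manifest.  Outputs are removed if the run fails.  Reruns
    with the same config are bit-identical on the spiking backend.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wrote = []
    try:
        bp = _resolve_blueprint(config.blueprint, config.seed)
        log.info("experiment seed=%d blueprint=%s backend=%s",
                 config.seed, config.blueprint, config.backend)
        (out / "config.yaml").write_text(config.to_yaml())
        wrote.append(out / "config.yaml")
        save_blueprint(bp, out / "blueprint.yaml")
        wrote.append(out / "blueprint.yaml")
        if config.backend == "spiking":
            if config.blueprint == "fig5_decision":
                from .decision import translate_to_spiking
                bp = translate_to_spiking(bp, seed=config.seed)
            net = bp.build(seed=config.seed)
            record, traces = run(net, config.duration, dt=config.dt,
                                 drive=bp.drive_functions(), seed=config.seed)
            write_spikes(record, out / "spikes.csv")
            wrote.append(out / "spikes.csv")
            cols = {nm: traces["graded"][i]
                    for i, nm in enumerate(record.pop_names)}
            write_traces(traces["t"], cols, out / "mean_currents.csv")
            wrote.append(out / "mean_currents.csv")
            summary = {"spikes": len(record), "counts": record.counts()}
        elif config.backend == "meanfield":
            from .ratenet import simulate_blueprint_rates
            rr = simulate_blueprint_rates(bp, config.duration)
            cols = {nm: rr.currents[i] for i, nm in enumerate(rr.pop_names)}
            write_traces(rr.t, cols, out / "rate_currents.csv")
            wrote.append(out / "rate_currents.csv")
            events = {nm: ts for nm, ts in rr.pulses.items() if ts}
            (out / "events.json").write_text(json.dumps(events, indent=1))
            wrote.append(out / "events.json")
            summary = {"pulses": {k: len(v) for k, v in events.items()}}
        else:
            raise ValueError(f"unknown backend {config.backend!r}")
        manifest = {
            "config": asdict(config),
            "blueprint_name": bp.meta.get("name", config.blueprint),
            "summary": summary,
            "package": "sgsc 0.1.0",
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out
    except Exception:
        for p in wrote:
            try:
                p.unlink()
            except OSError:
                pass
        raise
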