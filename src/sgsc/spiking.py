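"""Current-based integrate-and-fire network simulator.

Layered populations with IID Bernoulli random connectivity, delta-function
synapses filtered through a single exponential timescale, independent
per-neuron Poisson background input, hard threshold / reset, and a
one-step spike delivery latency.

Reduced units: time in seconds, ``V_thres - V_leak = 1``, currents
dimensionless.  Membrane dynamics (forward Euler)::

    dv/dt = -g_leak (v - V_leak) + I_graded + I_gating + I_bg + drive

Each presynaptic spike delivered through the realized adjacency increments
the target's synaptic current by ``S * K / (p * N_src * tau)`` (division
by the *expected* in-degree, so currents are O(1) in the population size);
each background Poisson event increments the background current by
``f / tau``.  Synaptic and background currents decay exponentially with
``tau`` between events.

The whole state trajectory is a pure function of (network, seed, drive,
dt); identical inputs give bit-identical spike records.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


__all__ = [
    "PopulationSpec",
    "ConnectivityBlock",
    "Network",
    "SpikeRecord",
    "BlueprintError",
    "IntegrationError",
    "build_network",
    "run",
    "GRADED",
    "GATING",
    "AUXILIARY",
]

GRADED, GATING, AUXILIARY = 0, 1, 2
_CLASS_NAMES = {"graded": GRADED, "gating": GATING, "auxiliary": AUXILIARY}


class BlueprintError(ValueError):
    """A block references an unknown population or is malformed."""


class IntegrationError(RuntimeError):
    """Non-finite state or recording overflow during simulation."""


@dataclass(frozen=True)
class PopulationSpec:
    """One homogeneous neuron population (a single layer)."""

    name: str
    N: int
    cls: str = "graded"  # graded | gating | auxiliary
    g_leak: float = 50.0
    V_leak: float = 0.0
    V_thres: float = 1.0
    tau: float = 0.005
    f: float = 0.0  # background strength (current * s per event)
    nu: float = 0.0  # background rate (events / s)
    t_ref: float = 0.0  # absolute refractory period (s); v clamped at reset

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N >= 1 required")
        if self.V_thres <= self.V_leak:
            raise ValueError("V_thres must exceed V_leak")
        if self.g_leak <= 0 or self.tau <= 0:
            raise ValueError("g_leak and tau must be positive")
        if self.f < 0 or self.nu < 0:
            raise ValueError("f and nu must be nonnegative")
        if self.t_ref < 0:
            raise ValueError("t_ref must be nonnegative")
        if self.cls not in _CLASS_NAMES:
            raise ValueError(f"unknown population class {self.cls!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name, "N": self.N, "cls": self.cls,
            "g_leak": self.g_leak, "V_leak": self.V_leak,
            "V_thres": self.V_thres, "tau": self.tau,
            "f": self.f, "nu": self.nu, "t_ref": self.t_ref,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationSpec":
        return cls(**{k: d[k] for k in (
            "name", "N", "cls", "g_leak", "V_leak", "V_thres", "tau", "f",
            "nu", "t_ref",
        ) if k in d})


@dataclass
class ConnectivityBlock:
    """A synaptic block between two populations.

    Per-spike increment to each connected target neuron is
    ``S * K / (p * N_src * tau)``; ``K`` may be negative (inhibition).
    """

    source: str
    target: str
    S: float
    p: float = 1.0
    K: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("connection probability must be in [0, 1]")

    def realize(self, n_src: int, n_tgt: int) -> np.ndarray:
        """IID Bernoulli(p) adjacency; same seed -> bit-identical matrix."""
        if self.seed is None:
            raise ValueError("block seed not assigned; build the network first")
        rng = np.random.default_rng(self.seed)
        if self.p >= 1.0:
            return np.ones((n_src, n_tgt), dtype=bool)
        if self.p <= 0.0:
            return np.zeros((n_src, n_tgt), dtype=bool)
        return rng.random((n_src, n_tgt)) < self.p

    def to_dict(self) -> dict:
        return {"source": self.source, "target": self.target, "S": self.S,
                "p": self.p, "K": self.K}


@dataclass
class SpikeRecord:
    """Immutable spike output: parallel arrays (population, neuron, time)."""

    pop_names: list[str]
    pop_index: np.ndarray  # int32, index into pop_names
    neuron: np.ndarray  # int32, local index within population
    time: np.ndarray  # float64, seconds
    duration: float
    pop_sizes: list[int] = field(default_factory=list)
    background: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def for_population(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(neuron, time) arrays for one population."""
        i = self.pop_names.index(name)
        m = self.pop_index == i
        return self.neuron[m], self.time[m]

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.pop_index == i))
            for i, name in enumerate(self.pop_names)
        }

    def __len__(self) -> int:
        return self.time.size


class Network:
    """Realized network: populations plus frozen adjacency matrices."""

    def __init__(self, populations: Sequence[PopulationSpec],
                 blocks: Sequence[ConnectivityBlock], seed: int):
        self.populations = list(populations)
        self.blocks = list(blocks)
        self.seed = seed
        self.name_to_idx = {p.name: i for i, p in enumerate(self.populations)}
        if len(self.name_to_idx) != len(self.populations):
            raise BlueprintError("duplicate population names")
        for b in self.blocks:
            if b.source not in self.name_to_idx or b.target not in self.name_to_idx:
                raise BlueprintError(
                    f"block {b.source}->{b.target} references unknown population"
                )
        self.n_pops = len(self.populations)
        self.offsets = np.zeros(self.n_pops + 1, dtype=np.int64)
        for i, p in enumerate(self.populations):
            self.offsets[i + 1] = self.offsets[i] + p.N
        self.n_total = int(self.offsets[-1])
        # assign per-block adjacency seeds deterministically from the master
        ss = np.random.SeedSequence(seed)
        child = ss.spawn(len(self.blocks) + 1)
        for b, s in zip(self.blocks, child[:-1]):
            if b.seed is None:
                b.seed = int(s.generate_state(1)[0])
        self._bg_seed_root = child[-1]
        self.adjacency = {}
        for bi, b in enumerate(self.blocks):
            ns = self.populations[self.name_to_idx[b.source]].N
            nt = self.populations[self.name_to_idx[b.target]].N
            self.adjacency[bi] = b.realize(ns, nt)
        self._flat = None

    def block_weight(self, b: ConnectivityBlock) -> float:
        n_src = self.populations[self.name_to_idx[b.source]].N
        tau = self.populations[self.name_to_idx[b.target]].tau
        return b.S * b.K / (b.p * n_src * tau) if b.p > 0 else 0.0

    def flat(self):
        """Flattened CSR arrays for the simulation kernel (cached)."""
        if self._flat is not None:
            return self._flat
        n_blocks = len(self.blocks)
        blk_w = np.zeros(n_blocks)
        blk_cls = np.zeros(n_blocks, dtype=np.int32)
        indptr_chunks, col_chunks = [], []
        blk_row_start = np.zeros(n_blocks + 1, dtype=np.int64)
        blk_col_start = np.zeros(n_blocks + 1, dtype=np.int64)
        row_total = 0
        col_total = 0
        blocks_of_src = [[] for _ in range(self.n_pops)]
        for bi, b in enumerate(self.blocks):
            si = self.name_to_idx[b.source]
            ti = self.name_to_idx[b.target]
            blocks_of_src[si].append(bi)
            blk_w[bi] = self.block_weight(b)
            src_cls = self.populations[si].cls
            blk_cls[bi] = GATING if src_cls == "gating" else GRADED
            A = self.adjacency[bi]
            counts = A.sum(axis=1).astype(np.int64)
            iptr = np.zeros(A.shape[0] + 1, dtype=np.int64)
            np.cumsum(counts, out=iptr[1:])
            cols = (np.nonzero(A)[1] + self.offsets[ti]).astype(np.int64)
            blk_row_start[bi] = row_total
            blk_col_start[bi] = col_total
            indptr_chunks.append(iptr)
            col_chunks.append(cols)
            row_total += A.shape[0] + 1
            col_total += cols.size
        blk_row_start[n_blocks] = row_total
        blk_col_start[n_blocks] = col_total
        indptr_all = (np.concatenate(indptr_chunks) if indptr_chunks
                      else np.zeros(0, dtype=np.int64))
        cols_all = (np.concatenate(col_chunks) if col_chunks
                    else np.zeros(0, dtype=np.int64))
        sb_ptr = np.zeros(self.n_pops + 1, dtype=np.int64)
        sb_idx = []
        for s in range(self.n_pops):
            sb_ptr[s + 1] = sb_ptr[s] + len(blocks_of_src[s])
            sb_idx.extend(blocks_of_src[s])
        self._flat = dict(
            blk_w=blk_w, blk_cls=blk_cls,
            blk_row_start=blk_row_start, blk_col_start=blk_col_start,
            indptr_all=indptr_all, cols_all=cols_all,
            sb_ptr=sb_ptr, sb_idx=np.array(sb_idx, dtype=np.int64),
        )
        return self._flat


def build_network(populations: Sequence[PopulationSpec],
                  blocks: Sequence[ConnectivityBlock], seed: int) -> Network:
    """Realize adjacency and derive per-stream RNG seeds from ``seed``."""
    # copy block specs so the caller's objects keep seed=None
    blocks = [replace(b) for b in blocks]
    return Network(populations, blocks, seed)


@njit(cache=True)
def _kernel(n_steps, dt, offsets, p_gleak, p_vleak, p_vthres, p_tau,
            p_f, p_nu, p_tref, pop_of, v, I_g, I_s, I_b,
            blk_w, blk_cls, blk_row_start, blk_col_start, indptr_all, cols_all,
            sb_ptr, sb_idx, drive, bg_seed,
            rec_gid, rec_t, rec_Ig, rec_Is, rec_Ib, record_currents,
            rec_bg_gid, rec_bg_t, record_bg):
    n_pops = offsets.size - 1
    n_total = v.size
    np.random.seed(bg_seed)
    decay = np.empty(n_pops)
    for s in range(n_pops):
        decay[s] = math.exp(-dt / p_tau[s])
    pending = np.empty(n_total, dtype=np.int64)
    refr_until = np.full(n_total, -1.0)
    n_pending = 0
    n_rec = 0
    n_bg = 0
    cap = rec_gid.size
    bg_cap = rec_bg_gid.size
    status = 0
    for k in range(n_steps):
        # 1) deliver last step's spikes through the adjacency
        for q in range(n_pending):
            gid = pending[q]
            s = pop_of[gid]
            loc = gid - offsets[s]
            for bj in range(sb_ptr[s], sb_ptr[s + 1]):
                bi = sb_idx[bj]
                w = blk_w[bi]
                if w == 0.0:
                    continue
                base = blk_row_start[bi] + loc
                cbase = blk_col_start[bi]
                lo = indptr_all[base] + cbase
                hi = indptr_all[base + 1] + cbase
                if blk_cls[bi] == 1:
                    for c in range(lo, hi):
                        I_s[cols_all[c]] += w
                else:
                    for c in range(lo, hi):
                        I_g[cols_all[c]] += w
        n_pending = 0
        # 2) background Poisson events
        for s in range(n_pops):
            lam = p_nu[s] * dt
            if lam <= 0.0:
                continue
            inc = p_f[s] / p_tau[s]
            for gid in range(offsets[s], offsets[s + 1]):
                c = np.random.poisson(lam)
                if c > 0:
                    I_b[gid] += c * inc
                    if record_bg and n_bg < bg_cap:
                        rec_bg_gid[n_bg] = gid
                        rec_bg_t[n_bg] = k * dt
                        n_bg += 1
        # 3) membrane update + threshold / reset
        t_spk = (k + 1) * dt
        for s in range(n_pops):
            gl = p_gleak[s]
            vl = p_vleak[s]
            vt = p_vthres[s]
            for gid in range(offsets[s], offsets[s + 1]):
                if t_spk <= refr_until[gid]:
                    v[gid] = vl  # clamped at reset while refractory
                    continue
                vv = v[gid] + dt * (-gl * (v[gid] - vl)
                                    + I_g[gid] + I_s[gid] + I_b[gid]
                                    + drive[s, k])
                if vv >= vt:
                    vv = vl
                    refr_until[gid] = t_spk + p_tref[s]
                    pending[n_pending] = gid
                    n_pending += 1
                    if n_rec < cap:
                        rec_gid[n_rec] = gid
                        rec_t[n_rec] = t_spk
                        n_rec += 1
                    else:
                        status = 2
                v[gid] = vv
        # 4) exponential current decay, per-population mean recording
        for s in range(n_pops):
            d = decay[s]
            acc_g = 0.0
            acc_s = 0.0
            acc_b = 0.0
            for gid in range(offsets[s], offsets[s + 1]):
                I_g[gid] *= d
                I_s[gid] *= d
                I_b[gid] *= d
                acc_g += I_g[gid]
                acc_s += I_s[gid]
                acc_b += I_b[gid]
            if record_currents:
                n_s = offsets[s + 1] - offsets[s]
                rec_Ig[s, k] = acc_g / n_s
                rec_Is[s, k] = acc_s / n_s
                rec_Ib[s, k] = acc_b / n_s
        if status == 2:
            break
    # finite-state check
    for gid in range(n_total):
        if not (math.isfinite(v[gid]) and math.isfinite(I_g[gid])
                and math.isfinite(I_s[gid]) and math.isfinite(I_b[gid])):
            status = 1
            break
    return n_rec, n_bg, status


def run(network: Network, duration: float, dt: float = 2e-5,
        drive: Mapping[str, Callable[[float], float]] | np.ndarray | None = None,
        seed: int | None = None, record_currents: bool = True,
        record_background: bool = False, spike_capacity: int | None = None):
    """Simulate the network; returns ``(SpikeRecord, traces)``.

    ``drive`` maps population names to injected-current functions of time
    (uniform across the population's neurons), or is a precomputed
    (n_pops, n_steps) array.  ``traces`` is a dict with keys ``t``,
    ``graded``, ``gating`` (per-population mean synaptic currents by
    source class, shape (n_pops, n_steps)); empty when
    ``record_currents`` is false.
    """
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    min_tau = min(p.tau for p in network.populations)
    if dt > min_tau / 10.0:
        warnings.warn("dt exceeds tau/10; integration may be inaccurate",
                      stacklevel=2)
    n_steps = int(round(duration / dt))
    n_pops = network.n_pops
    pop_names = [p.name for p in network.populations]
    if n_steps == 0:
        empty = np.zeros(0)
        rec = SpikeRecord(pop_names, empty.astype(np.int32),
                          empty.astype(np.int32), empty, 0.0,
                          [p.N for p in network.populations])
        z = np.zeros((n_pops, 0))
        return rec, {"t": empty, "graded": z, "gating": z, "background": z}

    drive_mat = np.zeros((n_pops, n_steps))
    if isinstance(drive, np.ndarray):
        if drive.shape != (n_pops, n_steps):
            raise ValueError("drive array must have shape (n_pops, n_steps)")
        drive_mat = np.ascontiguousarray(drive, dtype=np.float64)
    elif drive:
        tgrid = np.arange(n_steps) * dt
        for name, fn in drive.items():
            i = network.name_to_idx[name]
            drive_mat[i] = np.array([fn(t) for t in tgrid], dtype=float)

    p_gleak = np.array([p.g_leak for p in network.populations])
    p_vleak = np.array([p.V_leak for p in network.populations])
    p_vthres = np.array([p.V_thres for p in network.populations])
    p_tau = np.array([p.tau for p in network.populations])
    p_f = np.array([p.f for p in network.populations])
    p_nu = np.array([p.nu for p in network.populations])
    p_tref = np.array([p.t_ref for p in network.populations])
    pop_of = np.repeat(np.arange(n_pops, dtype=np.int64),
                       [p.N for p in network.populations])

    v = p_vleak[pop_of].copy()
    I_g = np.zeros(network.n_total)
    I_s = np.zeros(network.n_total)
    I_b = np.zeros(network.n_total)

    if seed is None:
        seed = network.seed
    bg_seed = int(
        np.random.SeedSequence([network.seed, seed]).generate_state(1)[0]
        % (2**31 - 1)
    )

    if spike_capacity is None:
        # generous default: ~2 spikes per neuron per 10 ms, floor of 1e6
        spike_capacity = max(int(network.n_total * duration * 200), 1_000_000)
    rec_gid = np.zeros(spike_capacity, dtype=np.int64)
    rec_t = np.zeros(spike_capacity)
    rec_Ig = np.zeros((n_pops, n_steps))
    rec_Is = np.zeros((n_pops, n_steps))
    rec_Ib = np.zeros((n_pops, n_steps))
    bg_cap = spike_capacity if record_background else 1
    rec_bg_gid = np.zeros(bg_cap, dtype=np.int64)
    rec_bg_t = np.zeros(bg_cap)

    flat = network.flat()
    n_rec, n_bg, status = _kernel(
        n_steps, dt, network.offsets, p_gleak, p_vleak, p_vthres, p_tau,
        p_f, p_nu, p_tref, pop_of, v, I_g, I_s, I_b,
        flat["blk_w"], flat["blk_cls"], flat["blk_row_start"],
        flat["blk_col_start"], flat["indptr_all"], flat["cols_all"],
        flat["sb_ptr"], flat["sb_idx"], drive_mat, bg_seed,
        rec_gid, rec_t, rec_Ig, rec_Is, rec_Ib, record_currents,
        rec_bg_gid, rec_bg_t, record_background,
    )
    if status == 1:
        raise IntegrationError("non-finite state encountered")
    if status == 2:
        raise IntegrationError("spike record capacity exceeded")

    gid = rec_gid[:n_rec]
    pop_idx = pop_of[gid].astype(np.int32)
    neuron = (gid - network.offsets[pop_idx]).astype(np.int32)
    bg = None
    if record_background:
        bgid = rec_bg_gid[:n_bg]
        bg = (pop_of[bgid].astype(np.int32),
              (bgid - network.offsets[pop_of[bgid]]).astype(np.int32),
              rec_bg_t[:n_bg].copy())
    record = SpikeRecord(pop_names, pop_idx, neuron, rec_t[:n_rec].copy(),
                         duration, [p.N for p in network.populations], bg)
    traces = {"t": (np.arange(n_steps) + 1) * dt, "graded": rec_Ig,
              "gating": rec_Is, "background": rec_Ib}
    if not record_currents:
        z = np.zeros((n_pops, 0))
        traces = {"t": traces["t"], "graded": z, "gating": z, "background": z}
    return record, traces
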