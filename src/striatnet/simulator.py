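"""Reduced-biophysics network simulator.

Each cell is a passive multicompartment cable on its morphology
scaffold with a leaky-integrate-and-fire surrogate at the soma; the
full ionic-channel complement of the detailed single-cell models is
deliberately not reproduced.  Synapses are two-state (difference of
exponentials) conductances: AMPA/NMDA glutamatergic pairs and GABA-A
with a -60 mV reversal.  Presynaptic spikes are delivered event-wise to
their contact compartments after the axonal delay (2.4 ms for lateral
and feedforward connections), and lateral / feedforward inhibition can
be toggled off without changing anything else, enabling exact paired
ON/OFF subtraction protocols.

Numerics: backward-Euler integration of each cable tree via a
Hines-style O(n) tree solve, vectorized over cells and JIT-compiled
with numba.  Conductances are treated as piecewise constant over a
step; events are quantized to the step grid.  Default dt is 0.1 ms for
network runs and 0.025 ms for IPSP studies.

Units: mV, ms, nS, pF, pA, um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .morphology import BranchOrder, MorphologyScaffold, build_msn_scaffold, build_fsi_scaffold
from .netbuild import Network, KIND_LATERAL, KIND_FEEDFORWARD

__all__ = [
    "SynapseParams",
    "default_synapses",
    "synapse_conductance",
    "synapse_peak_time",
    "CellDynamics",
    "SimConfig",
    "StimSet",
    "RasterSet",
    "TraceSet",
    "SimResult",
    "step_cell",
    "run_network",
    "paired_ipsp_run",
    "PairedRun",
]

# fixed kind order used by the state arrays
KIND_INDEX = {"AMPA": 0, "NMDA": 1, "GABA_A": 2}
N_KINDS = 3


@dataclass(frozen=True)
class SynapseParams:
    """Two-state conductance synapse, peak-normalized to ``g_max``."""

    kind: str
    g_max: float  # nS per contact
    e_rev: float  # mV
    tau_rise: float  # ms
    tau_decay: float  # ms

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")

    @property
    def norm(self) -> float:
        """Scale factor making the conductance peak equal g_max."""
        tp = synapse_peak_time(self.tau_rise, self.tau_decay)
        return 1.0 / (math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))


def synapse_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the conductance maximum for a difference of exponentials."""
    return math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def synapse_conductance(t_since_event, params: SynapseParams):
    """g(t) = g_max * N * (exp(-t/tau_decay) - exp(-t/tau_rise)), t >= 0."""
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_event must be non-negative")
    g = params.g_max * params.norm * (
        np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise)
    )
    return g if g.ndim else float(g)


def default_synapses(
    g_ampa: float = 0.58,
    g_nmda: float = 0.03,
    g_gaba: float = 0.45,
) -> dict[str, SynapseParams]:
    """Default synapse kinetics.

    Time constants follow typical striatal values (fast AMPA, slow
    NMDA tail, GABA-A decay of a few ms); per-contact conductances are
    calibration choices of the reduced tier.  Lateral and feedforward
    contacts share one GABA-A conductance.
    """
    return {
        "AMPA": SynapseParams("AMPA", g_ampa, 0.0, 0.5, 2.5),
        "NMDA": SynapseParams("NMDA", g_nmda, 0.0, 2.0, 80.0),
        "GABA_A": SynapseParams("GABA_A", g_gaba, -60.0, 0.5, 7.5),
    }


# ---------------------------------------------------------------------------
# cell dynamics
# ---------------------------------------------------------------------------

@dataclass
class CellDynamics:
    """Passive cable parameters plus the spiking-soma surrogate.

    Membrane: specific capacitance ``cm`` (uF/cm^2), resistance ``rm``
    (ohm cm^2), axial resistivity ``ra`` (ohm cm).  ``spine_scale``
    multiplies dendritic membrane area (capacitance and leak) on
    secondary/tertiary branches to account for unmodeled spines.
    """

    scaffold: MorphologyScaffold
    parent: np.ndarray  # (ncomp,), -1 at soma
    C: np.ndarray  # pF per compartment
    gL: np.ndarray  # nS per compartment
    g_ax: np.ndarray  # nS coupling to parent; 0 at soma
    e_leak: float
    v_thresh: float
    v_reset: float
    t_ref: float  # ms

    @property
    def n_comp(self) -> int:
        return len(self.C)

    @classmethod
    def from_scaffold(
        cls,
        scaffold: MorphologyScaffold,
        cm: float = 1.0,
        rm: float = 20000.0,
        ra: float = 100.0,
        e_leak: float = -80.0,
        v_thresh: float = -45.0,
        v_reset: float = -55.0,
        t_ref: float = 2.0,
        spine_scale: float = 1.0,
    ) -> "CellDynamics":
        comps = scaffold.compartments
        n = len(comps)
        parent = scaffold.parent_index()
        area = np.array([math.pi * c.diameter * c.length for c in comps])  # um^2
        spiny = np.array(
            [c.branch_order in (BranchOrder.SECONDARY, BranchOrder.TERTIARY) for c in comps]
        )
        area = np.where(spiny, area * spine_scale, area)
        C = 0.01 * cm * area  # pF
        gL = area * 10.0 / rm  # nS
        ra_um = ra * 1e4  # ohm um
        half_r = np.array(
            [ra_um * (c.length / 2.0) / (math.pi * (c.diameter / 2.0) ** 2) for c in comps]
        )  # ohm, half-compartment axial resistance
        g_ax = np.zeros(n)
        for i in range(1, n):
            g_ax[i] = 1e9 / (half_r[i] + half_r[parent[i]])  # nS
        return cls(scaffold, parent, C, gL, g_ax, e_leak, v_thresh, v_reset, t_ref)

    @classmethod
    def msn_default(cls, scaffold: MorphologyScaffold | None = None, **over) -> "CellDynamics":
        kw = dict(e_leak=-80.0, v_thresh=-45.0, v_reset=-55.0, t_ref=2.0, spine_scale=2.0)
        kw.update(over)
        return cls.from_scaffold(scaffold or build_msn_scaffold(), **kw)

    @classmethod
    def fsi_default(cls, scaffold: MorphologyScaffold | None = None, **over) -> "CellDynamics":
        kw = dict(e_leak=-70.0, v_thresh=-50.0, v_reset=-62.0, t_ref=1.2, spine_scale=1.0)
        kw.update(over)
        return cls.from_scaffold(scaffold or build_fsi_scaffold(), **kw)

    def static_diagonal(self, dt: float) -> np.ndarray:
        """C/dt + gL + axial couplings; the voltage-independent part of
        the backward-Euler system diagonal."""
        D0 = self.C / dt + self.gL + self.g_ax
        for i in range(1, self.n_comp):
            D0[self.parent[i]] += self.g_ax[i]
        return D0


# ---------------------------------------------------------------------------
# numba kernel (pure-numpy fallback kept for environments without a JIT)
# ---------------------------------------------------------------------------

def _step_kernel_py(V, Sd, Sr, fd, fr, Ek, Cdt, gL, EL, D0, g_ax, parent, bias, D, b):
    nk = Sd.shape[0]
    gtot = np.zeros_like(V)
    gE = np.zeros_like(V)
    for k in range(nk):
        g = np.maximum(Sd[k] - Sr[k], 0.0)
        gtot += g
        gE += g * Ek[k]
    D[:] = D0[None, :] + gtot
    b[:] = Cdt[None, :] * V + gL[None, :] * EL + gE
    b[:, 0] += bias
    ncomp = V.shape[1]
    for i in range(ncomp - 1, 0, -1):
        p = parent[i]
        f = g_ax[i] / D[:, i]
        D[:, p] -= f * g_ax[i]
        b[:, p] += f * b[:, i]
    V[:, 0] = b[:, 0] / D[:, 0]
    for i in range(1, ncomp):
        p = parent[i]
        V[:, i] = (b[:, i] + g_ax[i] * V[:, p]) / D[:, i]
    for k in range(nk):
        Sd[k] *= fd[k]
        Sr[k] *= fr[k]


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _step_kernel_jit(V, Sd, Sr, fd, fr, Ek, Cdt, gL, EL, D0, g_ax, parent, bias, D, b):
        ncells, ncomp = V.shape
        nk = Sd.shape[0]
        for c in range(ncells):
            for i in range(ncomp):
                gtot = 0.0
                gE = 0.0
                for k in range(nk):
                    g = Sd[k, c, i] - Sr[k, c, i]
                    if g < 0.0:
                        g = 0.0
                    gtot += g
                    gE += g * Ek[k]
                D[c, i] = D0[i] + gtot
                b[c, i] = Cdt[i] * V[c, i] + gL[i] * EL + gE
            b[c, 0] += bias[c]
            for i in range(ncomp - 1, 0, -1):
                p = parent[i]
                f = g_ax[i] / D[c, i]
                D[c, p] -= f * g_ax[i]
                b[c, p] += f * b[c, i]
            V[c, 0] = b[c, 0] / D[c, 0]
            for i in range(1, ncomp):
                p = parent[i]
                V[c, i] = (b[c, i] + g_ax[i] * V[c, p]) / D[c, i]
        for k in range(nk):
            for c in range(ncells):
                for i in range(ncomp):
                    Sd[k, c, i] *= fd[k]
                    Sr[k, c, i] *= fr[k]

    _step_kernel = _step_kernel_jit
except ImportError:  # pragma: no cover
    _step_kernel = _step_kernel_py


# ---------------------------------------------------------------------------
# stimulation and results containers
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    duration: float  # ms
    dt: float = 0.1  # ms
    lateral_on: bool = True
    feedforward_on: bool = True
    record_msn: Sequence[int] | str = ()  # compartment-0 (soma) traces; "all" or ids
    record_fsi: Sequence[int] | str = ()
    record_events: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")


class StimSet:
    """External drive: per-synapse spike trains plus soma bias currents."""

    def __init__(self) -> None:
        self._events: dict[str, list] = {"msn": [], "fsi": []}
        self._bias: dict[str, dict[int, float]] = {"msn": {}, "fsi": {}}

    def add_train(self, pop: str, cell: int, comp: int, kind: str, times, weight: float) -> None:
        """Attach a presynaptic spike train (ms) to one synaptic contact."""
        if kind not in KIND_INDEX:
            raise ValueError(f"unknown synapse kind {kind!r}")
        t = np.asarray(getattr(times, "times", times), dtype=float)
        self._events[pop].append((int(cell), int(comp), kind, t, float(weight)))

    def add_bias(self, pop: str, cell: int, current_pA: float) -> None:
        """Constant current injected at the soma (holding/driving current)."""
        self._bias[pop][int(cell)] = self._bias[pop].get(int(cell), 0.0) + current_pA

    def bias_vector(self, pop: str, n_cells: int) -> np.ndarray:
        out = np.zeros(n_cells)
        for cell, val in self._bias[pop].items():
            if cell >= n_cells:
                raise ValueError(f"bias for {pop} cell {cell} but population has {n_cells}")
            out[cell] = val
        return out

    def compile(self, pop: str, n_cells: int, n_comp: int, dt: float, norms: np.ndarray):
        """Flatten events to (bin, kind, flat_index, weight) sorted by bin."""
        bins, kinds, flats, ws = [], [], [], []
        for cell, comp, kind, t, w in self._events[pop]:
            if cell >= n_cells or comp >= n_comp:
                raise ValueError(f"stim targets {pop} cell {cell} comp {comp}: out of range")
            k = KIND_INDEX[kind]
            b = np.rint(t / dt).astype(np.int64)
            bins.append(b)
            kinds.append(np.full(b.shape, k, np.int64))
            flats.append(np.full(b.shape, cell * n_comp + comp, np.int64))
            ws.append(np.full(b.shape, w * norms[k]))
        if not bins:
            z = np.empty(0, np.int64)
            return z, z.copy(), z.copy(), np.empty(0)
        bins = np.concatenate(bins)
        order = np.argsort(bins, kind="stable")
        return (
            bins[order],
            np.concatenate(kinds)[order],
            np.concatenate(flats)[order],
            np.concatenate(ws)[order],
        )


class RasterSet:
    """Output spike times per population."""

    def __init__(self, spikes: dict[str, tuple[np.ndarray, np.ndarray]], duration: float,
                 n_cells: dict[str, int]) -> None:
        self.spikes = spikes  # pop -> (cells, times) sorted by time
        self.duration = duration
        self.n_cells = n_cells

    def cells_times(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        return self.spikes[pop]

    def per_cell(self, pop: str) -> list[np.ndarray]:
        cells, times = self.spikes[pop]
        out = [times[cells == c] for c in range(self.n_cells[pop])]
        return out

    def total(self, pop: str) -> int:
        return len(self.spikes[pop][1])


class TraceSet:
    """Somatic voltage traces at dt resolution, including t = 0."""

    def __init__(self, times: np.ndarray, data: dict[str, tuple[np.ndarray, np.ndarray]]) -> None:
        self.times = times
        self.data = data  # pop -> (ids, array (n_ids, n_samples))

    def trace(self, pop: str, cell: int) -> np.ndarray:
        ids, arr = self.data[pop]
        idx = np.nonzero(ids == cell)[0]
        if len(idx) == 0:
            raise KeyError(f"{pop} cell {cell} was not recorded")
        return arr[idx[0]]


@dataclass
class SimResult:
    raster: RasterSet
    traces: TraceSet
    config: SimConfig
    event_log: list = field(default_factory=list)  # (time_ms, source_pop, source_cell)


# ---------------------------------------------------------------------------
# single-cell stepping (exposed for tests / tiny studies)
# ---------------------------------------------------------------------------

def step_cell(
    dyn: CellDynamics,
    V: np.ndarray,
    dt: float,
    g_syn: np.ndarray | None = None,
    e_syn: float = 0.0,
    bias_pA: float = 0.0,
) -> tuple[np.ndarray, bool]:
    """One backward-Euler step of a single cell.

    ``g_syn`` is an optional per-compartment conductance (nS) with common
    reversal ``e_syn``.  Returns the new voltage vector and a spike flag
    (threshold crossing at the soma; caller handles reset bookkeeping
    when driving the cell manually).
    """
    V = np.asarray(V, dtype=float).reshape(1, -1).copy()
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite membrane state")
    n = dyn.n_comp
    Sd = np.zeros((1, 1, n))
    Sr = np.zeros((1, 1, n))
    if g_syn is not None:
        Sd[0, 0, :] = np.asarray(g_syn, dtype=float)
    D = np.empty_like(V)
    b = np.empty_like(V)
    bias = np.array([bias_pA])
    _step_kernel_py(
        V, Sd, Sr, np.ones(1), np.ones(1), np.array([e_syn]),
        dyn.C / dt, dyn.gL, dyn.e_leak, dyn.static_diagonal(dt),
        dyn.g_ax, dyn.parent, bias, D, b,
    )
    spiked = bool(V[0, 0] >= dyn.v_thresh)
    if spiked:
        V[0, 0] = dyn.v_reset
    return V[0], spiked


# ---------------------------------------------------------------------------
# network simulation
# ---------------------------------------------------------------------------

class _Population:
    def __init__(self, name: str, dyn: CellDynamics, n_cells: int, dt: float,
                 syn: dict[str, SynapseParams]) -> None:
        self.name = name
        self.dyn = dyn
        self.n_cells = n_cells
        self.n_comp = dyn.n_comp
        self.V = np.full((n_cells, self.n_comp), dyn.e_leak)
        self.Sd = np.zeros((N_KINDS, n_cells, self.n_comp))
        self.Sr = np.zeros((N_KINDS, n_cells, self.n_comp))
        self.D = np.empty_like(self.V)
        self.b = np.empty_like(self.V)
        self.kinds = [None] * N_KINDS
        for kind, p in syn.items():
            self.kinds[KIND_INDEX[kind]] = p
        self.fd = np.array([math.exp(-dt / p.tau_decay) for p in self.kinds])
        self.fr = np.array([math.exp(-dt / p.tau_rise) for p in self.kinds])
        self.Ek = np.array([p.e_rev for p in self.kinds])
        self.norms = np.array([p.norm for p in self.kinds])
        self.Cdt = dyn.C / dt
        self.D0 = dyn.static_diagonal(dt)
        self.bias = np.zeros(n_cells)
        self.ref_until = np.full(n_cells, -np.inf)
        self.spike_cells: list[int] = []
        self.spike_times: list[float] = []

    def add_events(self, kind_idx: np.ndarray, flat: np.ndarray, w: np.ndarray) -> None:
        for k in range(N_KINDS):
            m = kind_idx == k
            if np.any(m):
                np.add.at(self.Sd[k].reshape(-1), flat[m], w[m])
                np.add.at(self.Sr[k].reshape(-1), flat[m], w[m])

    def step(self, t_next: float) -> np.ndarray:
        _step_kernel(
            self.V, self.Sd, self.Sr, self.fd, self.fr, self.Ek,
            self.Cdt, self.dyn.gL, self.dyn.e_leak, self.D0,
            self.dyn.g_ax, self.dyn.parent, self.bias, self.D, self.b,
        )
        refractory = t_next < self.ref_until
        self.V[refractory, 0] = self.dyn.v_reset
        spiking = np.nonzero((self.V[:, 0] >= self.dyn.v_thresh) & ~refractory)[0]
        if len(spiking):
            self.V[spiking, 0] = self.dyn.v_reset
            self.ref_until[spiking] = t_next + self.dyn.t_ref
            self.spike_cells.extend(int(c) for c in spiking)
            self.spike_times.extend(t_next for _ in spiking)
        return spiking


def _recurrent_csr(network: Network, kind: str, n_sources: int, n_comp: int,
                   gaba_weight: float, norm_gaba: float):
    """CSR source -> flattened (target_cell, comp) contact arrays."""
    sub = network.connections.select(kind)
    counts = sub.n_contacts()
    n_contacts = int(counts.sum()) if len(sub) else 0
    flat = np.empty(n_contacts, np.int64)
    src_per_contact = np.repeat(sub.source, counts) if len(sub) else np.empty(0, np.int64)
    pos = 0
    for i in range(len(sub)):
        lo, hi = sub.contact_offsets[i], sub.contact_offsets[i + 1]
        comps = sub.contact_comp[lo:hi]
        flat[pos:pos + len(comps)] = sub.target[i] * n_comp + comps
        pos += len(comps)
    order = np.argsort(src_per_contact, kind="stable")
    flat = flat[order]
    src_sorted = src_per_contact[order]
    offsets = np.searchsorted(src_sorted, np.arange(n_sources + 1))
    w = np.full(n_contacts, gaba_weight * norm_gaba)
    return flat, w, offsets


def run_network(
    network: Network,
    stim: StimSet,
    config: SimConfig,
    msn_dyn: CellDynamics | None = None,
    fsi_dyn: CellDynamics | None = None,
    synapses: dict[str, SynapseParams] | None = None,
    initial_v: dict[str, np.ndarray] | None = None,
) -> SimResult:
    """Simulate the network under the given stimulation.

    ``lateral_on`` / ``feedforward_on`` gate only the event delivery of
    the corresponding recurrent GABA-A connections; inputs, wiring, and
    integration are otherwise bit-identical, so paired ON/OFF runs
    isolate the effect of one inhibition kind.
    """
    syn = synapses or default_synapses()
    msn_dyn = msn_dyn or CellDynamics.msn_default(network.msn_scaffold or build_msn_scaffold())
    fsi_dyn = fsi_dyn or CellDynamics.fsi_default(network.fsi_scaffold or build_fsi_scaffold())
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    gaba = syn["GABA_A"]

    pops = {
        "msn": _Population("msn", msn_dyn, network.n_msn, dt, syn),
        "fsi": _Population("fsi", fsi_dyn, network.n_fsi, dt, syn),
    }
    for name, pop in pops.items():
        pop.bias = stim.bias_vector(name, pop.n_cells)
        if initial_v and name in initial_v:
            v0 = np.asarray(initial_v[name], dtype=float)
            if v0.shape != pop.V.shape:
                raise ValueError(f"initial_v[{name!r}] must have shape {pop.V.shape}")
            pop.V[:] = v0

    compiled = {
        name: stim.compile(name, pop.n_cells, pop.n_comp, dt, pop.norms)
        for name, pop in pops.items()
    }
    ptr = {name: 0 for name in pops}

    # recurrent pathways: lateral MSN->MSN and feedforward FSI->MSN
    lat_flat, lat_w, lat_off = _recurrent_csr(
        network, KIND_LATERAL, network.n_msn, pops["msn"].n_comp, gaba.g_max, gaba.norm)
    ff_flat, ff_w, ff_off = _recurrent_csr(
        network, KIND_FEEDFORWARD, network.n_fsi, pops["msn"].n_comp, gaba.g_max, gaba.norm)

    delay_bins = max(1, int(round(network.topology.delay / dt)))
    ring_len = delay_bins + 2
    ring: list[list] = [[] for _ in range(ring_len)]
    gaba_k = KIND_INDEX["GABA_A"]
    event_log: list = []

    # trace recording
    def rec_ids(sel, n):
        if isinstance(sel, str) and sel == "all":
            return np.arange(n, dtype=np.int64)
        return np.asarray(list(sel), dtype=np.int64)

    rec = {name: rec_ids(getattr(config, f"record_{name}"), pops[name].n_cells)
           for name in pops}
    traces = {name: np.empty((len(rec[name]), n_steps + 1)) for name in pops}
    for name in pops:
        traces[name][:, 0] = pops[name].V[rec[name], 0]

    for step_i in range(n_steps):
        t_next = (step_i + 1) * dt
        # deliver recurrent GABA events scheduled for this step
        slot = step_i % ring_len
        for flat_idx, w_arr in ring[slot]:
            np.add.at(pops["msn"].Sd[gaba_k].reshape(-1), flat_idx, w_arr)
            np.add.at(pops["msn"].Sr[gaba_k].reshape(-1), flat_idx, w_arr)
        ring[slot] = []
        # deliver external input events
        for name, pop in pops.items():
            bins, kinds, flats, ws = compiled[name]
            p = ptr[name]
            q = p
            while q < len(bins) and bins[q] == step_i:
                q += 1
            if q > p:
                pop.add_events(kinds[p:q], flats[p:q], ws[p:q])
                ptr[name] = q
        # integrate and detect spikes
        for name, pop in pops.items():
            if pop.n_cells == 0:
                continue
            spiking = pop.step(t_next)
            if len(spiking) == 0:
                continue
            if name == "msn" and config.lateral_on and len(lat_flat):
                dest = (step_i + 1 + delay_bins) % ring_len
                for s in spiking:
                    lo, hi = lat_off[s], lat_off[s + 1]
                    if hi > lo:
                        ring[dest].append((lat_flat[lo:hi], lat_w[lo:hi]))
                        if config.record_events:
                            event_log.append((t_next, "msn", int(s)))
            if name == "fsi" and config.feedforward_on and len(ff_flat):
                dest = (step_i + 1 + delay_bins) % ring_len
                for s in spiking:
                    lo, hi = ff_off[s], ff_off[s + 1]
                    if hi > lo:
                        ring[dest].append((ff_flat[lo:hi], ff_w[lo:hi]))
                        if config.record_events:
                            event_log.append((t_next, "fsi", int(s)))
        for name in pops:
            if len(rec[name]):
                traces[name][:, step_i + 1] = pops[name].V[rec[name], 0]
        if step_i % 500 == 0:
            for pop in pops.values():
                if pop.n_cells and not np.all(np.isfinite(pop.V)):
                    raise FloatingPointError(
                        f"non-finite membrane state in {pop.name} at t={t_next} ms"
                    )

    raster = RasterSet(
        {
            name: (
                np.array(pops[name].spike_cells, np.int64),
                np.array(pops[name].spike_times),
            )
            for name in pops
        },
        config.duration,
        {name: pops[name].n_cells for name in pops},
    )
    times = np.arange(n_steps + 1) * dt
    trace_set = TraceSet(times, {name: (rec[name], traces[name]) for name in pops})
    return SimResult(raster, trace_set, config, event_log)


# ---------------------------------------------------------------------------
# paired IPSP protocol
# ---------------------------------------------------------------------------

@dataclass
class PairedRun:
    """Aligned inhibition ON / OFF runs of the same network and inputs."""

    result_on: SimResult
    result_off: SimResult
    presyn_pop: str
    presyn_cell: int
    t_first_spike: float  # first presynaptic spike (identical in both runs)

    @property
    def dt(self) -> float:
        return self.result_on.config.dt


def paired_ipsp_run(
    network: Network,
    stim: StimSet,
    config: SimConfig,
    presyn_pop: str,
    presyn_cell: int,
    **sim_kwargs,
) -> PairedRun:
    """Run the paired-subtraction IPSP protocol.

    The toggle matching the presynaptic population (lateral for an MSN
    source, feedforward for an FSI source) is flipped between the two
    runs; everything else, including every input spike, is identical.
    The designated presynaptic cell must spike within the duration.
    """
    if presyn_pop == "msn":
        cfg_on = replace(config, lateral_on=True)
        cfg_off = replace(config, lateral_on=False)
    elif presyn_pop == "fsi":
        cfg_on = replace(config, feedforward_on=True)
        cfg_off = replace(config, feedforward_on=False)
    else:
        raise ValueError("presyn_pop must be 'msn' or 'fsi'")

    res_on = run_network(network, stim, cfg_on, **sim_kwargs)
    res_off = run_network(network, stim, cfg_off, **sim_kwargs)

    def first_spike(res: SimResult) -> float:
        cells, times = res.raster.cells_times(presyn_pop)
        mine = times[cells == presyn_cell]
        if len(mine) == 0:
            raise RuntimeError(
                f"designated presynaptic {presyn_pop} cell {presyn_cell} "
                "did not spike within the simulation"
            )
        return float(mine[0])

    t_on = first_spike(res_on)
    t_off = first_spike(res_off)
    if abs(t_on - t_off) > config.dt / 2:
        raise RuntimeError(
            "presynaptic first spike differs between paired runs "
            f"({t_on} vs {t_off} ms); protocol assumptions violated"
        )
    return PairedRun(res_on, res_off, presyn_pop, presyn_cell, t_on)
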