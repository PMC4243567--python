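"""Spatial construction of the striatal network.

MSN somata sit on a cubic lattice (20 um spacing by default); FSIs are
scattered uniformly through the same cube at a 4:90 FSI:MSN ratio.
Connectivity is distance-gated and stochastic:

* lateral (MSN->MSN): ordered pairs within 380 um connect with
  probability 0.155; a connection makes 1-3 contacts (83/13/4 %)
  placed uniformly over secondary+tertiary dendritic compartments.
* feedforward (FSI->MSN): pairs within 250 um connect with probability
  0.25; a connection makes 7-12 contacts (uniform) placed uniformly
  over soma+primary compartments.

Self-connections are forbidden, reciprocal lateral pairs are allowed,
projections are not wrapped at the cube boundary, and every synaptic
connection has a 2.4 ms conduction delay.  Cortical drive is attached
as per-synapse external connections: 84 glutamatergic + 84 GABAergic
synapses spread over the whole FSI, and glutamatergic synapses confined
to MSN dendrites.

All randomness flows from a single master seed through named
sub-streams (placement, lateral, feedforward, cortical), so each stage
is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
from scipy.spatial.distance import cdist

from .morphology import MorphologyScaffold, build_msn_scaffold, build_fsi_scaffold, placement_zone

__all__ = [
    "PlacementParams",
    "TopologyParams",
    "Connection",
    "ConnectionTable",
    "Network",
    "place_msns",
    "place_fsis",
    "connect_lateral",
    "connect_feedforward",
    "assign_cortical_inputs",
    "build_network",
    "network_summary",
    "KIND_LATERAL",
    "KIND_FEEDFORWARD",
    "KIND_CORTICAL_GLUT",
    "KIND_CORTICAL_GABA",
]

KIND_LATERAL = "lateral"
KIND_FEEDFORWARD = "feedforward"
KIND_CORTICAL_GLUT = "cortical_glut"
KIND_CORTICAL_GABA = "cortical_gaba"

#: external (virtual cortical) source marker
EXTERNAL_SOURCE = -1

# named sub-streams spawned from the master seed, in fixed order
_STAGES = ("placement", "lateral", "feedforward", "cortical", "inputs")


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from one master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown RNG stage {stage!r}")
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGES.index(stage),))


@dataclass(frozen=True)
class PlacementParams:
    n_per_side: int = 14
    spacing: float = 20.0  # um
    fsi_ratio: tuple[int, int] = (4, 90)  # FSIs per MSNs
    extent: float = 280.0  # um, nominal tissue-cube edge (includes margins)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_side < 2:
            raise ValueError("n_per_side must be >= 2")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass(frozen=True)
class TopologyParams:
    p_lateral: float = 0.155
    r_lateral: float = 380.0  # um
    p_feedforward: float = 0.25
    r_feedforward: float = 250.0  # um
    lateral_contact_pmf: tuple[float, float, float] = (0.83, 0.13, 0.04)  # contacts 1,2,3
    ff_contact_range: tuple[int, int] = (7, 12)  # inclusive uniform
    delay: float = 2.4  # ms

    def __post_init__(self) -> None:
        for p in (self.p_lateral, self.p_feedforward):
            if not 0.0 <= p <= 1.0:
                raise ValueError("connection probabilities must lie in [0, 1]")
        if abs(sum(self.lateral_contact_pmf) - 1.0) > 1e-9:
            raise ValueError("lateral contact pmf must sum to 1")
        if self.delay <= 0:
            raise ValueError("delay must be positive")


@dataclass(frozen=True)
class Connection:
    """One axonal projection (possibly multi-contact) onto a target cell."""

    source_cell: int  # -1 for external cortical drive
    target_cell: int
    kind: str
    contacts: tuple[int, ...]  # target compartment ids
    delay: float  # ms


class ConnectionTable:
    """Columnar store of connections; scales to ~10^6 rows.

    Contacts are ragged: ``contact_comp[contact_offsets[i]:contact_offsets[i+1]]``
    are the target compartment ids of connection ``i``.
    """

    def __init__(
        self,
        source: np.ndarray,
        target: np.ndarray,
        kind: np.ndarray,
        delay: np.ndarray,
        contact_offsets: np.ndarray,
        contact_comp: np.ndarray,
    ) -> None:
        self.source = np.asarray(source, dtype=np.int64)
        self.target = np.asarray(target, dtype=np.int64)
        self.kind = np.asarray(kind)
        self.delay = np.asarray(delay, dtype=np.float64)
        self.contact_offsets = np.asarray(contact_offsets, dtype=np.int64)
        self.contact_comp = np.asarray(contact_comp, dtype=np.int64)
        n = len(self.source)
        if not (len(self.target) == len(self.kind) == len(self.delay) == n):
            raise ValueError("column length mismatch")
        if len(self.contact_offsets) != n + 1:
            raise ValueError("contact_offsets must have n+1 entries")

    @classmethod
    def empty(cls) -> "ConnectionTable":
        return cls(
            np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, object),
            np.empty(0), np.zeros(1, np.int64), np.empty(0, np.int64),
        )

    @classmethod
    def from_rows(
        cls,
        source: np.ndarray,
        target: np.ndarray,
        kind: str,
        delay: float,
        contact_counts: np.ndarray,
        contact_comp: np.ndarray,
    ) -> "ConnectionTable":
        n = len(source)
        offsets = np.zeros(n + 1, np.int64)
        np.cumsum(contact_counts, out=offsets[1:])
        return cls(
            source, target, np.full(n, kind, dtype=object),
            np.full(n, delay), offsets, contact_comp,
        )

    def __len__(self) -> int:
        return len(self.source)

    def n_contacts(self) -> np.ndarray:
        return np.diff(self.contact_offsets)

    def row(self, i: int) -> Connection:
        lo, hi = self.contact_offsets[i], self.contact_offsets[i + 1]
        return Connection(
            int(self.source[i]), int(self.target[i]), str(self.kind[i]),
            tuple(int(c) for c in self.contact_comp[lo:hi]), float(self.delay[i]),
        )

    def __iter__(self) -> Iterator[Connection]:
        return (self.row(i) for i in range(len(self)))

    def select(self, kind: str) -> "ConnectionTable":
        mask = self.kind == kind
        idx = np.nonzero(mask)[0]
        counts = self.n_contacts()[idx]
        offsets = np.zeros(len(idx) + 1, np.int64)
        np.cumsum(counts, out=offsets[1:])
        comp = np.concatenate(
            [self.contact_comp[self.contact_offsets[i]:self.contact_offsets[i + 1]] for i in idx]
        ) if len(idx) else np.empty(0, np.int64)
        return ConnectionTable(
            self.source[idx], self.target[idx], self.kind[idx],
            self.delay[idx], offsets, comp,
        )

    @staticmethod
    def concatenate(tables: list["ConnectionTable"]) -> "ConnectionTable":
        tables = [t for t in tables if len(t) > 0]
        if not tables:
            return ConnectionTable.empty()
        counts = np.concatenate([t.n_contacts() for t in tables])
        offsets = np.zeros(counts.size + 1, np.int64)
        np.cumsum(counts, out=offsets[1:])
        return ConnectionTable(
            np.concatenate([t.source for t in tables]),
            np.concatenate([t.target for t in tables]),
            np.concatenate([t.kind for t in tables]),
            np.concatenate([t.delay for t in tables]),
            offsets,
            np.concatenate([t.contact_comp for t in tables]),
        )


@dataclass
class Network:
    """Cell placements plus the synaptic connection table."""

    msn_positions: np.ndarray  # (n_msn, 3) um
    fsi_positions: np.ndarray  # (n_fsi, 3) um
    connections: ConnectionTable
    placement: PlacementParams = field(default_factory=PlacementParams)
    topology: TopologyParams = field(default_factory=TopologyParams)
    msn_scaffold: MorphologyScaffold | None = None
    fsi_scaffold: MorphologyScaffold | None = None

    @property
    def n_msn(self) -> int:
        return len(self.msn_positions)

    @property
    def n_fsi(self) -> int:
        return len(self.fsi_positions)

    # --- serialization -------------------------------------------------
    def to_json(self) -> str:
        conns = []
        t = self.connections
        for i in range(len(t)):
            lo, hi = t.contact_offsets[i], t.contact_offsets[i + 1]
            conns.append([
                int(t.source[i]), int(t.target[i]), str(t.kind[i]),
                [int(c) for c in t.contact_comp[lo:hi]], float(t.delay[i]),
            ])
        doc = {
            "placement": asdict(self.placement),
            "topology": asdict(self.topology),
            "msn_positions_um": self.msn_positions.tolist(),
            "fsi_positions_um": self.fsi_positions.tolist(),
            "connections": conns,
            "msn_scaffold": json.loads(self.msn_scaffold.to_json()) if self.msn_scaffold else None,
            "fsi_scaffold": json.loads(self.fsi_scaffold.to_json()) if self.fsi_scaffold else None,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Network":
        doc = json.loads(text)
        conns = doc["connections"]
        n = len(conns)
        source = np.array([c[0] for c in conns], np.int64)
        target = np.array([c[1] for c in conns], np.int64)
        kind = np.array([c[2] for c in conns], object)
        delay = np.array([c[4] for c in conns], np.float64)
        counts = np.array([len(c[3]) for c in conns], np.int64)
        offsets = np.zeros(n + 1, np.int64)
        np.cumsum(counts, out=offsets[1:])
        comp = np.array(
            [cid for c in conns for cid in c[3]], np.int64
        ) if n else np.empty(0, np.int64)
        pl = doc["placement"]
        pl["fsi_ratio"] = tuple(pl["fsi_ratio"])
        tp = doc["topology"]
        tp["lateral_contact_pmf"] = tuple(tp["lateral_contact_pmf"])
        tp["ff_contact_range"] = tuple(tp["ff_contact_range"])
        return cls(
            msn_positions=np.asarray(doc["msn_positions_um"], float),
            fsi_positions=np.asarray(doc["fsi_positions_um"], float),
            connections=ConnectionTable(source, target, kind, delay, offsets, comp),
            placement=PlacementParams(**pl),
            topology=TopologyParams(**tp),
            msn_scaffold=(
                MorphologyScaffold.from_json(json.dumps(doc["msn_scaffold"]))
                if doc.get("msn_scaffold") else None
            ),
            fsi_scaffold=(
                MorphologyScaffold.from_json(json.dumps(doc["fsi_scaffold"]))
                if doc.get("fsi_scaffold") else None
            ),
        )


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_msns(params: PlacementParams) -> np.ndarray:
    """Cubic lattice of MSN soma positions (um); deterministic."""
    axis = np.arange(params.n_per_side) * params.spacing
    x, y, z = np.meshgrid(axis, axis, axis, indexing="ij")
    return np.column_stack([x.ravel(), y.ravel(), z.ravel()]).astype(float)


def n_fsi_for(n_msn: int, ratio: tuple[int, int] = (4, 90)) -> int:
    return int(np.floor(n_msn * ratio[0] / ratio[1]))


def place_fsis(n_msn: int, params: PlacementParams, rng_seed) -> np.ndarray:
    """FSI somata drawn uniformly inside the MSN lattice bounding cube."""
    if n_msn < 1:
        raise ValueError("n_msn must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n_fsi = n_fsi_for(n_msn, params.fsi_ratio)
    hi = (params.n_per_side - 1) * params.spacing
    return rng.uniform(0.0, hi, size=(n_fsi, 3))


# ---------------------------------------------------------------------------
# wiring
# ---------------------------------------------------------------------------

def connect_lateral(
    network: Network,
    scaffold: MorphologyScaffold,
    rng_seed,
) -> ConnectionTable:
    """MSN->MSN projections: distance-gated Bernoulli wiring.

    Every ordered pair within ``r_lateral`` connects independently with
    probability ``p_lateral``; each connection draws 1-3 contacts from
    the stated pmf and places them uniformly (with replacement) over the
    secondary+tertiary dendritic compartments of the target.
    """
    rng = np.random.default_rng(rng_seed)
    pos = network.msn_positions
    topo = network.topology
    n = len(pos)
    dist = cdist(pos, pos)
    in_range = (dist <= topo.r_lateral)
    np.fill_diagonal(in_range, False)  # no self-connections
    draw = rng.random((n, n)) < topo.p_lateral
    src, tgt = np.nonzero(in_range & draw)
    n_conn = len(src)
    pmf = np.asarray(topo.lateral_contact_pmf)
    counts = rng.choice(np.array([1, 2, 3]), size=n_conn, p=pmf)
    zone = placement_zone(scaffold, "lateral_target")
    comp = rng.choice(zone, size=int(counts.sum()), replace=True)
    return ConnectionTable.from_rows(src, tgt, KIND_LATERAL, topo.delay, counts, comp)


def connect_feedforward(
    network: Network,
    scaffold: MorphologyScaffold,
    rng_seed,
) -> ConnectionTable:
    """FSI->MSN projections: within 250 um, p=0.25, 7-12 proximal contacts."""
    rng = np.random.default_rng(rng_seed)
    topo = network.topology
    if network.n_fsi == 0:
        return ConnectionTable.empty()
    dist = cdist(network.fsi_positions, network.msn_positions)
    in_range = dist <= topo.r_feedforward
    draw = rng.random(dist.shape) < topo.p_feedforward
    src, tgt = np.nonzero(in_range & draw)
    lo, hi = topo.ff_contact_range
    counts = rng.integers(lo, hi + 1, size=len(src))
    zone = placement_zone(scaffold, "feedforward_target")
    comp = rng.choice(zone, size=int(counts.sum()), replace=True)
    return ConnectionTable.from_rows(src, tgt, KIND_FEEDFORWARD, topo.delay, counts, comp)


def assign_cortical_inputs(
    network: Network,
    msn_scaffold: MorphologyScaffold,
    fsi_scaffold: MorphologyScaffold,
    rng_seed,
    n_fsi_glut: int = 84,
    n_fsi_gaba: int = 84,
    n_msn_glut: int = 84,
) -> ConnectionTable:
    """External cortical synapses.

    Each FSI receives ``n_fsi_glut`` glutamatergic (AMPA/NMDA pair) and
    ``n_fsi_gaba`` GABAergic synapses over the whole cell; each MSN
    receives ``n_msn_glut`` glutamatergic synapses confined to its
    dendritic (non-soma) compartments.  Each synapse is one single-contact
    external connection (source -1); delay 0 is conventional for drive
    whose timing is already expressed in the input trains.
    """
    if n_msn_glut <= 0:
        raise ValueError("n_msn_glut must be positive")
    rng = np.random.default_rng(rng_seed)
    tables = []

    msn_zone = placement_zone(msn_scaffold, "cortical_target_msn")
    fsi_zone = placement_zone(fsi_scaffold, "whole_cell")

    n_msn = network.n_msn
    tgt = np.repeat(np.arange(n_msn), n_msn_glut)
    comp = rng.choice(msn_zone, size=n_msn * n_msn_glut, replace=True)
    tables.append(ConnectionTable.from_rows(
        np.full(tgt.shape, EXTERNAL_SOURCE), tgt, KIND_CORTICAL_GLUT, 0.0,
        np.ones(tgt.shape, np.int64), comp,
    ))

    n_fsi = network.n_fsi
    if n_fsi:
        for kind, n_syn in ((KIND_CORTICAL_GLUT, n_fsi_glut), (KIND_CORTICAL_GABA, n_fsi_gaba)):
            # FSI targets are offset past the MSN ids in the global numbering
            tgt = np.repeat(np.arange(n_fsi) + n_msn, n_syn)
            comp = rng.choice(fsi_zone, size=n_fsi * n_syn, replace=True)
            tables.append(ConnectionTable.from_rows(
                np.full(tgt.shape, EXTERNAL_SOURCE), tgt, kind, 0.0,
                np.ones(tgt.shape, np.int64), comp,
            ))
    return ConnectionTable.concatenate(tables)


def build_network(
    placement: PlacementParams | None = None,
    topology: TopologyParams | None = None,
    seed: int | None = None,
    lateral: bool = True,
    feedforward: bool = True,
    cortical: bool = False,
    n_msn_glut: int = 84,
) -> Network:
    """Build the full network from a single master seed."""
    placement = placement or PlacementParams()
    topology = topology or TopologyParams()
    master = placement.seed if seed is None else seed

    msn_scaffold = build_msn_scaffold()
    fsi_scaffold = build_fsi_scaffold()
    msn_pos = place_msns(placement)
    fsi_pos = place_fsis(len(msn_pos), placement, stage_seed(master, "placement"))

    net = Network(
        msn_positions=msn_pos, fsi_positions=fsi_pos,
        connections=ConnectionTable.empty(),
        placement=placement, topology=topology,
        msn_scaffold=msn_scaffold, fsi_scaffold=fsi_scaffold,
    )
    tables = []
    if lateral:
        tables.append(connect_lateral(net, msn_scaffold, stage_seed(master, "lateral")))
    if feedforward:
        tables.append(connect_feedforward(net, msn_scaffold, stage_seed(master, "feedforward")))
    if cortical:
        tables.append(assign_cortical_inputs(
            net, msn_scaffold, fsi_scaffold, stage_seed(master, "cortical"),
            n_msn_glut=n_msn_glut,
        ))
    net.connections = ConnectionTable.concatenate(tables)
    return net


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _in_range_ordered_pairs(pos_a: np.ndarray, pos_b: np.ndarray, radius: float,
                            exclude_diagonal: bool) -> int:
    dist = cdist(pos_a, pos_b)
    mask = dist <= radius
    if exclude_diagonal:
        np.fill_diagonal(mask, False)
    return int(mask.sum())


def network_summary(network: Network) -> dict:
    """Realized wiring statistics for a built network.

    Returns per-MSN afferent means (cells and contacts by kind), the
    realized connection probabilities among in-range pairs, contact-count
    histograms, and the set of delays.
    """
    t = network.connections
    out: dict = {"n_msn": network.n_msn, "n_fsi": network.n_fsi}
    n_msn = network.n_msn

    for kind, radius, pos_src, excl in (
        (KIND_LATERAL, network.topology.r_lateral, network.msn_positions, True),
        (KIND_FEEDFORWARD, network.topology.r_feedforward, network.fsi_positions, False),
    ):
        sub = t.select(kind)
        counts = sub.n_contacts()
        per_cell_contacts = np.bincount(sub.target, weights=counts, minlength=n_msn) \
            if len(sub) else np.zeros(n_msn)
        per_cell_sources = np.bincount(sub.target, minlength=n_msn) \
            if len(sub) else np.zeros(n_msn)
        n_in_range = _in_range_ordered_pairs(
            pos_src, network.msn_positions, radius, excl,
        ) if len(pos_src) else 0
        hist = np.bincount(counts, minlength=14)[1:14] if len(sub) else np.zeros(13, int)
        out[kind] = {
            "n_connections": int(len(sub)),
            "n_contacts": int(counts.sum()) if len(sub) else 0,
            "mean_afferent_cells_per_msn": float(per_cell_sources.mean()) if n_msn else 0.0,
            "mean_afferent_contacts_per_msn": float(per_cell_contacts.mean()) if n_msn else 0.0,
            "n_in_range_ordered_pairs": n_in_range,
            "realized_p": float(len(sub) / n_in_range) if n_in_range else 0.0,
            "contact_count_hist": hist.tolist(),
        }
    out["delays_ms"] = sorted(
        {float(d) for d, k in zip(t.delay, t.kind) if k in (KIND_LATERAL, KIND_FEEDFORWARD)}
    )
    return out
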