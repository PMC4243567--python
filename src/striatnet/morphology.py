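"""Compartment scaffolds for striatal model neurons.

Medium spiny neurons (MSNs) and fast-spiking interneurons (FSIs) are
represented as branched trees of electrical compartments labelled by
branch order (soma, primary, secondary, tertiary dendrite).  The default
MSN scaffold has 189 compartments (1 soma, 4 primary dendrites of one
compartment each, 8 secondary dendrites of one compartment each, 16
tertiary dendrites of 11 compartments each); the default FSI scaffold
has 148 compartments (1 soma, 3 primary dendrites of 3 compartments, 6
secondary of 5, 12 tertiary of 9).  The scaffold fixes the targets that
the network builder wires synapses onto; geometric dimensions are
configurable defaults that only matter to the reduced cable dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "BranchOrder",
    "Compartment",
    "MorphologyScaffold",
    "BranchGeometry",
    "build_msn_scaffold",
    "build_fsi_scaffold",
    "placement_zone",
    "PLACEMENT_ZONES",
]


class BranchOrder(str, Enum):
    SOMA = "soma"
    PRIMARY = "primary"
    SECONDARY = "secondary"
    TERTIARY = "tertiary"


#: order in which branch orders may parent one another
_ORDER_RANK = {
    BranchOrder.SOMA: 0,
    BranchOrder.PRIMARY: 1,
    BranchOrder.SECONDARY: 2,
    BranchOrder.TERTIARY: 3,
}


@dataclass(frozen=True)
class Compartment:
    """One electrical segment of a model neuron."""

    id: int
    branch_order: BranchOrder
    parent_id: int | None  # None for the soma only
    length: float  # um
    diameter: float  # um

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("compartment length and diameter must be positive")


@dataclass(frozen=True)
class BranchGeometry:
    """Per-branch-order segment dimensions (um).

    ``length`` is the length of a single compartment of that order, not
    of the whole dendrite.
    """

    soma_length: float = 16.0
    soma_diameter: float = 16.0
    primary_length: float = 20.0
    primary_diameter: float = 2.25
    secondary_length: float = 24.0
    secondary_diameter: float = 1.10
    tertiary_length: float = 13.0
    tertiary_diameter: float = 0.72


@dataclass(frozen=True)
class MorphologyScaffold:
    """Branched compartment tree for one cell type.

    Compartments are stored parent-before-child (the soma has index 0),
    which downstream cable solvers rely on.
    """

    cell_type: str  # "MSN" or "FSI"
    compartments: tuple[Compartment, ...]
    branching: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [c for c in self.compartments if c.parent_id is None]
        if len(roots) != 1 or roots[0].branch_order is not BranchOrder.SOMA:
            raise ValueError("scaffold must have exactly one soma root")
        by_id = {c.id: c for c in self.compartments}
        if len(by_id) != len(self.compartments):
            raise ValueError("duplicate compartment ids")
        for c in self.compartments:
            if c.parent_id is None:
                continue
            parent = by_id.get(c.parent_id)
            if parent is None:
                raise ValueError(f"compartment {c.id} has unknown parent")
            if _ORDER_RANK[parent.branch_order] > _ORDER_RANK[c.branch_order]:
                raise ValueError("parent branch order must not exceed child's")

    def __len__(self) -> int:
        return len(self.compartments)

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def parent_index(self) -> np.ndarray:
        """Parent id per compartment, -1 at the soma."""
        return np.array(
            [-1 if c.parent_id is None else c.parent_id for c in self.compartments],
            dtype=np.int64,
        )

    def orders(self) -> np.ndarray:
        return np.array([c.branch_order.value for c in self.compartments])

    def ids_with_order(self, *orders: BranchOrder) -> np.ndarray:
        wanted = set(orders)
        return np.array(
            [c.id for c in self.compartments if c.branch_order in wanted],
            dtype=np.int64,
        )

    def ancestors(self, comp_id: int) -> list[int]:
        """Chain of ids from ``comp_id``'s parent up to the soma."""
        by_id = {c.id: c for c in self.compartments}
        chain: list[int] = []
        cur = by_id[comp_id]
        while cur.parent_id is not None:
            chain.append(cur.parent_id)
            cur = by_id[cur.parent_id]
        return chain

    # --- serialization -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "cell_type": self.cell_type,
            "branching": self.branching,
            "compartments": [
                {
                    "id": c.id,
                    "parent": c.parent_id,
                    "order": c.branch_order.value,
                    "length_um": c.length,
                    "diam_um": c.diameter,
                }
                for c in self.compartments
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "MorphologyScaffold":
        doc = json.loads(text)
        comps = tuple(
            Compartment(
                id=int(c["id"]),
                branch_order=BranchOrder(c["order"]),
                parent_id=None if c["parent"] is None else int(c["parent"]),
                length=float(c["length_um"]),
                diameter=float(c["diam_um"]),
            )
            for c in doc["compartments"]
        )
        return cls(
            cell_type=doc["cell_type"],
            compartments=comps,
            branching={k: int(v) for k, v in doc.get("branching", {}).items()},
        )


def _build_scaffold(
    cell_type: str,
    n_primary: int,
    comps_per_primary: int,
    comps_per_secondary: int,
    comps_per_tertiary: int,
    geometry: BranchGeometry,
) -> MorphologyScaffold:
    """Binary-branching tree: each primary dendrite splits into two
    secondaries, each secondary into two tertiaries."""
    comps: list[Compartment] = [
        Compartment(0, BranchOrder.SOMA, None, geometry.soma_length, geometry.soma_diameter)
    ]
    next_id = 1

    def chain(n: int, order: BranchOrder, parent: int, length: float, diam: float) -> int:
        nonlocal next_id
        for _ in range(n):
            comps.append(Compartment(next_id, order, parent, length, diam))
            parent = next_id
            next_id += 1
        return parent  # id of last compartment in the chain

    for _ in range(n_primary):
        p_tip = chain(
            comps_per_primary, BranchOrder.PRIMARY, 0,
            geometry.primary_length, geometry.primary_diameter,
        )
        for _ in range(2):
            s_tip = chain(
                comps_per_secondary, BranchOrder.SECONDARY, p_tip,
                geometry.secondary_length, geometry.secondary_diameter,
            )
            for _ in range(2):
                chain(
                    comps_per_tertiary, BranchOrder.TERTIARY, s_tip,
                    geometry.tertiary_length, geometry.tertiary_diameter,
                )

    return MorphologyScaffold(
        cell_type=cell_type,
        compartments=tuple(comps),
        branching={
            "primary": n_primary,
            "secondary": 2 * n_primary,
            "tertiary": 4 * n_primary,
        },
    )


def build_msn_scaffold(
    n_primary: int = 4,
    comps_per_primary: int = 1,
    comps_per_secondary: int = 1,
    comps_per_tertiary: int = 11,
    geometry: BranchGeometry | None = None,
) -> MorphologyScaffold:
    """Medium spiny neuron scaffold: 189 compartments by default.

    1 soma + 4 primary (1 compartment each) + 8 secondary (1 each) +
    16 tertiary dendrites of 11 compartments each.
    """
    geometry = geometry or BranchGeometry()
    return _build_scaffold(
        "MSN", n_primary, comps_per_primary, comps_per_secondary,
        comps_per_tertiary, geometry,
    )


def build_fsi_scaffold(
    n_primary: int = 3,
    comps_per_primary: int = 3,
    comps_per_secondary: int = 5,
    comps_per_tertiary: int = 9,
    geometry: BranchGeometry | None = None,
) -> MorphologyScaffold:
    """Fast-spiking interneuron scaffold: 148 compartments by default.

    1 soma + 3 primary dendrites of 3 compartments + 6 secondary of 5 +
    12 tertiary of 9.
    """
    geometry = geometry or BranchGeometry(
        soma_length=15.0, soma_diameter=15.0,
        primary_length=10.0, primary_diameter=1.5,
        secondary_length=12.0, secondary_diameter=1.0,
        tertiary_length=12.0, tertiary_diameter=0.6,
    )
    return _build_scaffold(
        "FSI", n_primary, comps_per_primary, comps_per_secondary,
        comps_per_tertiary, geometry,
    )


PLACEMENT_ZONES = ("lateral_target", "feedforward_target", "cortical_target_msn", "whole_cell")


def placement_zone(scaffold: MorphologyScaffold, zone: str) -> np.ndarray:
    """Compartment ids eligible for synapse placement in a named zone.

    ``lateral_target``
        secondary + tertiary dendrites (distal MSN->MSN contacts)
    ``feedforward_target``
        soma + primary dendrites (proximal FSI->MSN contacts)
    ``cortical_target_msn``
        all dendritic (non-soma) compartments
    ``whole_cell``
        every compartment
    """
    if zone == "lateral_target":
        return scaffold.ids_with_order(BranchOrder.SECONDARY, BranchOrder.TERTIARY)
    if zone == "feedforward_target":
        return scaffold.ids_with_order(BranchOrder.SOMA, BranchOrder.PRIMARY)
    if zone == "cortical_target_msn":
        return scaffold.ids_with_order(
            BranchOrder.PRIMARY, BranchOrder.SECONDARY, BranchOrder.TERTIARY
        )
    if zone == "whole_cell":
        return np.array([c.id for c in scaffold.compartments], dtype=np.int64)
    raise ValueError(f"unknown placement zone {zone!r}; expected one of {PLACEMENT_ZONES}")
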