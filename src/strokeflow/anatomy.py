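"""Assembly of the heart-to-pial-surface arterial network.

The systemic large vessels (aorta, carotids, vertebrals, circle of Willis,
basilar chain with pontine branches) are described by a packaged parameter
table and hard-wired named connectivity.  The six major cerebral arteries
(left/right ACA, MCA, PCA) can be extended with donor cerebral trees --
either tabulated centreline data or synthetic bifurcating trees generated
from Murray's law and a length-to-radius ratio -- so that the network
terminates in ~10^2 small pial outlets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WallModelConstants",
    "VesselSegment",
    "ArterialNetwork",
    "DonorTree",
    "DonorVessel",
    "wall_thickness",
    "build_default_anatomy",
    "load_vessel_table",
    "default_vessel_table",
    "default_co_fractions",
    "attach_donor_tree",
    "generate_synthetic_cerebral_tree",
    "generate_synthetic_donor",
    "discretize_network",
    "subtree_resistance",
    "poiseuille_resistance",
    "TopologyError",
    "ValidationError",
    "AttachmentError",
]

PROXIMAL = "proximal"
DISTAL = "distal"

MAJOR_CEREBRAL_LABELS = ("L ACA", "R ACA", "L MCA", "R MCA", "L PCA", "R PCA")

#: default dynamic viscosity of blood [Pa s], used for Poiseuille resistances
DEFAULT_VISCOSITY = 0.0035


class TopologyError(ValueError):
    """The wiring of the network is inconsistent (missing parent, cycles ...)."""


class ValidationError(ValueError):
    """A vessel parameter violates its physical constraints."""


class AttachmentError(ValueError):
    """A donor subtree could not be matched to the patient network."""


# ---------------------------------------------------------------------------
# wall model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WallModelConstants:
    """Constants of the empirical wall-thickness law h = r0 [a e^{b r0} + c e^{d r0}].

    ``b`` and ``d`` are in 1/mm; ``a`` and ``c`` are dimensionless.
    """

    a: float = 0.2802
    b: float = -0.5053
    c: float = 0.1324
    d: float = -0.01114


def wall_thickness(r0_mm: float, constants: WallModelConstants = WallModelConstants()) -> float:
    """Vessel wall thickness [mm] from the lumen radius [mm].

    Empirical two-exponential fit; thick-walled for small radii (h/r ~ 0.4 at
    0.1 mm) and thin-walled for the aorta (h/r ~ 0.12 at 12 mm).
    """
    r0 = np.asarray(r0_mm, dtype=float)
    if np.any(r0 <= 0):
        raise ValidationError(f"radius must be positive, got {r0_mm!r}")
    k = constants
    h = r0 * (k.a * np.exp(k.b * r0) + k.c * np.exp(k.d * r0))
    return float(h) if np.isscalar(r0_mm) else h


# ---------------------------------------------------------------------------
# vessel segments and networks
# ---------------------------------------------------------------------------

@dataclass
class VesselSegment:
    """One elastic tube of the network (geometry in mm, stiffness in Pa)."""

    name: str
    length_mm: float
    r_prox_mm: float
    r_dist_mm: float
    youngs_modulus_pa: float
    poisson_ratio: float = 0.5
    major_label: str = "systemic"
    #: axial node coordinates [mm], populated by :func:`discretize_network`
    node_positions_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValidationError(f"{self.name}: length must be positive")
        if self.r_prox_mm <= 0 or self.r_dist_mm <= 0:
            raise ValidationError(f"{self.name}: radii must be positive")
        if self.youngs_modulus_pa <= 0:
            raise ValidationError(f"{self.name}: Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 1.0:
            raise ValidationError(f"{self.name}: Poisson ratio must be in [0, 1)")

    @property
    def mean_radius_mm(self) -> float:
        return 0.5 * (self.r_prox_mm + self.r_dist_mm)

    @property
    def wall_thickness_mm(self) -> float:
        """Thickness evaluated at the mean radius."""
        return wall_thickness(self.mean_radius_mm)

    def radius_at(self, x_mm: np.ndarray) -> np.ndarray:
        """Linear taper r(x) between the proximal and distal radius."""
        x = np.asarray(x_mm, dtype=float)
        t = np.clip(x / self.length_mm, 0.0, 1.0)
        return self.r_prox_mm + (self.r_dist_mm - self.r_prox_mm) * t

    def node_radii_mm(self) -> np.ndarray:
        if self.node_positions_mm is None:
            raise ValidationError(f"{self.name}: segment not discretized")
        return self.radius_at(self.node_positions_mm)


class ArterialNetwork:
    """Directed multigraph of vessel segments.

    Junctions are lists of ``(segment_name, end)`` pairs, ``end`` being
    ``"proximal"`` or ``"distal"``.  Exactly one proximal end is the inlet
    (ascending aorta at the heart); every end that appears in no junction
    and is not the inlet is an outlet.  The communicating arteries of the
    circle of Willis close loops, so acyclicity is not required.
    """

    def __init__(
        self,
        segments: Iterable[VesselSegment],
        junctions: Sequence[Sequence[tuple[str, str]]],
        inlet: str,
        outlet_tags: Mapping[str, str] | None = None,
        default_outlet_tag: str = "head",
        co_fractions: Mapping[str, float] | None = None,
    ) -> None:
        self.segments: dict[str, VesselSegment] = {}
        for seg in segments:
            if seg.name in self.segments:
                raise TopologyError(f"duplicate segment name {seg.name!r}")
            self.segments[seg.name] = seg
        self.junctions: list[list[tuple[str, str]]] = [
            [(str(n), str(e)) for n, e in j] for j in junctions
        ]
        self.inlet = inlet
        self._outlet_tags = dict(outlet_tags or {})
        self._default_outlet_tag = default_outlet_tag
        self.co_fractions = dict(co_fractions or {})
        self._validate()

    # -- construction and validation ------------------------------------

    def _validate(self) -> None:
        if not self.segments:
            raise ValidationError("network has no segments")
        if self.inlet not in self.segments:
            raise TopologyError(f"inlet segment {self.inlet!r} not in table")
        seen_ends: set[tuple[str, str]] = set()
        for jct in self.junctions:
            if len(jct) < 2:
                raise TopologyError(f"junction {jct} has fewer than two ends")
            for name, end in jct:
                if name not in self.segments:
                    raise TopologyError(f"junction references missing vessel {name!r}")
                if end not in (PROXIMAL, DISTAL):
                    raise TopologyError(f"bad end {end!r} for {name!r}")
                if (name, end) in seen_ends:
                    raise TopologyError(f"end {(name, end)} used in two junctions")
                seen_ends.add((name, end))
        if (self.inlet, PROXIMAL) in seen_ends:
            raise TopologyError("inlet proximal end may not sit in a junction")
        g = self.segment_graph()
        if g.number_of_nodes() and not nx.is_connected(nx.Graph(g)):
            raise TopologyError("network is not connected")

    # -- topology queries ------------------------------------------------

    def free_ends(self) -> list[tuple[str, str]]:
        """Ends not attached to any junction (inlet end included)."""
        used = {(n, e) for j in self.junctions for n, e in j}
        out = []
        for name in self.segments:
            for end in (PROXIMAL, DISTAL):
                if (name, end) not in used:
                    out.append((name, end))
        return out

    @property
    def outlets(self) -> list[tuple[str, str]]:
        """Free ends excluding the inlet, in stable (table) order."""
        return [fe for fe in self.free_ends() if fe != (self.inlet, PROXIMAL)]

    def outlet_tag(self, name: str) -> str:
        return self._outlet_tags.get(name, self._default_outlet_tag)

    def outlet_registry(self) -> pd.DataFrame:
        """One row per outlet: segment, end, outlet radius [mm], tag, label."""
        rows = []
        for name, end in self.outlets:
            seg = self.segments[name]
            r = seg.r_dist_mm if end == DISTAL else seg.r_prox_mm
            rows.append(
                {
                    "outlet": name,
                    "end": end,
                    "radius_mm": r,
                    "tag": self.outlet_tag(name),
                    "label": seg.major_label,
                }
            )
        return pd.DataFrame(rows)

    def segment_graph(self) -> nx.MultiGraph:
        """Graph whose nodes are junction ids / free ends, edges are segments."""
        end_to_node: dict[tuple[str, str], object] = {}
        for i, jct in enumerate(self.junctions):
            for name, end in jct:
                end_to_node[(name, end)] = ("J", i)
        g = nx.MultiGraph()
        for name, seg in self.segments.items():
            u = end_to_node.get((name, PROXIMAL), ("E", name, PROXIMAL))
            v = end_to_node.get((name, DISTAL), ("E", name, DISTAL))
            g.add_edge(u, v, key=name, length_mm=seg.length_mm)
        return g

    def downstream_segments(self, name: str) -> list[str]:
        """Segments fed (in the heart-to-periphery sense) through ``name``.

        Computed by cutting ``name`` out of the segment graph and collecting
        every segment no longer reachable from the inlet.
        """
        g = self.segment_graph()
        keep = nx.MultiGraph(
            (u, v, k) for u, v, k in g.edges(keys=True) if k != name
        )
        inlet_end = ("E", self.inlet, PROXIMAL)
        for i, jct in enumerate(self.junctions):
            if (self.inlet, PROXIMAL) in jct:  # pragma: no cover - inlet is free
                inlet_end = ("J", i)
        if inlet_end not in keep:
            keep.add_node(inlet_end)
        reachable_edges: set[str] = set()
        for comp in nx.connected_components(keep):
            if inlet_end in comp:
                for u, v, k in keep.edges(comp, keys=True):
                    reachable_edges.add(k)
        return [s for s in self.segments if s != name and s not in reachable_edges]

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "inlet": self.inlet,
            "junctions": self.junctions,
            "outlet_tags": self._outlet_tags,
            "default_outlet_tag": self._default_outlet_tag,
            "co_fractions": self.co_fractions,
            "segments": [
                {
                    "name": s.name,
                    "length_mm": s.length_mm,
                    "r_prox_mm": s.r_prox_mm,
                    "r_dist_mm": s.r_dist_mm,
                    "youngs_modulus_pa": s.youngs_modulus_pa,
                    "poisson_ratio": s.poisson_ratio,
                    "major_label": s.major_label,
                    "node_positions_mm": None
                    if s.node_positions_mm is None
                    else list(map(float, s.node_positions_mm)),
                }
                for s in self.segments.values()
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ArterialNetwork":
        d = json.loads(text)
        segs = []
        for s in d["segments"]:
            pos = s.pop("node_positions_mm", None)
            seg = VesselSegment(**s)
            if pos is not None:
                seg.node_positions_mm = np.asarray(pos, dtype=float)
            segs.append(seg)
        return cls(
            segs,
            [[(n, e) for n, e in j] for j in d["junctions"]],
            d["inlet"],
            outlet_tags=d.get("outlet_tags"),
            default_outlet_tag=d.get("default_outlet_tag", "head"),
            co_fractions=d.get("co_fractions"),
        )


# ---------------------------------------------------------------------------
# default anatomy
# ---------------------------------------------------------------------------

def _data_text(fname: str) -> str:
    return resources.files("strokeflow.data").joinpath(fname).read_text()


def default_vessel_table() -> pd.DataFrame:
    """The packaged large-vessel parameter table (mm / MPa)."""
    import io

    return pd.read_csv(io.StringIO(_data_text("default_vessels.csv")))


def default_co_fractions() -> dict[str, float]:
    return dict(json.loads(_data_text("default_topology.json"))["co_fractions"])


def load_vessel_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def build_default_anatomy(table: pd.DataFrame | None = None) -> ArterialNetwork:
    """Build the default heart-to-CoW anatomy from the packaged vessel table.

    ``table`` may override vessel parameters (same ``name`` column); the named
    wiring (aorta chain, carotid bifurcations, vertebro-basilar chain with
    pontine branches, circle of Willis ring) is fixed.
    """
    topo = json.loads(_data_text("default_topology.json"))
    if table is None:
        table = default_vessel_table()
    required = {"name", "length_mm", "r_prox_mm", "r_dist_mm", "E_MPa"}
    if table is None or len(table) == 0:
        raise ValidationError("empty vessel table")
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"vessel table lacks columns {sorted(missing)}")
    labels = topo["labels"]
    segments = []
    for row in table.itertuples(index=False):
        segments.append(
            VesselSegment(
                name=row.name,
                length_mm=float(row.length_mm),
                r_prox_mm=float(row.r_prox_mm),
                r_dist_mm=float(row.r_dist_mm),
                youngs_modulus_pa=float(row.E_MPa) * 1e6,
                major_label=labels.get(row.name, "systemic"),
            )
        )
    junctions = [[(n, e) for n, e in j] for j in topo["junctions"]]
    names = {s.name for s in segments}
    for jct in junctions:
        for n, _ in jct:
            if n not in names:
                raise TopologyError(f"wiring references vessel {n!r} missing from table")
    net = ArterialNetwork(
        segments,
        junctions,
        inlet=topo["inlet"],
        outlet_tags=topo["outlet_tags"],
        default_outlet_tag=topo["default_outlet_tag"],
        co_fractions=topo["co_fractions"],
    )
    net.attachment_points = dict(topo["attachment_points"])
    return net


# ---------------------------------------------------------------------------
# donor cerebral trees
# ---------------------------------------------------------------------------

@dataclass
class DonorVessel:
    id: int
    parent_id: int  # -1 for a subtree root
    length_mm: float
    radius_mm: float
    label: str


class DonorTree:
    """Flat table of smoothed cerebral vessels grouped into labelled subtrees.

    Emulates centreline datasets in which every vessel is reduced to its mean
    radius and length; the solver depends on nothing else.  Each major-artery
    label owns exactly one rooted subtree whose root is the donor's copy of
    that major artery.
    """

    def __init__(self, vessels: Iterable[DonorVessel]) -> None:
        self.vessels: dict[int, DonorVessel] = {}
        for v in vessels:
            if v.radius_mm <= 0 or v.length_mm < 0:
                raise ValidationError(f"donor vessel {v.id}: non-positive geometry")
            if v.id in self.vessels:
                raise ValidationError(f"duplicate donor vessel id {v.id}")
            self.vessels[v.id] = v
        self.children: dict[int, list[int]] = {i: [] for i in self.vessels}
        for v in self.vessels.values():
            if v.parent_id >= 0:
                if v.parent_id not in self.vessels:
                    raise ValidationError(f"donor vessel {v.id}: missing parent")
                self.children[v.parent_id].append(v.id)

    @property
    def labels(self) -> list[str]:
        return sorted({v.label for v in self.vessels.values()})

    def subtree_root(self, label: str) -> DonorVessel:
        roots = [
            v
            for v in self.vessels.values()
            if v.label == label and (v.parent_id < 0 or self.vessels[v.parent_id].label != label)
        ]
        if len(roots) != 1:
            raise AttachmentError(
                f"label {label!r} has {len(roots)} roots; expected exactly one"
            )
        return roots[0]

    def descendants(self, vid: int) -> list[int]:
        out, stack = [], [vid]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(sorted(self.children[i]))
        return out

    def leaves(self, vid: int | None = None) -> list[int]:
        ids = self.descendants(vid) if vid is not None else list(self.vessels)
        return [i for i in ids if not self.children[i]]

    # -- tabular I/O -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": v.id,
                    "parent_id": v.parent_id,
                    "length_mm": v.length_mm,
                    "radius_mm": v.radius_mm,
                    "label": v.label,
                }
                for v in self.vessels.values()
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DonorTree":
        return cls(
            DonorVessel(
                int(r.id), int(r.parent_id), float(r.length_mm), float(r.radius_mm), str(r.label)
            )
            for r in df.itertuples(index=False)
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DonorTree":
        return cls.from_frame(pd.read_csv(path))


def generate_synthetic_cerebral_tree(
    root_radius_mm: float,
    terminal_radius_mm: float,
    length_to_radius_ratio: float = 20.0,
    murray_exponent: float = 3.0,
    asymmetry: float = 1.0,
    seed: int = 0,
    label: str = "tree",
    id_offset: int = 0,
) -> DonorTree:
    """Recursive bifurcating tree obeying Murray's law.

    At every bifurcation the child radii satisfy
    ``r_p^gamma = r_1^gamma + r_2^gamma`` with the ratio ``r_1/r_2`` drawn
    uniformly from ``[asymmetry, 1]`` (so ``asymmetry=1`` is the symmetric,
    fully deterministic tree).  Segment length is
    ``length_to_radius_ratio * radius``.  A vessel whose radius has dropped
    below ``terminal_radius_mm`` spawns no children.  The subtree root is the
    major artery itself (radius ``root_radius_mm``).
    """
    if not (0.0 < terminal_radius_mm < root_radius_mm):
        raise ValidationError("need 0 < terminal_radius < root_radius")
    if not (0.0 < asymmetry <= 1.0):
        raise ValidationError("asymmetry must lie in (0, 1]")
    if murray_exponent <= 0:
        raise ValidationError("murray exponent must be positive")
    rng = np.random.default_rng(seed)
    g = murray_exponent
    vessels: list[DonorVessel] = []
    next_id = id_offset

    def emit(parent: int, radius: float) -> int:
        nonlocal next_id
        vid = next_id
        next_id += 1
        vessels.append(
            DonorVessel(vid, parent, length_to_radius_ratio * radius, radius, label)
        )
        return vid

    stack = [(emit(-1, root_radius_mm), root_radius_mm)]
    while stack:
        vid, r = stack.pop()
        if r < terminal_radius_mm:
            continue
        xi = 1.0 if asymmetry == 1.0 else float(rng.uniform(asymmetry, 1.0))
        # r1/r2 = xi with r1^g + r2^g = r^g
        r2 = r / (1.0 + xi**g) ** (1.0 / g)
        r1 = xi * r2
        # push larger child last so ids follow a stable depth-first order
        stack.append((emit(vid, r1), r1))
        stack.append((emit(vid, r2), r2))
    return DonorTree(vessels)


def generate_synthetic_donor(
    root_radii_mm: Mapping[str, float],
    terminal_radius_mm: float = 0.4,
    length_to_radius_ratio: float = 20.0,
    murray_exponent: float = 3.0,
    asymmetry: float = 0.8,
    seed: int = 0,
) -> DonorTree:
    """One synthetic subtree per major cerebral artery, in a single DonorTree.

    Per-label seeds are derived deterministically from ``seed``.
    """
    vessels: list[DonorVessel] = []
    offset = 0
    for k, lbl in enumerate(sorted(root_radii_mm)):
        sub = generate_synthetic_cerebral_tree(
            root_radii_mm[lbl],
            terminal_radius_mm,
            length_to_radius_ratio,
            murray_exponent,
            asymmetry,
            seed=(seed * 1009 + k) % (2**31 - 1),
            label=lbl,
            id_offset=offset,
        )
        vessels.extend(sub.vessels.values())
        offset += len(sub.vessels)
    return DonorTree(vessels)


def attach_donor_tree(patient: ArterialNetwork, donor: DonorTree) -> ArterialNetwork:
    """Graft donor cerebral subtrees onto the matching patient leaves.

    For every major cerebral label: the donor's copy of the major artery (the
    subtree root) is identified with the patient vessel of the same label, all
    radii downstream of it are multiplied by the single ratio
    ``r_patient / r_donor_root`` (preserving any scaling law between donor
    vessels), and the scaled child subtrees are attached at the patient leaf.
    The donor leaves become the new outlets, inheriting the patient outlet tag.
    """
    attach_map: dict[str, str] = getattr(patient, "attachment_points", None) or {}
    if not attach_map:
        attach_map = {
            s.major_label: s.name
            for s in patient.segments.values()
            if s.major_label in MAJOR_CEREBRAL_LABELS
        }
    new_segments = [replace(s) for s in patient.segments.values()]
    new_junctions = [list(j) for j in patient.junctions]
    outlet_tags = dict(patient._outlet_tags)
    patient_leaves = dict(patient.outlets)

    for label in donor.labels:
        if label not in attach_map:
            raise AttachmentError(f"no patient attachment point for label {label!r}")
        host_name = attach_map[label]
        if host_name not in patient.segments:
            raise AttachmentError(f"attachment vessel {host_name!r} missing: {label!r}")
        if patient_leaves.get(host_name) != DISTAL:
            raise AttachmentError(
                f"patient vessel {host_name!r} for label {label!r} is not a free leaf"
            )
        host = patient.segments[host_name]
        root = donor.subtree_root(label)
        ratio = host.r_dist_mm / root.radius_mm
        tag = patient.outlet_tag(host_name)

        def add(vid: int, parent_seg: str) -> None:
            kids = sorted(donor.children[vid])
            if not kids:
                return
            jct = [(parent_seg, DISTAL)]
            for kid in kids:
                v = donor.vessels[kid]
                seg = VesselSegment(
                    name=f"{label}:{kid}",
                    length_mm=v.length_mm,
                    r_prox_mm=v.radius_mm * ratio,
                    r_dist_mm=v.radius_mm * ratio,
                    youngs_modulus_pa=host.youngs_modulus_pa,
                    poisson_ratio=host.poisson_ratio,
                    major_label=label,
                )
                new_segments.append(seg)
                outlet_tags[seg.name] = tag
                jct.append((seg.name, PROXIMAL))
            new_junctions.append(jct)
            for kid in kids:
                add(kid, f"{label}:{kid}")

        add(root.id, host_name)

    net = ArterialNetwork(
        new_segments,
        new_junctions,
        inlet=patient.inlet,
        outlet_tags=outlet_tags,
        default_outlet_tag=patient._default_outlet_tag,
        co_fractions=patient.co_fractions,
    )
    net.attachment_points = attach_map
    return net


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize_network(
    net: ArterialNetwork, max_spacing_mm: float = 10.0, min_nodes: int = 3
) -> ArterialNetwork:
    """Place uniform axial nodes on every segment (in place; returns ``net``).

    Node count is ``max(min_nodes, ceil(L / max_spacing) + 1)``, which keeps
    the spacing at or below ``max_spacing_mm`` and gives even the shortest
    communicating arteries at least ``min_nodes`` nodes.
    """
    if max_spacing_mm <= 0 or min_nodes < 2:
        raise ValidationError("need positive spacing and at least two nodes")
    for seg in net.segments.values():
        n = max(min_nodes, math.ceil(seg.length_mm / max_spacing_mm) + 1)
        seg.node_positions_mm = np.linspace(0.0, seg.length_mm, n)
    return net


# ---------------------------------------------------------------------------
# lumped resistances
# ---------------------------------------------------------------------------

def poiseuille_resistance(
    length_mm: float, radius_mm: float, viscosity: float = DEFAULT_VISCOSITY
) -> float:
    """Steady laminar (Poiseuille) resistance 8 mu L / (pi r^4) in Pa s m^-3."""
    if radius_mm <= 0 or length_mm < 0:
        raise ValidationError("non-positive geometry")
    L = length_mm * 1e-3
    r = radius_mm * 1e-3
    return 8.0 * viscosity * L / (math.pi * r**4)


def subtree_resistance(
    tree: DonorTree, root_id: int | None = None, viscosity: float = DEFAULT_VISCOSITY
) -> float:
    """Equivalent resistance of a leaf-terminated subtree, leaves to root.

    Per-segment Poiseuille resistances combine serially along a vessel's path
    and in parallel across sibling subtrees:
    ``R_eq(v) = R_seg(v) + 1 / sum_children(1 / R_eq(child))``.
    """
    if root_id is None:
        roots = [v.id for v in tree.vessels.values() if v.parent_id < 0]
        if len(roots) != 1:
            raise ValidationError("tree has multiple roots; pass root_id")
        root_id = roots[0]

    def req(vid: int) -> float:
        v = tree.vessels[vid]
        r = poiseuille_resistance(v.length_mm, v.radius_mm, viscosity)
        kids = tree.children[vid]
        if kids:
            r += 1.0 / sum(1.0 / req(k) for k in kids)
        return r

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        return req(root_id)
    finally:
        sys.setrecursionlimit(old)


def donor_path_resistances(
    tree: DonorTree, label: str, viscosity: float = DEFAULT_VISCOSITY
) -> dict[int, float]:
    """Serial path resistance from just below the subtree root to each leaf.

    The root segment itself is excluded: at attachment it is identified with
    the patient's own copy of the major artery, which the 1D solver resolves.
    """
    root = tree.subtree_root(label)
    out: dict[int, float] = {}
    stack: list[tuple[int, float]] = [(root.id, 0.0)]
    while stack:
        vid, acc = stack.pop()
        v = tree.vessels[vid]
        here = acc
        if vid != root.id:
            here += poiseuille_resistance(v.length_mm, v.radius_mm, viscosity)
        kids = tree.children[vid]
        if not kids and vid != root.id:
            out[vid] = here
        for k in kids:
            stack.append((k, here))
    return out
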