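"""Perfusion-territory estimation on a triangulated pial surface.

Each cerebral outlet of the 1D model is mapped to a connected set of surface
triangles sized by Murray's law (territory fraction proportional to the
cubed outlet radius), confined to the major-artery region the outlet belongs
to (left/right ACA, MCA, PCA, cerebellum, brainstem).  Distances between
triangles are geodesic graph distances (Dijkstra on the share-a-vertex
adjacency of triangle centres), with a Euclidean option for flat patches.
The outlet's mean volume flow is then spread uniformly over its territory.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from heapq import heappop, heappush

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .anatomy import ValidationError

__all__ = [
    "SurfaceMesh",
    "SurfaceGraph",
    "TerritoryAssignment",
    "SurfaceFlowMap",
    "REGION_LABELS",
    "murray_fractions",
    "element_counts",
    "build_surface_graph",
    "assign_territories",
    "map_flow_to_surface",
    "save_flow_map_vtk",
    "generate_synthetic_pial_mesh",
    "load_surface_mesh",
    "save_surface_mesh",
    "load_region_labels",
    "save_region_labels",
    "RegionError",
]

REGION_LABELS = (
    "L ACA", "R ACA", "L MCA", "R MCA", "L PCA", "R PCA", "cerebellum", "brainstem",
)


class RegionError(ValueError):
    """A major-artery region is missing, unlabeled or disconnected."""


# ---------------------------------------------------------------------------
# mesh container and I/O
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated pial surface (mm) with one major-region label per triangle."""

    vertices: np.ndarray  # (nv, 3) mm
    triangles: np.ndarray  # (nt, 3) vertex indices
    region: np.ndarray  # (nt,) str labels

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.region = np.asarray(self.region, dtype=object)
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValidationError("triangles must be (n, 3) vertex triples")
        if len(self.region) != len(self.triangles):
            raise ValidationError("every triangle needs a region label")
        if any(lbl is None or str(lbl) == "" for lbl in self.region):
            raise ValidationError("empty region label")

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    @property
    def areas(self) -> np.ndarray:
        """Per-triangle area [mm^2] from the cross product."""
        p = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def region_triangles(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.region == label)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)


def load_surface_mesh(path, labels_path=None, default_region: str | None = None) -> SurfaceMesh:
    """Read STL/OBJ (via trimesh) or legacy-ASCII VTK polydata.

    Region labels come from VTK cell data named ``region`` when present,
    otherwise from a ``labels_path`` CSV (triangle_id, region), otherwise
    every triangle gets ``default_region``.
    """
    path = str(path)
    labels = None
    if path.lower().endswith(".vtk"):
        verts, tris, labels = _read_legacy_vtk(path)
    else:
        tm = trimesh.load(path, force="mesh", process=False)
        verts, tris = np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64)
    if labels_path is not None:
        labels = load_region_labels(labels_path, len(tris))
    if labels is None:
        if default_region is None:
            raise ValidationError("no region labels: pass labels_path or default_region")
        labels = np.array([default_region] * len(tris), dtype=object)
    return SurfaceMesh(verts, tris, labels)


def save_surface_mesh(mesh: SurfaceMesh, path, labels_path=None) -> None:
    """Write STL/OBJ via trimesh, or legacy-ASCII VTK with region cell data."""
    path = str(path)
    if path.lower().endswith(".vtk"):
        _write_legacy_vtk(mesh, path)
    else:
        mesh.to_trimesh().export(path)
    if labels_path is not None:
        save_region_labels(mesh.region, labels_path)


def load_region_labels(path, n_triangles: int) -> np.ndarray:
    df = pd.read_csv(path)
    labels = np.empty(n_triangles, dtype=object)
    labels[:] = None
    labels[df["triangle_id"].to_numpy()] = df["region"].astype(str).to_numpy()
    if any(l is None for l in labels):
        raise ValidationError("label file does not cover every triangle")
    return labels


def save_region_labels(labels: np.ndarray, path) -> None:
    pd.DataFrame(
        {"triangle_id": np.arange(len(labels)), "region": labels}
    ).to_csv(path, index=False)


_REGION_CODES = {lbl: i for i, lbl in enumerate(REGION_LABELS)}


def _read_legacy_vtk(path):
    with open(path) as fh:
        tokens_lines = fh.read().splitlines()
    verts, tris, labels = None, None, None
    i = 0
    while i < len(tokens_lines):
        line = tokens_lines[i].split()
        if not line:
            i += 1
            continue
        key = line[0].upper()
        if key == "POINTS":
            n = int(line[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(t) for t in tokens_lines[i].split())
                i += 1
            verts = np.asarray(vals).reshape(n, 3)
        elif key == "POLYGONS":
            n = int(line[1])
            vals = []
            i += 1
            while len(vals) < 4 * n:
                vals.extend(int(t) for t in tokens_lines[i].split())
                i += 1
            arr = np.asarray(vals, dtype=np.int64).reshape(n, 4)
            if not np.all(arr[:, 0] == 3):
                raise ValidationError("VTK polydata contains non-triangle cells")
            tris = arr[:, 1:]
        elif key == "SCALARS" and len(line) > 1 and line[1] == "region":
            i += 2  # skip LOOKUP_TABLE line
            vals = []
            while i < len(tokens_lines) and len(vals) < len(tris):
                vals.extend(int(t) for t in tokens_lines[i].split())
                i += 1
            inv = {v: k for k, v in _REGION_CODES.items()}
            labels = np.array([inv.get(v, str(v)) for v in vals], dtype=object)
        else:
            i += 1
    if verts is None or tris is None:
        raise ValidationError(f"{path}: not a triangulated legacy-VTK polydata file")
    return verts, tris, labels


def _write_legacy_vtk(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\npial surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} float\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_DATA {mesh.n_triangles}\n")
        fh.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        codes = [_REGION_CODES.get(str(l), -1) for l in mesh.region]
        for c in codes:
            fh.write(f"{c}\n")


# ---------------------------------------------------------------------------
# surface graph
# ---------------------------------------------------------------------------

@dataclass
class SurfaceGraph:
    """Triangle-adjacency graph: nodes are triangle centres, edges join
    triangles sharing a vertex, weighted by the Euclidean centre distance."""

    adjacency: csr_matrix
    centroids: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def submatrix(self, idx: np.ndarray) -> csr_matrix:
        return self.adjacency[idx][:, idx]


def build_surface_graph(mesh: SurfaceMesh) -> SurfaceGraph:
    nt = mesh.n_triangles
    cent = mesh.centroids
    vert_to_tri: dict[int, list[int]] = {}
    for t, tri in enumerate(mesh.triangles):
        for vtx in tri:
            vert_to_tri.setdefault(int(vtx), []).append(t)
    rows, cols = [], []
    for tris in vert_to_tri.values():
        for a_i in range(len(tris)):
            for b_i in range(a_i + 1, len(tris)):
                rows.append(tris[a_i])
                cols.append(tris[b_i])
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    w = np.linalg.norm(cent[rows] - cent[cols], axis=1)
    if np.any(w <= 0):
        raise ValidationError("degenerate mesh: coincident triangle centres")
    adj = csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(nt, nt),
    )
    adj.sum_duplicates()
    # duplicate entries (two shared vertices) added up; restore the distance
    counts = csr_matrix(
        (np.ones(2 * len(w)), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(nt, nt),
    )
    counts.sum_duplicates()
    adj.data = adj.data / counts.data
    return SurfaceGraph(adj, cent)


# ---------------------------------------------------------------------------
# Murray sizing
# ---------------------------------------------------------------------------

def murray_fractions(radii) -> np.ndarray:
    """Territory fractions f_i = r_i^3 / sum r_j^3 within one region."""
    r = np.asarray(radii, dtype=float)
    if r.size == 0:
        raise ValidationError("empty outlet set")
    if np.any(r <= 0):
        raise ValidationError("outlet radii must be positive")
    r3 = r**3
    return r3 / r3.sum()


def element_counts(fractions, n_triangles: int) -> np.ndarray:
    """Integer triangle budgets n_i ~ f_i N with largest-remainder rounding.

    Counts sum to N exactly, every outlet keeps at least one triangle, and
    ties break on the lower outlet index.
    """
    f = np.asarray(fractions, dtype=float)
    if len(f) > n_triangles:
        raise ValidationError("more outlets than triangles in the region")
    ideal = f * n_triangles
    base = np.floor(ideal).astype(int)
    rem = ideal - base
    short = n_triangles - base.sum()
    order = np.lexsort((np.arange(len(f)), -rem))  # largest remainder, low index first
    for k in range(int(short)):
        base[order[k % len(f)]] += 1
    # guarantee a non-empty territory per outlet
    while np.any(base == 0):
        base[int(np.argmin(base))] += 1
        base[int(np.argmax(base))] -= 1
    return base


# ---------------------------------------------------------------------------
# territory assignment
# ---------------------------------------------------------------------------

@dataclass
class TerritoryAssignment:
    """Outlet -> triangle-set partition of the labelled pial surface."""

    outlet_ids: list[str]
    outlet_region: dict[str, str]
    fractions: dict[str, float]
    counts: dict[str, int]
    roots: dict[str, int]
    triangle_outlet: np.ndarray  # (nt,) outlet id per triangle ('' = no outlet)
    iterations: dict[str, int] = field(default_factory=dict)

    def triangles_of(self, outlet: str) -> np.ndarray:
        return np.flatnonzero(self.triangle_outlet == outlet)

    def territory_areas(self, mesh: SurfaceMesh) -> dict[str, float]:
        areas = mesh.areas
        return {o: float(areas[self.triangles_of(o)].sum()) for o in self.outlet_ids}


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "little")


def _project_outlet(
    outlet_id: str,
    position,
    region_idx: np.ndarray,
    centroids: np.ndarray,
    seed: int,
    taken: set[int],
) -> int:
    """Initial root triangle for an outlet, within its labelled region.

    With a 3D position: the nearest region triangle.  Without (the network
    data model carries no centreline coordinates), a deterministic
    pseudo-position derived from a hash of the outlet id.
    """
    if position is not None:
        d = np.linalg.norm(centroids[region_idx] - np.asarray(position, float), axis=1)
        order = np.argsort(d, kind="stable")
    else:
        rng = np.random.default_rng((_stable_hash(outlet_id) ^ (seed * 0x9E3779B9)) % 2**63)
        order = rng.permutation(len(region_idx))
    for k in order:
        t = int(region_idx[k])
        if t not in taken:
            return t
    return int(region_idx[order[0]])


def _grow_clusters(
    D: np.ndarray, counts: np.ndarray, roots: list[int], sub: csr_matrix
) -> np.ndarray:
    """Interleaved capacity-constrained connected growth.

    All clusters grow simultaneously from their roots: at every step the
    globally cheapest (root-to-triangle Dijkstra distance) claim among the
    frontier triangles of all unfilled clusters is made, so claims interleave
    by distance and every cluster stays connected by construction.  Ties
    break on (distance, cluster index, triangle index).  Once capacities are
    exhausted the remaining (walled-in) triangles are swept up by the same
    frontier growth with capacities ignored, which keeps them attached to
    their nearest territory.  D is (n_clusters, n_region).
    """
    nc, nt = D.shape
    owner = np.full(nt, -1, dtype=int)
    left = counts.copy()
    heap: list[tuple[float, int, int]] = []
    for c in range(nc):
        heappush(heap, (D[c, roots[c]], c, roots[c]))
    deferred: list[tuple[float, int, int]] = []  # over-capacity claims, phase 2

    def claim(c: int, t: int) -> None:
        owner[t] = c
        for nb in sub.indices[sub.indptr[t]:sub.indptr[t + 1]]:
            if owner[nb] == -1 and np.isfinite(D[c, nb]):
                heappush(heap, (D[c, nb], c, int(nb)))

    while heap:
        d, c, t = heappop(heap)
        if owner[t] != -1:
            continue
        if left[c] == 0:
            deferred.append((d, c, t))
            continue
        left[c] -= 1
        claim(c, t)
    if np.any(owner == -1) and deferred:
        for item in deferred:
            heappush(heap, item)
        while heap:
            d, c, t = heappop(heap)
            if owner[t] == -1:
                claim(c, t)
    return owner


def _rebalance(owner: np.ndarray, D: np.ndarray, counts: np.ndarray, sub: csr_matrix) -> None:
    """Restore Murray triangle budgets by connectivity-preserving boundary moves.

    Frontier growth can wall a cluster in below its budget while another
    overfills.  Every under-full cluster repeatedly steals the cheapest
    (by its own root distance) boundary triangle from an adjacent donor,
    preferring over-full donors but also taking from exactly-full ones --
    the deficit then hops one cluster closer to the surplus and the chain
    terminates at an over-full donor.  Moves that would disconnect the donor
    are rejected; per-triangle move counts are capped to rule out cycles.
    """
    nc = D.shape[0]
    sizes = np.bincount(owner, minlength=nc)
    moves = np.zeros(owner.shape[0], dtype=np.int8)
    budget = 20 * owner.shape[0]
    stuck: set[int] = set()
    while budget > 0:
        under = [u for u in np.flatnonzero(sizes < counts) if u not in stuck]
        if not under:
            break
        u = max(under, key=lambda k: (counts[k] - sizes[k], -k))
        # candidate donors: triangles adjacent to u's territory
        cand: list[tuple[int, float, int, int]] = []
        for t in np.flatnonzero(owner == u):
            for nb in sub.indices[sub.indptr[t]:sub.indptr[t + 1]]:
                c = owner[nb]
                if c != u and sizes[c] > 1 and moves[nb] < 3 and np.isfinite(D[u, nb]):
                    tier = 0 if sizes[c] > counts[c] else 1
                    cand.append((tier, float(D[u, nb]), int(nb), int(c)))
        cand.sort()
        moved = False
        for tier, d, t, c in cand:
            members = np.flatnonzero(owner == c)
            rest = members[members != t]
            ncomp, _ = connected_components(sub[rest][:, rest], directed=False)
            if ncomp == 1:
                owner[t] = u
                sizes[c] -= 1
                sizes[u] += 1
                moves[t] += 1
                moved = True
                budget -= 1
                break
        if not moved:
            stuck.add(u)


def _minimax_root(sub: csr_matrix, members: np.ndarray) -> int:
    """1-centre of a cluster: the member minimizing the maximum geodesic
    distance to the other members (distances through the whole region)."""
    Dm = dijkstra(sub, directed=False, indices=members)
    worst = Dm[:, members].max(axis=1)
    return int(members[int(np.argmin(worst))])


def assign_territories(
    graph: SurfaceGraph,
    mesh: SurfaceMesh,
    outlets: pd.DataFrame,
    metric: str = "dijkstra",
    max_iter: int = 50,
    seed: int = 0,
) -> TerritoryAssignment:
    """Partition each major region among its outlets, Murray-sized.

    ``outlets`` needs columns ``outlet``, ``region``, ``radius_mm`` and may
    carry ``x, y, z`` projection coordinates.  Per region: project outlets to
    initial root triangles; grow capacity-constrained clusters by nearest
    geodesic distance in interleaved rounds; move each root to its cluster's
    1-centre; iterate until the assignment is stable; then join any
    unassigned triangles to the nearest cluster.
    """
    if metric not in ("dijkstra", "euclidean"):
        raise ValidationError(f"unknown metric {metric!r}")
    required = {"outlet", "region", "radius_mm"}
    if not required <= set(outlets.columns):
        raise ValidationError(f"outlet table needs columns {sorted(required)}")
    nt = mesh.n_triangles
    if len(outlets) >= nt:
        raise ValidationError("more outlets than surface triangles")
    triangle_outlet = np.full(nt, "", dtype=object)
    out = TerritoryAssignment(
        outlet_ids=list(outlets["outlet"]),
        outlet_region=dict(zip(outlets["outlet"], outlets["region"])),
        fractions={},
        counts={},
        roots={},
        triangle_outlet=triangle_outlet,
    )
    has_pos = {"x", "y", "z"} <= set(outlets.columns)
    for region, grp in outlets.groupby("region", sort=True):
        region_idx = mesh.region_triangles(region)
        if region_idx.size == 0:
            raise RegionError(f"mesh has no triangles labelled {region!r}")
        sub = graph.submatrix(region_idx)
        ncomp, _ = connected_components(sub, directed=False)
        if ncomp != 1:
            raise RegionError(f"region {region!r} is disconnected in the surface graph")
        ids = list(grp["outlet"])
        fr = murray_fractions(grp["radius_mm"].to_numpy())
        counts = element_counts(fr, region_idx.size)
        for o, f, c in zip(ids, fr, counts):
            out.fractions[o] = float(f)
            out.counts[o] = int(c)
        taken: set[int] = set()
        roots_local = []
        for k, o in enumerate(ids):
            pos = grp.iloc[k][["x", "y", "z"]].to_numpy(float) if has_pos else None
            t = _project_outlet(o, pos, region_idx, graph.centroids, seed, taken)
            taken.add(t)
            roots_local.append(int(np.flatnonzero(region_idx == t)[0]))
        seen: set[bytes] = set()
        it = 0
        for it in range(1, max_iter + 1):
            if metric == "dijkstra":
                D = dijkstra(sub, directed=False, indices=roots_local)
            else:
                D = np.linalg.norm(
                    graph.centroids[region_idx][None, :, :]
                    - graph.centroids[region_idx[roots_local]][:, None, :],
                    axis=2,
                )
            owner = _grow_clusters(D, counts, roots_local, sub)
            key = owner.tobytes()
            if key in seen:  # stable assignment or a limit cycle: stop
                break
            seen.add(key)
            new_roots = []
            for c in range(len(ids)):
                members = np.flatnonzero(owner == c)
                if members.size == 0:
                    new_roots.append(roots_local[c])
                elif metric == "dijkstra":
                    new_roots.append(_minimax_root(sub, members))
                else:
                    cm = graph.centroids[region_idx[members]]
                    worst = np.linalg.norm(cm[:, None] - cm[None, :], axis=2).max(axis=1)
                    new_roots.append(int(members[int(np.argmin(worst))]))
            if new_roots == roots_local and it > 1:
                break
            roots_local = new_roots
        else:
            warnings.warn(f"territory iteration in {region!r} hit max_iter={max_iter}")
        # sweep: any unassigned triangle joins the nearest cluster
        un = np.flatnonzero(owner == -1)
        if un.size:
            owner[un] = np.argmin(D[:, un], axis=0)
        _rebalance(owner, D, counts, sub)
        for c, o in enumerate(ids):
            out.triangle_outlet[region_idx[owner == c]] = o
            out.roots[o] = int(region_idx[roots_local[c]])
        out.iterations[region] = it
    return out


# ---------------------------------------------------------------------------
# flow mapping
# ---------------------------------------------------------------------------

@dataclass
class SurfaceFlowMap:
    """Per-triangle volumetric flow [ml/min] and flux [ml/min/mm^2]."""

    table: pd.DataFrame  # triangle_id, outlet_id, region, area_mm2, flow, flux

    @property
    def triangle_flow(self) -> np.ndarray:
        return self.table["flow_ml_min"].to_numpy()


def map_flow_to_surface(
    assignment: TerritoryAssignment,
    outlet_mean_flows: dict[str, float],
    mesh: SurfaceMesh,
) -> SurfaceFlowMap:
    """Spread each outlet's mean flow uniformly over its territory.

    Triangle flow is the outlet flow times the triangle's area fraction of
    the territory; the flux (flow per area) is uniform within a territory.
    """
    missing = [o for o in assignment.outlet_ids if o not in outlet_mean_flows]
    if missing:
        raise ValidationError(f"no flow record for outlets {missing[:5]}")
    areas = mesh.areas
    nt = mesh.n_triangles
    flow = np.zeros(nt)
    flux = np.zeros(nt)
    for o in assignment.outlet_ids:
        tri = assignment.triangles_of(o)
        if tri.size == 0:
            continue
        terr_area = areas[tri].sum()
        q = outlet_mean_flows[o]
        flow[tri] = q * areas[tri] / terr_area
        flux[tri] = q / terr_area
    df = pd.DataFrame(
        {
            "triangle_id": np.arange(nt),
            "outlet_id": assignment.triangle_outlet,
            "region": mesh.region,
            "area_mm2": areas,
            "flow_ml_min": flow,
            "flux_ml_min_mm2": flux,
        }
    )
    return SurfaceFlowMap(df)


def save_flow_map_vtk(mesh: SurfaceMesh, flow_map: SurfaceFlowMap, path) -> None:
    """Legacy-ASCII VTK polydata with region/flow/flux cell data, for viewers."""
    _write_legacy_vtk(mesh, path)
    with open(path, "a") as fh:
        fh.write("SCALARS flow_ml_min float 1\nLOOKUP_TABLE default\n")
        for v in flow_map.table["flow_ml_min"]:
            fh.write(f"{v:.6g}\n")
        fh.write("SCALARS flux_ml_min_mm2 float 1\nLOOKUP_TABLE default\n")
        for v in flow_map.table["flux_ml_min_mm2"]:
            fh.write(f"{v:.6g}\n")


# ---------------------------------------------------------------------------
# synthetic pial surface
# ---------------------------------------------------------------------------

def generate_synthetic_pial_mesh(
    subdivisions: int = 4,
    radius_mm: float = 70.0,
    region_layout: dict | None = None,
    seed: int = 0,
) -> SurfaceMesh:
    """Icosphere stand-in for a pial surface with eight contiguous regions.

    Near-uniform triangles by construction (subdivided icosahedron).  The
    labelling splits a lower cap into brainstem and cerebellum bands and the
    remaining 'cerebrum' into hemispheres with anterior (ACA), middle (MCA)
    and posterior (PCA) sectors, giving realistic area proportions with the
    MCA territories largest.  ``seed`` applies a small random rotation to
    the labelling frame; the geometry is deterministic.
    """
    layout = {"z_brainstem": -0.75, "z_cerebellum": -0.45, "y_split": 0.45}
    layout.update(region_layout or {})
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    verts = np.asarray(ico.vertices, dtype=float)
    tris = np.asarray(ico.faces, dtype=np.int64)
    cent = verts[tris].mean(axis=1)
    n = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    ang = rng.uniform(-0.05, 0.05, size=3)  # small labelling-frame jitter [rad]
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    rot = (
        np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        @ np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        @ np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    )
    n = n @ rot.T
    labels = np.empty(len(tris), dtype=object)
    z, y, x = n[:, 2], n[:, 1], n[:, 0]
    labels[z < layout["z_brainstem"]] = "brainstem"
    band = (z >= layout["z_brainstem"]) & (z < layout["z_cerebellum"])
    labels[band] = "cerebellum"
    cer = z >= layout["z_cerebellum"]
    for side, mask in (("L", cer & (x < 0)), ("R", cer & (x >= 0))):
        labels[mask & (y > layout["y_split"])] = f"{side} ACA"
        labels[mask & (y < -layout["y_split"])] = f"{side} PCA"
        labels[mask & (np.abs(y) <= layout["y_split"])] = f"{side} MCA"
    mesh = SurfaceMesh(verts, tris, labels)
    _heal_region_components(mesh)
    return mesh


def _heal_region_components(mesh: SurfaceMesh, max_pass: int = 10) -> None:
    """Relabel stray disconnected slivers to the dominant neighbouring region."""
    graph = build_surface_graph(mesh)
    adj = graph.adjacency
    for _ in range(max_pass):
        changed = False
        for label in np.unique(mesh.region.astype(str)):
            idx = mesh.region_triangles(label)
            sub = graph.submatrix(idx)
            ncomp, comp = connected_components(sub, directed=False)
            if ncomp <= 1:
                continue
            sizes = np.bincount(comp)
            keep = int(np.argmax(sizes))
            for c in range(ncomp):
                if c == keep:
                    continue
                for t in idx[comp == c]:
                    nbrs = adj.indices[adj.indptr[t]:adj.indptr[t + 1]]
                    nbr_lbl = [str(l) for l in mesh.region[nbrs] if str(l) != label]
                    if nbr_lbl:
                        vals, cnts = np.unique(nbr_lbl, return_counts=True)
                        mesh.region[t] = vals[int(np.argmax(cnts))]
                        changed = True
        if not changed:
            break
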