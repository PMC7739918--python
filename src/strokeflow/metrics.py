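"""Pulsatility indices and waveform summaries of a converged run.

The (Gosling) pulsatility index (max - min) / mean of a pressure or velocity
waveform over one cardiac cycle reflects the downstream vascular resistance;
in this model it decays with distance from the heart once the circle of
Willis is passed, as high frequencies are damped in the stiff small vessels.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .anatomy import DISTAL, PROXIMAL, MAJOR_CEREBRAL_LABELS, ArterialNetwork, ValidationError
from .solver import SimulationResult

__all__ = [
    "pressure_pulsatility_index",
    "velocity_pulsatility_index",
    "distance_from_heart",
    "pulsatility_summary",
    "paths_beyond_cow",
]


def pressure_pulsatility_index(series: np.ndarray) -> float:
    """(p_max - p_min) / p_mean over one cycle; requires a positive mean."""
    s = np.asarray(series, dtype=float)
    mean = s.mean()
    if mean <= 0:
        raise ValidationError("pressure PI needs a positive mean pressure")
    return float((s.max() - s.min()) / mean)


def velocity_pulsatility_index(series: np.ndarray) -> float:
    """(v_max - v_min) / v_mean over one cycle; undefined at zero mean."""
    s = np.asarray(series, dtype=float)
    mean = s.mean()
    if abs(mean) <= 1e-12 * max(np.abs(s).max(), 1e-300):
        raise ValidationError("velocity PI undefined for zero mean (occluded vessel)")
    return float((s.max() - s.min()) / mean)


def _pi_from_extrema(vmax: float, vmin: float, vmean: float) -> float:
    return (vmax - vmin) / vmean


def _junction_graph(net: ArterialNetwork) -> tuple[nx.MultiGraph, object]:
    g = net.segment_graph()
    inlet_node = ("E", net.inlet, PROXIMAL)
    return g, inlet_node


def distance_from_heart(net: ArterialNetwork, segment: str, x_mm: float | None = None) -> float:
    """Path length [m] from the inlet to axial position ``x_mm`` of ``segment``.

    Shortest route along segment axes; through the communicating arteries of
    the CoW several routes may exist and the minimum is taken.  Defaults to
    the segment midpoint.
    """
    if segment not in net.segments:
        raise ValidationError(f"unknown segment {segment!r}")
    seg = net.segments[segment]
    if x_mm is None:
        x_mm = 0.5 * seg.length_mm
    if not 0.0 <= x_mm <= seg.length_mm:
        raise ValidationError("position outside the segment")
    g, inlet_node = _junction_graph(net)
    # remove the segment's own edge so the distance to each of its ends is
    # measured through the rest of the network
    end_nodes = {}
    for u, v, k in g.edges(keys=True):
        if k == segment:
            end_nodes[PROXIMAL], end_nodes[DISTAL] = u, v
            # segment_graph orients edge (proximal_node, distal_node)
            g.remove_edge(u, v, k)
            break
    dist = nx.single_source_dijkstra_path_length(g, inlet_node, weight="length_mm")
    best = np.inf
    dprox = dist.get(end_nodes[PROXIMAL], np.inf)
    ddist = dist.get(end_nodes[DISTAL], np.inf)
    best = min(dprox + x_mm, ddist + (seg.length_mm - x_mm))
    if not np.isfinite(best):
        raise ValidationError(f"segment {segment!r} unreachable from the inlet")
    return float(best) * 1e-3


def pulsatility_summary(result: SimulationResult, net: ArterialNetwork | None = None) -> pd.DataFrame:
    """Per-segment pulsatility table from last-cycle mid-node waveforms.

    Pressure PI always; velocity PI missing (NaN) for occluded or zero-mean
    segments rather than 0 or infinity.  Distances are from the heart to the
    segment midpoint.
    """
    net = net or result.model.net
    rows = []
    for nm in result.model.segment_names:
        mid = result.mid_node(nm)
        p_mean = result.mean_p[mid]
        v_mean = result.mean_v[mid]
        pip = _pi_from_extrema(result.p_max[mid], result.p_min[mid], p_mean)
        if v_mean != 0.0 and np.isfinite(v_mean):
            piv = _pi_from_extrema(result.v_max[mid], result.v_min[mid], v_mean)
        else:
            piv = np.nan
        rows.append(
            {
                "segment": nm,
                "label": net.segments[nm].major_label,
                "distance_m": distance_from_heart(net, nm),
                "p_mean_pa": p_mean,
                "p_min_pa": result.p_min[mid],
                "p_max_pa": result.p_max[mid],
                "v_mean_ms": v_mean,
                "v_min_ms": result.v_min[mid],
                "v_max_ms": result.v_max[mid],
                "pi_pressure": pip,
                "pi_velocity": piv,
            }
        )
    for nm in result.model.occluded_segments:
        rows.append(
            {
                "segment": nm,
                "label": net.segments[nm].major_label,
                "distance_m": distance_from_heart(net, nm),
                "p_mean_pa": np.nan,
                "p_min_pa": np.nan,
                "p_max_pa": np.nan,
                "v_mean_ms": 0.0,
                "v_min_ms": 0.0,
                "v_max_ms": 0.0,
                "pi_pressure": np.nan,
                "pi_velocity": np.nan,
            }
        )
    return pd.DataFrame(rows)


def paths_beyond_cow(net: ArterialNetwork) -> list[list[str]]:
    """Root-to-leaf segment chains through the cerebral trees.

    Each path starts at a major cerebral trunk (MCA, ACA A2 or PCA P2) and
    follows distal-to-proximal junction links down to a pial leaf.
    """
    children: dict[str, list[str]] = {nm: [] for nm in net.segments}
    for jct in net.junctions:
        parents = [nm for nm, e in jct if e == DISTAL]
        kids = [nm for nm, e in jct if e == PROXIMAL]
        if len(parents) == 1:
            children[parents[0]].extend(kids)
    trunks = [
        nm
        for nm, seg in net.segments.items()
        if seg.major_label in MAJOR_CEREBRAL_LABELS and ":" not in nm
    ]
    paths: list[list[str]] = []
    for trunk in sorted(trunks):
        stack = [[trunk]]
        while stack:
            path = stack.pop()
            kids = children[path[-1]]
            if not kids:
                if len(path) > 1:
                    paths.append(path)
                continue
            for k in sorted(kids):
                stack.append(path + [k])
    return paths
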