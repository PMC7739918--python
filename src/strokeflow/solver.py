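"""1D pulsatile blood-flow solver on an assembled arterial network.

The cross-sectionally averaged continuity and momentum equations

    dA/dt + d(A v)/dx = 0
    dv/dt + (2a-1) v dv/dx + (a-1) (v^2/A) dA/dx + (1/rho) dp/dx
        = -2 a pi mu v / ((a-1) rho A)

(a the momentum correction factor) are closed by the thin-walled elastic
tube law p = pref + (beta/A0)(sqrt(A) - sqrt(A0)) and integrated with the
explicit second-order MacCormack scheme under a CFL time step.  Segments
couple at junctions through extrapolated Riemann invariants, conservation of
mass and continuity of total pressure, solved per junction by Newton's
method.  The heart prescribes a periodic volumetric inflow; every outlet
carries a calibrated three-element windkessel; a clot is a reflective
(zero-velocity, zero pressure-gradient) internal face that severs its
downstream subtree.  Cycles repeat from rest (zero velocity, diastolic
pressure) until the cycle-to-cycle relative pressure change drops below
tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .anatomy import DISTAL, PROXIMAL, ArterialNetwork, ValidationError
from .calibration import CardiacParameters, WindkesselOutlet, allocate_outlets

__all__ = [
    "BloodProperties",
    "SolverOptions",
    "InletWaveform",
    "Occlusion",
    "SimulationResult",
    "beta_coefficient",
    "tube_law_pressure",
    "tube_law_area",
    "wave_speed",
    "inlet_flow",
    "default_inlet_template",
    "maccormack_step",
    "solve_junction",
    "apply_clot",
    "convergence_metric",
    "run_pulsatile_simulation",
    "NumericalBlowupError",
    "JunctionSolveError",
    "NonConvergenceWarning",
]


class NumericalBlowupError(RuntimeError):
    pass


class JunctionSolveError(RuntimeError):
    pass


class NonConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties; alpha > 1 (a flat profile makes drag singular)."""

    density: float = 1050.0  # kg/m^3
    viscosity: float = 0.0035  # Pa s
    momentum_correction: float = 1.1

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValidationError("density and viscosity must be positive")
        if self.momentum_correction <= 1.0:
            raise ValidationError("momentum correction factor must exceed 1")

    @property
    def friction_coefficient(self) -> float:
        """Kf in the drag term -Kf v / A: 2 a pi mu / ((a - 1) rho) [m^2/s]."""
        a = self.momentum_correction
        return 2.0 * a * math.pi * self.viscosity / ((a - 1.0) * self.density)


@dataclass(frozen=True)
class SolverOptions:
    cfl: float = 0.8
    max_cycles: int = 20
    snapshots_per_cycle: int = 100
    tolerance: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.cfl <= 1:
            raise ValidationError("CFL number must lie in (0, 1]")
        if self.max_cycles < 2 or self.snapshots_per_cycle < 2:
            raise ValidationError("need at least 2 cycles and 2 snapshots")


# ---------------------------------------------------------------------------
# tube law
# ---------------------------------------------------------------------------

def beta_coefficient(E_pa: float, h_m: float, nu: float = 0.5) -> float:
    """Tube-law stiffness beta = sqrt(pi) E h / (1 - nu^2) [Pa m]."""
    if not 0.0 <= nu < 1.0:
        raise ValidationError("Poisson ratio must lie in [0, 1)")
    if E_pa <= 0 or h_m <= 0:
        raise ValidationError("E and h must be positive")
    return math.sqrt(math.pi) * E_pa * h_m / (1.0 - nu * nu)


def tube_law_pressure(A, A0, beta, pref=0.0):
    """p = pref + (beta/A0)(sqrt(A) - sqrt(A0))."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValidationError("area must be positive")
    out = pref + (beta / A0) * (np.sqrt(A) - np.sqrt(A0))
    return float(out) if out.ndim == 0 else out

def tube_law_area(p, A0, beta, pref=0.0):
    """Inverse tube law; defined while sqrt(A) = sqrt(A0) + (p-pref) A0/beta > 0."""
    p = np.asarray(p, dtype=float)
    root = np.sqrt(A0) + (p - pref) * A0 / beta
    if np.any(root <= 0):
        raise ValidationError("pressure below the collapse limit of the tube law")
    out = root**2
    return float(out) if out.ndim == 0 else out


def wave_speed(A, A0, beta, rho=1050.0):
    """Local tube-law wave speed c = sqrt(beta sqrt(A) / (2 rho A0))."""
    out = np.sqrt(beta * np.sqrt(np.asarray(A, dtype=float)) / (2.0 * rho * A0))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# inlet waveform
# ---------------------------------------------------------------------------

class InletWaveform:
    """Periodic unit-period inflow template with unit integral.

    Tabulated on a uniform phase grid and evaluated by linear interpolation;
    ``Q(t) = SV * template(phase) / T`` then integrates to exactly one stroke
    volume per beat.
    """

    def __init__(self, phases: np.ndarray, values: np.ndarray) -> None:
        phases = np.asarray(phases, dtype=float)
        values = np.asarray(values, dtype=float)
        if phases[0] != 0.0 or phases[-1] != 1.0:
            raise ValidationError("template phases must span [0, 1]")
        integral = np.trapezoid(values, phases)
        if integral <= 0:
            raise ValidationError("template must have positive integral")
        self.phases = phases
        self.values = values / integral

    def __call__(self, phase):
        return np.interp(np.mod(phase, 1.0), self.phases, self.values)

    @classmethod
    def from_samples(cls, phases, values) -> "InletWaveform":
        return cls(phases, values)


def default_inlet_template(n: int = 512, systole_fraction: float = 1.0 / 3.0) -> InletWaveform:
    """Half-sine systolic ejection over the first third of the cycle.

    A deliberately simple stand-in for a measured aortic flow waveform; mean
    flows are insensitive to the shape, pulsatility indices are not.
    """
    ph = np.linspace(0.0, 1.0, n)
    val = np.where(ph < systole_fraction, np.sin(np.pi * ph / systole_fraction), 0.0)
    return InletWaveform(ph, val)


def inlet_flow(t, sv_ml: float, hr_per_min: float, template: InletWaveform | None = None):
    """Volumetric inflow Q(t) [m^3/s] scaled to SV per beat at the given rate."""
    if sv_ml <= 0 or hr_per_min <= 0:
        raise ValidationError("SV and HR must be positive")
    template = template or default_inlet_template()
    period = 60.0 / hr_per_min
    out = (sv_ml * 1e-6 / period) * template(np.asarray(t, dtype=float) / period)
    return float(out) if np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# occlusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Occlusion:
    """A clot in ``segment`` at fractional axial position (0, 1]."""

    segment: str
    position: float = 1.0


def apply_clot(net: ArterialNetwork, segment_id: str, position: float = 1.0) -> Occlusion:
    """Validate and return the occlusion plan for ``segment_id``.

    The clot enforces v = 0 and dp/dx = 0 at its face; every segment that is
    unreachable from the inlet without passing the clot is severed from the
    simulation and reports zero flow at venous pressure.
    """
    if segment_id not in net.segments:
        raise ValidationError(f"unknown segment {segment_id!r}")
    if segment_id == net.inlet:
        raise ValidationError("a clot on the inlet segment is not a defined scenario")
    if not 0.0 < position <= 1.0:
        raise ValidationError("clot position must lie in (0, 1]")
    return Occlusion(segment_id, position)


# ---------------------------------------------------------------------------
# compiled model
# ---------------------------------------------------------------------------

class _CompiledModel:
    """Flat-array view of a discretized network for the numba kernels."""

    def __init__(
        self,
        net: ArterialNetwork,
        blood: BloodProperties,
        cardiac: CardiacParameters,
        outlets: list[WindkesselOutlet],
        clot: Occlusion | None,
        template: InletWaveform,
        options: SolverOptions,
    ) -> None:
        self.net = net
        self.blood = blood
        self.cardiac = cardiac
        self.options = options
        self.template = template
        self.clot = clot

        occluded: set[str] = set()
        truncate_nodes: dict[str, int] = {}
        clot_faces: list[tuple[str, str]] = []  # (segment, end) reflective ends
        if clot is not None:
            occluded = set(net.downstream_segments(clot.segment))
            seg = net.segments[clot.segment]
            if seg.node_positions_mm is None:
                raise ValidationError("network must be discretized before compiling")
            n = len(seg.node_positions_mm)
            keep = int(round(clot.position * (n - 1))) + 1
            keep = min(n, max(3, keep))
            if keep < n:
                truncate_nodes[clot.segment] = keep
            clot_faces.append((clot.segment, DISTAL))

        self.occluded_segments = sorted(occluded)
        names = [net.inlet] + [
            s for s in net.segments if s != net.inlet and s not in occluded
        ]
        self.segment_names = names
        self.node_slice: dict[str, slice] = {}

        nu_nodes: list[np.ndarray] = []
        seg_start = []
        seg_n = []
        seg_dx = []
        A0_l, k1_l, beta_l, dx_l = [], [], [], []
        pos = 0
        self.seg_beta: dict[str, float] = {}
        for nm in names:
            seg = net.segments[nm]
            if seg.node_positions_mm is None:
                raise ValidationError(f"{nm}: network must be discretized first")
            x = seg.node_positions_mm
            n = truncate_nodes.get(nm, len(x))
            x = x[:n]
            if n < 3:
                raise ValidationError(f"{nm}: fewer than 3 nodes")
            r_m = seg.radius_at(x) * 1e-3
            A0 = np.pi * r_m**2
            h = seg.wall_thickness_mm * 1e-3
            beta = beta_coefficient(seg.youngs_modulus_pa, h, seg.poisson_ratio)
            self.seg_beta[nm] = beta
            dx = (x[1] - x[0]) * 1e-3
            seg_start.append(pos)
            seg_n.append(n)
            seg_dx.append(dx)
            self.node_slice[nm] = slice(pos, pos + n)
            A0_l.append(A0)
            k1_l.append(beta / A0)
            beta_l.append(np.full(n, beta))
            dx_l.append(np.full(n, dx))
            nu_nodes.append(x)
            pos += n

        self.n_nodes = pos
        self.A0 = np.concatenate(A0_l)
        self.k1 = np.concatenate(k1_l)
        self.beta_node = np.concatenate(beta_l)
        self.node_dx = np.concatenate(dx_l)
        self.sqA0 = np.sqrt(self.A0)
        self.node_x_mm = np.concatenate(nu_nodes)
        self.seg_start = np.asarray(seg_start, dtype=np.int64)
        self.seg_n = np.asarray(seg_n, dtype=np.int64)
        self.seg_dx = np.asarray(seg_dx, dtype=np.float64)

        def end_node(nm: str, end: str) -> int:
            sl = self.node_slice[nm]
            return sl.start if end == PROXIMAL else sl.stop - 1

        def end_inner(nm: str, end: str) -> int:
            sl = self.node_slice[nm]
            return sl.start + 1 if end == PROXIMAL else sl.stop - 2

        # junctions, pruned for the clot
        jct_ends: list[list[tuple[str, str]]] = []
        extra_faces: list[tuple[str, str]] = []
        for jct in net.junctions:
            kept = [
                (nm, e)
                for nm, e in jct
                if nm not in occluded and not (clot and (nm, e) in clot_faces)
                and not (nm in truncate_nodes and e == DISTAL)
            ]
            if len(kept) >= 2:
                jct_ends.append(kept)
            elif len(kept) == 1:
                extra_faces.append(kept[0])  # junction degenerated to a dead end
        ptr = [0]
        e_node, e_inner, e_sigma, e_dx = [], [], [], []
        for ends in jct_ends:
            for nm, e in ends:
                e_node.append(end_node(nm, e))
                e_inner.append(end_inner(nm, e))
                e_sigma.append(1 if e == DISTAL else -1)
                e_dx.append(self.seg_dx[self.segment_names.index(nm)])
            ptr.append(len(e_node))
        self.jct_ptr = np.asarray(ptr, dtype=np.int64)
        self.jend_node = np.asarray(e_node, dtype=np.int64)
        self.jend_inner = np.asarray(e_inner, dtype=np.int64)
        self.jend_sigma = np.asarray(e_sigma, dtype=np.int64)
        self.jend_dx = np.asarray(e_dx, dtype=np.float64)
        self.junction_ends = jct_ends

        # clot faces (named faces plus degenerated junctions)
        faces = [(nm, e) for nm, e in clot_faces if nm not in occluded] + extra_faces
        self.clot_node = np.asarray([end_node(nm, e) for nm, e in faces], dtype=np.int64)
        self.clot_inner = np.asarray([end_inner(nm, e) for nm, e in faces], dtype=np.int64)

        # outlets
        by_name = {o.outlet: o for o in outlets}
        missing = [nm for nm, _ in net.outlets if nm not in by_name]
        if missing:
            raise ValidationError(f"outlets without windkessel calibration: {missing[:5]}")
        self.active_outlets: list[WindkesselOutlet] = []
        self.occluded_outlets: list[WindkesselOutlet] = []
        o_node, o_inner, o_sigma, o_dx = [], [], [], []
        for nm, e in net.outlets:
            o = by_name[nm]
            if nm in occluded or (clot and nm == clot.segment):
                self.occluded_outlets.append(o)
                continue
            self.active_outlets.append(o)
            o_node.append(end_node(nm, e))
            o_inner.append(end_inner(nm, e))
            o_sigma.append(1 if e == DISTAL else -1)
            o_dx.append(self.seg_dx[self.segment_names.index(nm)])
        self.out_node = np.asarray(o_node, dtype=np.int64)
        self.out_inner = np.asarray(o_inner, dtype=np.int64)
        self.out_sigma = np.asarray(o_sigma, dtype=np.int64)
        self.out_dx = np.asarray(o_dx, dtype=np.float64)
        self.out_R1 = np.asarray([o.proximal_resistance for o in self.active_outlets])
        self.out_R2 = np.asarray([o.distal_resistance for o in self.active_outlets])
        self.out_C = np.asarray([o.compliance for o in self.active_outlets])
        self.out_pv = np.asarray([o.venous_pressure_pa for o in self.active_outlets])

        self.inlet_node = end_node(net.inlet, PROXIMAL)
        self.inlet_inner = end_inner(net.inlet, PROXIMAL)
        self.inlet_dx = float(self.seg_dx[0])


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Converged last-cycle summaries and waveforms of a pulsatile run."""

    model: _CompiledModel
    mean_p: np.ndarray  # per node [Pa]
    mean_v: np.ndarray  # [m/s]
    mean_q: np.ndarray  # [m^3/s]
    p_min: np.ndarray
    p_max: np.ndarray
    v_min: np.ndarray
    v_max: np.ndarray
    p_snap: np.ndarray  # (n_snap, N)
    v_snap: np.ndarray
    cycles: int
    converged: bool
    convergence_history: list[float]
    steps_last_cycle: int

    M3S_TO_MLMIN = 6.0e7

    # -- node addressing -------------------------------------------------

    def nodes_of(self, segment: str) -> slice:
        return self.model.node_slice[segment]

    def mid_node(self, segment: str) -> int:
        sl = self.nodes_of(segment)
        return sl.start + (sl.stop - sl.start - 1) // 2

    def is_occluded(self, segment: str) -> bool:
        return segment in self.model.occluded_segments

    # -- per-segment summaries -------------------------------------------

    def segment_mean_flow_mlmin(self, segment: str) -> float:
        """Cycle-averaged volumetric flow at the segment midpoint [ml/min]."""
        if self.is_occluded(segment):
            return 0.0
        return float(self.mean_q[self.mid_node(segment)] * self.M3S_TO_MLMIN)

    def velocity_waveform(self, segment: str, node: int | None = None) -> np.ndarray:
        n = self.mid_node(segment) if node is None else self.nodes_of(segment).start + node
        return self.v_snap[:, n]

    def pressure_waveform(self, segment: str, node: int | None = None) -> np.ndarray:
        n = self.mid_node(segment) if node is None else self.nodes_of(segment).start + node
        return self.p_snap[:, n]

    # -- outlet summaries ------------------------------------------------

    def outlet_table(self) -> pd.DataFrame:
        """Per-outlet mean flow [ml/min] and pressure [Pa]; occluded rows at
        zero flow and venous pressure."""
        rows = []
        for o, node in zip(self.model.active_outlets, self.model.out_node):
            rows.append(
                {
                    "outlet": o.outlet,
                    "tag": o.tag,
                    "label": o.label,
                    "radius_mm": o.radius_mm,
                    "mean_q_mlmin": self.mean_q[node] * self.M3S_TO_MLMIN,
                    "mean_p_pa": self.mean_p[node],
                    "min_p_pa": self.p_min[node],
                    "max_p_pa": self.p_max[node],
                    "occluded": False,
                }
            )
        for o in self.model.occluded_outlets:
            rows.append(
                {
                    "outlet": o.outlet,
                    "tag": o.tag,
                    "label": o.label,
                    "radius_mm": o.radius_mm,
                    "mean_q_mlmin": 0.0,
                    "mean_p_pa": o.venous_pressure_pa,
                    "min_p_pa": o.venous_pressure_pa,
                    "max_p_pa": o.venous_pressure_pa,
                    "occluded": True,
                }
            )
        return pd.DataFrame(rows)

    def node_table(self) -> pd.DataFrame:
        rows = []
        for nm in self.model.segment_names:
            sl = self.model.node_slice[nm]
            for j, g in enumerate(range(sl.start, sl.stop)):
                rows.append(
                    {
                        "segment": nm,
                        "node": j,
                        "x_mm": self.model.node_x_mm[g],
                        "mean_p_pa": self.mean_p[g],
                        "min_p_pa": self.p_min[g],
                        "max_p_pa": self.p_max[g],
                        "mean_v_ms": self.mean_v[g],
                        "min_v_ms": self.v_min[g],
                        "max_v_ms": self.v_max[g],
                        "mean_q_mlmin": self.mean_q[g] * self.M3S_TO_MLMIN,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def inlet_mean_flow_mlmin(self) -> float:
        return float(self.mean_q[self.model.inlet_node] * self.M3S_TO_MLMIN)

    def waveform_table(self, field: str = "pressure") -> pd.DataFrame:
        """Last-cycle per-node time series (rows: stored phases; columns:
        ``segment:node``), pressure [Pa] or velocity [m/s]."""
        if field not in ("pressure", "velocity"):
            raise ValidationError("field must be 'pressure' or 'velocity'")
        data = self.p_snap if field == "pressure" else self.v_snap
        cols = []
        for nm in self.model.segment_names:
            sl = self.model.node_slice[nm]
            cols.extend(f"{nm}:{j}" for j in range(sl.stop - sl.start))
        n_snap = data.shape[0]
        df = pd.DataFrame(data, columns=cols)
        df.insert(0, "phase", np.arange(1, n_snap + 1) / n_snap)
        return df


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def convergence_metric(p_i: np.ndarray, p_prev: np.ndarray) -> float:
    """Cycle-to-cycle relative pressure change ||p_i - p_{i-1}|| / ||p_i||."""
    p_i = np.ravel(p_i)
    p_prev = np.ravel(p_prev)
    if p_i.shape != p_prev.shape:
        raise ValidationError("snapshot vectors differ in length")
    denom = float(np.linalg.norm(p_i))
    if denom == 0.0:
        raise ValidationError("zero-norm pressure snapshot")
    return float(np.linalg.norm(p_i - p_prev) / denom)


def run_pulsatile_simulation(
    net: ArterialNetwork,
    blood: BloodProperties | None = None,
    cardiac: CardiacParameters | None = None,
    outlets: list[WindkesselOutlet] | None = None,
    clot: Occlusion | str | None = None,
    template: InletWaveform | None = None,
    options: SolverOptions | None = None,
) -> SimulationResult:
    """Integrate whole cardiac cycles from rest until periodic convergence.

    Initial conditions are zero velocity and diastolic pressure everywhere
    (the tube law's reference state, hence A = A0 exactly).  Stops when the
    cycle-to-cycle pressure-change norm drops below ``options.tolerance`` or
    after ``options.max_cycles`` cycles (with a warning).
    """
    blood = blood or BloodProperties()
    cardiac = cardiac or CardiacParameters()
    options = options or SolverOptions()
    template = template or default_inlet_template()
    if outlets is None:
        outlets = allocate_outlets(net, cardiac, rho=blood.density, viscosity=blood.viscosity)
    if isinstance(clot, str):
        clot = apply_clot(net, clot)
    elif clot is not None:
        clot = apply_clot(net, clot.segment, clot.position)

    m = _CompiledModel(net, blood, cardiac, outlets, clot, template, options)
    N = m.n_nodes
    pref = cardiac.p_dia_pa
    A = m.A0.copy()
    v = np.zeros(N)
    pc = np.full(len(m.active_outlets), float(cardiac.p_dia_pa))
    n_snap = options.snapshots_per_cycle
    period = cardiac.period_s
    q_scale = cardiac.sv_ml * 1e-6 / period

    p_snap = np.empty((n_snap, N))
    v_snap = np.empty((n_snap, N))
    sum_p = np.empty(N)
    sum_v = np.empty(N)
    sum_q = np.empty(N)
    p_lo = np.empty(N)
    p_hi = np.empty(N)
    v_lo = np.empty(N)
    v_hi = np.empty(N)
    err = np.zeros(1, dtype=np.int64)

    prev_snap: np.ndarray | None = None
    history: list[float] = []
    converged = False
    cycles = 0
    steps = 0
    for cyc in range(options.max_cycles):
        sum_p[:] = 0.0
        sum_v[:] = 0.0
        sum_q[:] = 0.0
        p_lo[:] = np.inf
        p_hi[:] = -np.inf
        v_lo[:] = np.inf
        v_hi[:] = -np.inf
        status, steps = K.advance_cycle(
            A, v, pc,
            cyc * period, period, options.cfl,
            m.A0, m.k1, m.sqA0, m.beta_node, m.node_dx,
            m.seg_start, m.seg_n, m.seg_dx,
            blood.density, blood.momentum_correction, blood.friction_coefficient, pref,
            m.inlet_node, m.inlet_inner, m.inlet_dx,
            template.phases, template.values, q_scale,
            m.jct_ptr, m.jend_node, m.jend_inner, m.jend_sigma, m.jend_dx,
            m.out_node, m.out_inner, m.out_sigma, m.out_dx,
            m.out_R1, m.out_R2, m.out_C, m.out_pv,
            m.clot_node, m.clot_inner,
            p_snap, v_snap,
            sum_p, sum_v, sum_q,
            p_lo, p_hi, v_lo, v_hi,
            err,
        )
        cycles = cyc + 1
        if status == K.STATUS_JUNCTION_FAIL:
            ends = m.junction_ends[err[0]]
            raise JunctionSolveError(
                f"junction Newton failed in cycle {cycles} at junction {ends}"
            )
        if status in (K.STATUS_NONFINITE, K.STATUS_NEGATIVE_AREA):
            i = int(err[0])
            if status == K.STATUS_NEGATIVE_AREA:
                loc = m.segment_names[i]
            else:
                loc = next(
                    nm for nm, sl in m.node_slice.items() if sl.start <= i < sl.stop
                )
            raise NumericalBlowupError(
                f"non-physical state in segment {loc!r} during cycle {cycles}"
            )
        if prev_snap is not None:
            metric = convergence_metric(p_snap, prev_snap)
            history.append(metric)
            if metric < options.tolerance:
                converged = True
                break
        prev_snap = p_snap.copy()
    if not converged:
        warnings.warn(
            f"no periodic convergence within {options.max_cycles} cycles "
            f"(last metric {history[-1] if history else float('nan'):.3g})",
            NonConvergenceWarning,
        )
    return SimulationResult(
        model=m,
        mean_p=sum_p / period,
        mean_v=sum_v / period,
        mean_q=sum_q / period,
        p_min=p_lo,
        p_max=p_hi,
        v_min=v_lo,
        v_max=v_hi,
        p_snap=p_snap.copy(),
        v_snap=v_snap.copy(),
        cycles=cycles,
        converged=converged,
        convergence_history=history,
        steps_last_cycle=int(steps),
    )


# ---------------------------------------------------------------------------
# single-operation wrappers (used by the test suite and for exploration)
# ---------------------------------------------------------------------------

def maccormack_step(
    A: np.ndarray,
    v: np.ndarray,
    dt: float,
    dx: float,
    A0,
    beta: float,
    pref: float = 0.0,
    blood: BloodProperties | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One MacCormack step on a single uniform tube; interior nodes only.

    Boundary nodes are carried over unchanged (they belong to junction or
    boundary-condition operators).  Returns the new (A, v).
    """
    blood = blood or BloodProperties()
    A = np.asarray(A, dtype=float).copy()
    v = np.asarray(v, dtype=float).copy()
    n = A.size
    A0v = np.broadcast_to(np.asarray(A0, dtype=float), (n,)).copy()
    k1 = beta / A0v
    sqA0 = np.sqrt(A0v)
    p = pref + k1 * (np.sqrt(A) - sqA0)
    An = A.copy()
    vn = v.copy()
    ok = K._maccormack_segment(
        A, v, p, An, vn, 0, n, dx, dt,
        blood.density, blood.momentum_correction, blood.friction_coefficient,
        k1, sqA0, pref,
    )
    if not ok:
        raise NumericalBlowupError("negative area in MacCormack step")
    if not np.all(np.isfinite(An)) or not np.all(np.isfinite(vn)):
        raise NumericalBlowupError("non-finite state in MacCormack step")
    return An, vn


def solve_junction(
    ends: list[dict],
    dt: float = 1e-5,
    blood: BloodProperties | None = None,
    pref: float = 0.0,
) -> list[dict]:
    """Couple segment ends meeting at one junction (thin kernel wrapper).

    Each end is a dict with keys ``A``, ``v`` (state at the boundary and, via
    optional ``A_inner``/``v_inner``, just inside), ``A0``, ``beta`` and
    ``sigma`` (+1 if the segment's +x direction points into the junction).
    Returns one dict per end with the coupled ``A``, ``v``, ``p`` and the
    invariant ``W`` that constrained it.
    """
    blood = blood or BloodProperties()
    if len(ends) < 2:
        raise ValidationError("a junction needs at least two segment ends")
    E = len(ends)
    A = np.empty(2 * E)
    v = np.empty(2 * E)
    k1 = np.empty(2 * E)
    sqA0 = np.empty(2 * E)
    beta = np.empty(2 * E)
    node = np.empty(E, dtype=np.int64)
    inner = np.empty(E, dtype=np.int64)
    sigma = np.empty(E, dtype=np.int64)
    dxs = np.empty(E)
    for e, d in enumerate(ends):
        b, i = 2 * e, 2 * e + 1
        node[e], inner[e] = b, i
        A[b], v[b] = d["A"], d["v"]
        A[i] = d.get("A_inner", d["A"])
        v[i] = d.get("v_inner", d["v"])
        for ix in (b, i):
            k1[ix] = d["beta"] / d["A0"]
            sqA0[ix] = math.sqrt(d["A0"])
            beta[ix] = d["beta"]
        sigma[e] = d["sigma"]
        dxs[e] = d.get("dx", 1e-3)
    An = A.copy()
    vn = v.copy()
    ok = K._solve_junction(
        A, v, An, vn, k1, sqA0, beta, node, inner, sigma, dxs,
        dt, blood.density, blood.friction_coefficient, pref,
    )
    if not ok:
        raise JunctionSolveError("junction Newton did not converge")
    out = []
    for e, d in enumerate(ends):
        b = 2 * e
        W = K._char_invariant(
            A, v, k1, sqA0, node[e], inner[e], sigma[e], dxs[e], dt,
            blood.density, blood.friction_coefficient, pref,
        )
        out.append(
            {
                "A": An[b],
                "v": vn[b],
                "p": tube_law_pressure(An[b], d["A0"], d["beta"], pref),
                "W": W,
            }
        )
    return out
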