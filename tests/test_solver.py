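"""1D solver: tube law, MacCormack, junction coupling, boundaries, occlusion."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    bifurcation_network,
    constant_inflow_template,
    simple_windkessel,
    single_tube_network,
)
from strokeflow.anatomy import (
    ArterialNetwork,
    ValidationError,
    VesselSegment,
    discretize_network,
)
from strokeflow.calibration import CardiacParameters, WindkesselOutlet, allocate_outlets
from strokeflow.solver import (
    BloodProperties,
    InletWaveform,
    NonConvergenceWarning,
    Occlusion,
    SolverOptions,
    apply_clot,
    beta_coefficient,
    convergence_metric,
    default_inlet_template,
    inlet_flow,
    maccormack_step,
    run_pulsatile_simulation,
    solve_junction,
    tube_law_area,
    tube_law_pressure,
    wave_speed,
)

CARD = CardiacParameters()


class TestTubeLaw:
    def test_beta_reference_value(self):
        # sqrt(pi) * 1.6e6 * 3e-4 / (1 - 0.25)
        assert beta_coefficient(1.6e6, 0.3e-3, 0.5) == pytest.approx(1134.4, rel=1e-3)

    def test_beta_simplifies_at_zero_poisson(self):
        assert beta_coefficient(1e6, 1e-3, 0.0) == pytest.approx(math.sqrt(math.pi) * 1e3)

    def test_beta_linear_in_thickness(self):
        assert beta_coefficient(1e6, 2e-3, 0.3) == pytest.approx(
            2 * beta_coefficient(1e6, 1e-3, 0.3)
        )

    def test_beta_rejects_poisson_at_one(self):
        with pytest.raises(ValidationError):
            beta_coefficient(1e6, 1e-3, 1.0)

    def test_reference_area_gives_reference_pressure(self):
        assert tube_law_pressure(2e-5, 2e-5, 1000.0, pref=10100.0) == 10100.0

    def test_quadruple_area_adds_beta_over_sqrt_a0(self):
        A0, beta = 1e-5, 800.0
        assert tube_law_pressure(4 * A0, A0, beta) == pytest.approx(beta / math.sqrt(A0))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        logA0=st.floats(min_value=-14, max_value=-6),
        beta=st.floats(min_value=10.0, max_value=1e5),
        ratio=st.floats(min_value=0.3, max_value=4.0),
    )
    def test_round_trip_is_bijective(self, logA0, beta, ratio):
        A0 = 10.0**logA0
        A = ratio * A0
        p = tube_law_pressure(A, A0, beta, pref=10100.0)
        assert tube_law_area(p, A0, beta, pref=10100.0) == pytest.approx(A, rel=1e-12)

    def test_rejects_nonpositive_area(self):
        with pytest.raises(ValidationError):
            tube_law_pressure(0.0, 1e-5, 100.0)


class TestInletFlow:
    def test_one_beat_integrates_to_stroke_volume(self):
        t = np.linspace(0.0, 1.0, 200001)
        q = inlet_flow(t, sv_ml=70.0, hr_per_min=60.0)
        vol_ml = np.trapezoid(q, t) * 1e6
        assert vol_ml == pytest.approx(70.0, rel=1e-6)

    def test_mean_flow_is_sv_times_hr(self):
        t = np.linspace(0.0, 60.0 / 72.0, 100001)
        q = inlet_flow(t, sv_ml=65.0, hr_per_min=72.0)
        mean_mlmin = np.trapezoid(q, t) / t[-1] * 6e7
        assert mean_mlmin == pytest.approx(65.0 * 72.0, rel=1e-5)

    def test_periodicity_exact(self):
        t = np.linspace(0.0, 0.999, 557)
        q1 = inlet_flow(t, 70.0, 60.0)
        q2 = inlet_flow(t + 3.0, 70.0, 60.0)
        assert np.allclose(q1, q2, rtol=0, atol=1e-14 * q1.max())


class TestMacCormack:
    def test_equilibrium_is_a_fixed_point(self):
        n = 21
        A0, beta, pref = math.pi * (5e-3) ** 2, 700.0, 10100.0
        A = np.full(n, A0)
        v = np.zeros(n)
        An, vn = maccormack_step(A, v, dt=1e-4, dx=1e-2, A0=A0, beta=beta, pref=pref)
        assert np.max(np.abs(An - A)) < 1e-14 * A0
        assert np.max(np.abs(vn)) < 1e-14

    def test_blowup_reported_with_diagnostic(self):
        from strokeflow.solver import NumericalBlowupError

        A0 = math.pi * (5e-3) ** 2
        A = np.full(11, A0)
        v = np.linspace(0, 50.0, 11)  # absurd velocity; CFL violated on purpose
        with pytest.raises(NumericalBlowupError):
            for _ in range(200):
                A, v = maccormack_step(A, v, dt=5e-3, dx=1e-3, A0=A0, beta=700.0)

    def test_pulse_travels_at_linear_wave_speed(self):
        """A weak inflow pulse propagates at c0 = sqrt(beta/(2 rho sqrt(A0)))."""
        net = single_tube_network(length_mm=1000.0, radius_mm=5.0, E_mpa=0.4)
        seg = net.segments["tube"]
        blood = BloodProperties()
        from strokeflow.anatomy import wall_thickness

        beta = beta_coefficient(seg.youngs_modulus_pa, wall_thickness(5.0) * 1e-3, 0.5)
        A0 = math.pi * (5e-3) ** 2
        c0 = wave_speed(A0, A0, beta, blood.density)
        z0 = blood.density * c0 / A0
        wk = WindkesselOutlet(
            "tube", "distal", "lower_body", "systemic", 5.0,
            z0 + 1e9, z0, 1e9, 1e-9, CARD.venous_pressure_pa,
        )
        card = CardiacParameters(sv_ml=0.5)  # weak pulse keeps it linear
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonConvergenceWarning)
            res = run_pulsatile_simulation(
                net, blood, card, [wk],
                template=default_inlet_template(systole_fraction=0.12),
                options=SolverOptions(max_cycles=2, snapshots_per_cycle=1000, tolerance=1e-9),
            )

        def peak_time(node):
            p = res.p_snap[:, node]
            k = int(np.argmax(p))
            # parabolic refinement of the sampled peak
            if 0 < k < len(p) - 1:
                d = 0.5 * (p[k - 1] - p[k + 1]) / (p[k - 1] - 2 * p[k] + p[k + 1])
                return (k + d) / 1000
            return k / 1000

        n1, n2 = 20, 80  # x = 0.2 m and 0.8 m at 10 mm spacing
        measured = 0.6 / (peak_time(n2) - peak_time(n1))
        assert measured == pytest.approx(c0, rel=0.02)

    def test_steady_profile_matches_friction_ode(self):
        """Converged constant-inflow profile obeys dp/dx = -2 a pi mu v/((a-1) A)."""
        seg = VesselSegment("s", 400.0, 2.0, 2.0, 0.8e6)
        net = discretize_network(ArterialNetwork([seg], [], inlet="s"), max_spacing_mm=5)
        wk = simple_windkessel("s", 1e8, 1e9, 1e-9)
        res = run_pulsatile_simulation(
            net, cardiac=CardiacParameters(sv_ml=10.0), outlets=[wk],
            template=constant_inflow_template(),
            options=SolverOptions(max_cycles=20, tolerance=1e-9),
        )
        blood = BloodProperties()
        i0, i1 = 20, 60
        x = np.arange(res.mean_p.size) * 5e-3
        v = res.mean_v[i0:i1 + 1]
        A = res.mean_q[i0:i1 + 1] / v
        rhs = -blood.friction_coefficient * blood.density * v / A
        dp_pred = np.trapezoid(rhs, x[i0:i1 + 1])
        dp_sim = res.mean_p[i1] - res.mean_p[i0]
        assert dp_sim == pytest.approx(dp_pred, rel=0.01)

    def test_grid_refinement_changes_outlet_flows_below_one_percent(self):
        flows = {}
        for spacing in (10.0, 5.0):
            net = bifurcation_network(spacing_mm=spacing)
            out = allocate_outlets(net, CARD)
            res = run_pulsatile_simulation(net, cardiac=CARD, outlets=out)
            flows[spacing] = res.outlet_table().set_index("outlet")["mean_q_mlmin"]
        rel = (flows[10.0] - flows[5.0]).abs() / flows[5.0]
        assert rel.max() < 0.01


class TestJunction:
    def _end(self, r_mm, E, v, sigma, dA=0.0):
        A0 = math.pi * (r_mm * 1e-3) ** 2
        from strokeflow.anatomy import wall_thickness

        beta = beta_coefficient(E, wall_thickness(r_mm) * 1e-3, 0.5)
        return {"A": A0 * (1 + dA), "v": v, "A0": A0, "beta": beta, "sigma": sigma}

    def test_symmetric_bifurcation_splits_flow_equally(self):
        parent = self._end(4.0, 0.4e6, 0.3, +1, dA=0.01)
        d1 = self._end(3.0, 0.8e6, 0.2, -1)
        d2 = self._end(3.0, 0.8e6, 0.2, -1)
        out = solve_junction([parent, d1, d2], dt=1e-5, pref=10100.0)
        assert out[1]["A"] == pytest.approx(out[2]["A"], rel=1e-12)
        assert out[1]["v"] == pytest.approx(out[2]["v"], rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_constraint_residuals_vanish(self, seed):
        """Mass, total pressure and characteristic residuals after the solve."""
        rng = np.random.default_rng(seed)
        blood = BloodProperties()
        ends = [self._end(rng.uniform(2, 6), 0.4e6, rng.uniform(0.0, 0.5), +1,
                          dA=rng.uniform(-0.02, 0.02))]
        for _ in range(int(rng.integers(1, 4))):
            ends.append(
                self._end(rng.uniform(1, 4), 0.8e6, rng.uniform(-0.3, 0.3), -1,
                          dA=rng.uniform(-0.02, 0.02))
            )
        out = solve_junction(ends, dt=1e-5, blood=blood, pref=10100.0)
        mass = sum(e["sigma"] * o["A"] * o["v"] for e, o in zip(ends, out))
        qscale = max(abs(o["A"] * o["v"]) for o in out) + 1e-30
        assert abs(mass) / qscale < 1e-8
        ptot = [o["p"] + 0.5 * blood.density * o["v"] ** 2 for o in out]
        assert max(ptot) - min(ptot) < 1e-6 * max(ptot)
        for e, o in zip(ends, out):
            c = wave_speed(o["A"], e["A0"], e["beta"], blood.density)
            assert o["v"] + 4 * e["sigma"] * c == pytest.approx(o["W"], abs=1e-9)

    def test_two_segment_junction_is_transparent(self):
        """A chain junction with identical tubes behaves as one tube.

        The boundary coupling is first-order in the characteristics against a
        second-order interior, so transparency holds to the scheme error
        (~0.1% here), not to round-off.
        """
        card = CARD
        opts = SolverOptions(max_cycles=6, tolerance=1e-12)
        netA = single_tube_network(length_mm=200.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonConvergenceWarning)
            resA = run_pulsatile_simulation(
                netA, cardiac=card, outlets=[simple_windkessel("tube")], options=opts
            )
            s1 = VesselSegment("t1", 100.0, 5.0, 5.0, 0.4e6)
            s2 = VesselSegment("t2", 100.0, 5.0, 5.0, 0.4e6)
            netB = discretize_network(
                ArterialNetwork(
                    [s1, s2], [[("t1", "distal"), ("t2", "proximal")]], inlet="t1"
                )
            )
            resB = run_pulsatile_simulation(
                netB, cardiac=card, outlets=[simple_windkessel("t2")], options=opts
            )
        pa = resA.p_snap
        pb = np.concatenate([resB.p_snap[:, :11], resB.p_snap[:, 12:]], axis=1)
        assert np.max(np.abs(pa - pb)) / np.max(np.abs(pa)) < 5e-3

    def test_junction_mass_and_total_pressure_in_network_run(self, default_run):
        """At every junction of the converged run the boundary states satisfy
        the coupling constraints (they are re-imposed each step)."""
        res = default_run["result"]
        m = res.model
        blood = BloodProperties()
        # use the stored final-state snapshots at the last phase
        p = res.p_snap[-1]
        v = res.v_snap[-1]
        worst_mass, worst_dp = 0.0, 0.0
        for j in range(len(m.jct_ptr) - 1):
            lo, hi = m.jct_ptr[j], m.jct_ptr[j + 1]
            nodes = m.jend_node[lo:hi]
            sig = m.jend_sigma[lo:hi]
            A = (np.sqrt(m.A0[nodes]) + (p[nodes] - CARD.p_dia_pa) * m.A0[nodes] / m.beta_node[nodes]) ** 2
            q = sig * A * v[nodes]
            worst_mass = max(worst_mass, abs(q.sum()) / (np.abs(q).max() + 1e-30))
            ptot = p[nodes] + 0.5 * blood.density * v[nodes] ** 2
            worst_dp = max(worst_dp, (ptot.max() - ptot.min()) / ptot.max())
        assert worst_mass < 1e-6
        assert worst_dp < 1e-6


class TestBoundariesAndOcclusion:
    def test_single_tube_windkessel_steady_closed_form(self):
        net = single_tube_network()
        r1, r2 = 1e7, 1.6e8
        wk = simple_windkessel("tube", r1, r2)
        res = run_pulsatile_simulation(
            net, cardiac=CARD, outlets=[wk], template=constant_inflow_template(),
            options=SolverOptions(max_cycles=20, tolerance=1e-6),
        )
        p_pred = CARD.venous_pressure_pa + CARD.mean_flow_m3s * (r1 + r2)
        assert res.mean_p[-1] == pytest.approx(p_pred, rel=1e-3)

    def test_zero_inflow_relaxes_to_venous_pressure(self):
        net = single_tube_network()
        wk = simple_windkessel("tube", 1e7, 1.6e8, 2e-9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonConvergenceWarning)
            res = run_pulsatile_simulation(
                net, cardiac=CardiacParameters(sv_ml=1e-6), outlets=[wk],
                template=constant_inflow_template(),
                options=SolverOptions(max_cycles=20, tolerance=1e-14),
            )
        # started at diastolic 10100 Pa, must have decayed most of the way
        assert res.mean_p.max() < CARD.venous_pressure_pa + 800.0
        assert res.mean_p.min() > CARD.venous_pressure_pa - 50.0

    def test_clot_validation(self):
        net = bifurcation_network()
        with pytest.raises(ValidationError):
            apply_clot(net, "missing")
        with pytest.raises(ValidationError):
            apply_clot(net, "parent")  # inlet segment
        with pytest.raises(ValidationError):
            apply_clot(net, "d1", position=0.0)

    def test_clot_blocks_daughter_and_conserves_flow(self):
        net = bifurcation_network()
        out = allocate_outlets(net, CARD)
        res = run_pulsatile_simulation(net, cardiac=CARD, outlets=out, clot="d1")
        tbl = res.outlet_table().set_index("outlet")
        assert tbl.loc["d1", "mean_q_mlmin"] == 0.0
        assert tbl.loc["d1", "occluded"]
        total = tbl["mean_q_mlmin"].sum()
        assert total == pytest.approx(res.inlet_mean_flow_mlmin, rel=0.005)
        # the surviving daughter takes over the whole cardiac output
        assert tbl.loc["d2", "mean_q_mlmin"] == pytest.approx(
            res.inlet_mean_flow_mlmin, rel=0.005
        )

    def test_clot_removal_restores_baseline(self):
        net = bifurcation_network()
        out = allocate_outlets(net, CARD)
        base = run_pulsatile_simulation(net, cardiac=CARD, outlets=out)
        _ = run_pulsatile_simulation(net, cardiac=CARD, outlets=out, clot="d1")
        again = run_pulsatile_simulation(net, cardiac=CARD, outlets=out)
        a = base.outlet_table().set_index("outlet")["mean_q_mlmin"]
        b = again.outlet_table().set_index("outlet")["mean_q_mlmin"]
        assert np.allclose(a, b, rtol=1e-12)

    def test_area_stays_positive_everywhere(self, default_run):
        res = default_run["result"]
        # the kernel aborts on A <= 0; additionally the stored extrema and
        # snapshots of the accepted run must be physical
        assert np.all(np.isfinite(res.p_snap))
        assert np.all(res.p_max >= res.p_min)
        A_last = (np.sqrt(res.model.A0)
                  + (res.p_snap - CARD.p_dia_pa) * res.model.A0 / res.model.beta_node) ** 2
        assert np.all(A_last > 0)


class TestConvergence:
    def test_identical_snapshots_give_zero(self):
        p = np.random.default_rng(0).uniform(9000, 16000, size=(100, 50))
        assert convergence_metric(p, p) == 0.0

    def test_proportional_snapshots_give_the_scale_factor(self):
        p = np.random.default_rng(1).uniform(9000, 16000, size=(100, 50))
        assert convergence_metric(p, 0.999 * p) == pytest.approx(1e-3, rel=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValidationError):
            convergence_metric(np.zeros(10), np.zeros(10))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            convergence_metric(np.ones(10), np.ones(11))

    def test_periodic_state_conservation(self, default_run):
        """Sum of outlet mean flows balances the inlet mean flow once the
        run is periodic (capacitor net charge over a cycle ~ 0)."""
        res = default_run["result"]
        total_out = res.outlet_table()["mean_q_mlmin"].sum()
        assert total_out == pytest.approx(res.inlet_mean_flow_mlmin, rel=0.005)
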