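"""Shared fixtures.

The heavy fixtures (full default-anatomy pulsatile runs) are session scoped
and built lazily, so unit-test-only invocations never pay for them and the
acceptance tests share a single converged run.
"""

from __future__ import annotations

import time
import warnings

import numpy as np
import pytest

from strokeflow.anatomy import ArterialNetwork, VesselSegment, discretize_network
from strokeflow.calibration import CardiacParameters, WindkesselOutlet, allocate_outlets
from strokeflow.pipeline import ExperimentConfig, build_network
from strokeflow.solver import (
    InletWaveform,
    SolverOptions,
    run_pulsatile_simulation,
)

DEFAULT_SEED = 1


def single_tube_network(
    name="tube", length_mm=200.0, radius_mm=5.0, E_mpa=0.4, spacing_mm=10.0
) -> ArterialNetwork:
    net = ArterialNetwork(
        [VesselSegment(name, length_mm, radius_mm, radius_mm, E_mpa * 1e6)],
        [],
        inlet=name,
        outlet_tags={name: "lower_body"},
    )
    return discretize_network(net, max_spacing_mm=spacing_mm)


def simple_windkessel(name, r1=1e7, r2=1.6e8, c=8e-9, p_venous=2500.0) -> WindkesselOutlet:
    return WindkesselOutlet(
        name, "distal", "lower_body", "systemic", 5.0, r1 + r2, r1, r2, c, p_venous
    )


def bifurcation_network(spacing_mm=10.0) -> ArterialNetwork:
    """Parent tube feeding two identical daughters, windkessel-terminated."""
    segs = [
        VesselSegment("parent", 100.0, 4.0, 4.0, 0.4e6),
        VesselSegment("d1", 80.0, 3.0, 3.0, 0.8e6),
        VesselSegment("d2", 80.0, 3.0, 3.0, 0.8e6),
    ]
    net = ArterialNetwork(
        segs,
        [[("parent", "distal"), ("d1", "proximal"), ("d2", "proximal")]],
        inlet="parent",
        outlet_tags={"d1": "lower_body", "d2": "lower_body"},
        co_fractions={"lower_body": 1.0},
    )
    return discretize_network(net, max_spacing_mm=spacing_mm)


def constant_inflow_template() -> InletWaveform:
    return InletWaveform(np.linspace(0.0, 1.0, 11), np.ones(11))


def default_study_network(seed: int = DEFAULT_SEED) -> ArterialNetwork:
    """Default large-vessel anatomy with synthetic Murray cerebral trees."""
    return build_network(ExperimentConfig(seed=seed))


def run_default(seed: int = DEFAULT_SEED, clot=None, **solver_kw):
    net = default_study_network(seed)
    cardiac = CardiacParameters()
    outlets = allocate_outlets(net, cardiac)
    options = SolverOptions(**solver_kw) if solver_kw else SolverOptions()
    return net, run_pulsatile_simulation(
        net, cardiac=cardiac, outlets=outlets, clot=clot, options=options
    )


@pytest.fixture(scope="session")
def default_run():
    """Converged default-anatomy run (seed 1) plus its wall-clock time."""
    t0 = time.perf_counter()
    net, res = run_default()
    return {"net": net, "result": res, "runtime_s": time.perf_counter() - t0}


@pytest.fixture(scope="session")
def clot_run():
    """Same anatomy and calibration with a clot at the right MCA."""
    net, res = run_default(clot="R. MCA")
    return {"net": net, "result": res}


@pytest.fixture(scope="session")
def seed_sweep_runs():
    """Default runs across five synthetic-cerebral-tree seeds."""
    out = {}
    for seed in (1, 2, 3, 4, 5):
        net, res = run_default(seed=seed)
        out[seed] = {"net": net, "result": res}
    return out


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """Coarse end-to-end pipeline bundle (small trees, coarse mesh)."""
    from strokeflow.pipeline import run_experiment

    out_dir = tmp_path_factory.mktemp("bundle")
    cfg = ExperimentConfig(
        seed=3,
        anatomy={"terminal_radius_mm": 0.9},
        solver={"max_cycles": 12, "tolerance": 5e-3},
        mesh={"subdivisions": 2},
        out_dir=str(out_dir),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_experiment(cfg)
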