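"""Perfusion territories: Murray sizing, surface graph, clustering, flow maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse.csgraph import connected_components, dijkstra

from strokeflow.anatomy import ValidationError
from strokeflow.territories import (
    REGION_LABELS,
    SurfaceMesh,
    assign_territories,
    build_surface_graph,
    element_counts,
    generate_synthetic_pial_mesh,
    load_surface_mesh,
    map_flow_to_surface,
    murray_fractions,
    save_surface_mesh,
)


def strip_mesh(n=40, width=10.0, label="R MCA"):
    """Flat rectangular strip of 2n triangles along +x."""
    verts, tris = [], []
    for i in range(n + 1):
        verts.append([i * width, 0.0, 0.0])
        verts.append([i * width, width, 0.0])
    for i in range(n):
        a, b, c, d = 2 * i, 2 * i + 1, 2 * i + 2, 2 * i + 3
        tris.append([a, b, c])
        tris.append([b, d, c])
    return SurfaceMesh(
        np.asarray(verts, float), np.asarray(tris), np.array([label] * 2 * n, dtype=object)
    )


class TestMurraySizing:
    def test_symmetric_and_cubed_ratio(self):
        assert np.allclose(murray_fractions([1.0, 1.0]), [0.5, 0.5])
        assert np.allclose(murray_fractions([2.0, 1.0]), [8 / 9, 1 / 9])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.05, max_value=5.0), min_size=1, max_size=30))
    def test_fractions_normalize(self, radii):
        f = murray_fractions(radii)
        assert f.sum() == pytest.approx(1.0)
        assert np.all(f > 0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            murray_fractions([])

    @pytest.mark.parametrize(
        "fractions,n,expected",
        [
            ([0.5, 0.3, 0.2], 10, [5, 3, 2]),
            ([1 / 3, 1 / 3, 1 / 3], 10, [4, 3, 3]),  # largest remainder, low index wins
            ([1.0], 7, [7]),
        ],
    )
    def test_element_counts_examples(self, fractions, n, expected):
        assert element_counts(fractions, n).tolist() == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.05, max_value=5.0), min_size=1, max_size=12),
        st.integers(min_value=12, max_value=500),
    )
    def test_element_counts_sum_exactly_and_stay_positive(self, radii, n):
        counts = element_counts(murray_fractions(radii), n)
        assert counts.sum() == n
        assert counts.min() >= 1

    def test_more_outlets_than_triangles_rejected(self):
        with pytest.raises(ValidationError):
            element_counts(np.full(11, 1 / 11), 10)


class TestSurfaceGraph:
    def test_shared_edge_means_connected(self):
        mesh = strip_mesh(n=1)
        g = build_surface_graph(mesh)
        assert g.adjacency[0, 1] > 0

    def test_icosphere_is_one_component(self):
        mesh = generate_synthetic_pial_mesh(subdivisions=2)
        g = build_surface_graph(mesh)
        ncomp, _ = connected_components(g.adjacency, directed=False)
        assert ncomp == 1

    def test_dijkstra_close_to_euclidean_on_flat_strip(self):
        mesh = strip_mesh(n=40)
        g = build_surface_graph(mesh)
        d = dijkstra(g.adjacency, directed=False, indices=[0])[0]
        far = mesh.n_triangles - 1
        euclid = np.linalg.norm(g.centroids[far] - g.centroids[0])
        assert d[far] == pytest.approx(euclid, rel=0.15)


class TestSyntheticMesh:
    @pytest.mark.parametrize("sub,expected", [(2, 320), (3, 1280), (4, 5120)])
    def test_triangle_counts(self, sub, expected):
        assert generate_synthetic_pial_mesh(subdivisions=sub).n_triangles == expected

    def test_all_triangles_labelled_with_connected_regions(self):
        mesh = generate_synthetic_pial_mesh(subdivisions=3, seed=4)
        assert set(np.unique(mesh.region.astype(str))) == set(REGION_LABELS)
        g = build_surface_graph(mesh)
        for lbl in REGION_LABELS:
            idx = mesh.region_triangles(lbl)
            ncomp, _ = connected_components(g.submatrix(idx), directed=False)
            assert ncomp == 1, lbl

    def test_deterministic_per_seed_and_near_uniform_areas(self):
        a = generate_synthetic_pial_mesh(subdivisions=2, seed=9)
        b = generate_synthetic_pial_mesh(subdivisions=2, seed=9)
        assert np.array_equal(a.region, b.region)
        areas = a.areas
        assert areas.std() / areas.mean() < 0.25

    def test_mca_territory_is_largest(self):
        mesh = generate_synthetic_pial_mesh(subdivisions=3)
        areas = mesh.areas
        per = {lbl: areas[mesh.region_triangles(lbl)].sum() for lbl in REGION_LABELS}
        assert per["L MCA"] > per["L ACA"] and per["L MCA"] > per["L PCA"]


def _region_outlets(nper=4, seed=0, radius_range=(0.3, 0.8)):
    rng = np.random.default_rng(seed)
    rows = []
    for reg in REGION_LABELS:
        for i in range(nper):
            rows.append(
                {"outlet": f"{reg}#{i}", "region": reg,
                 "radius_mm": rng.uniform(*radius_range)}
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def assigned():
    mesh = generate_synthetic_pial_mesh(subdivisions=3, seed=0)
    graph = build_surface_graph(mesh)
    outlets = _region_outlets()
    asg = assign_territories(graph, mesh, outlets, seed=0)
    return mesh, graph, outlets, asg


class TestAssignment:
    _outlets = staticmethod(_region_outlets)

    def test_partition_of_every_region(self, assigned):
        mesh, _, _, asg = assigned
        for reg in REGION_LABELS:
            idx = mesh.region_triangles(reg)
            owners = asg.triangle_outlet[idx]
            assert (owners != "").all()
            assert {o.split("#")[0] for o in owners} == {reg}

    def test_capacities_match_largest_remainder_budgets(self, assigned):
        _, _, _, asg = assigned
        for o in asg.outlet_ids:
            size = len(asg.triangles_of(o))
            assert abs(size - asg.counts[o]) <= max(1, 0.05 * asg.counts[o])

    def test_each_territory_connected(self, assigned):
        _, graph, _, asg = assigned
        for o in asg.outlet_ids:
            tri = asg.triangles_of(o)
            ncomp, _ = connected_components(graph.submatrix(tri), directed=False)
            assert ncomp == 1

    def test_deterministic(self, assigned):
        mesh, graph, outlets, asg = assigned
        again = assign_territories(graph, mesh, outlets, seed=0)
        assert np.array_equal(asg.triangle_outlet, again.triangle_outlet)

    def test_single_outlet_owns_entire_region(self):
        mesh = generate_synthetic_pial_mesh(subdivisions=2, seed=0)
        graph = build_surface_graph(mesh)
        outlets = pd.DataFrame(
            [{"outlet": f"{reg}#0", "region": reg, "radius_mm": 0.5} for reg in REGION_LABELS]
        )
        asg = assign_territories(graph, mesh, outlets, seed=0)
        for reg in REGION_LABELS:
            assert len(asg.triangles_of(f"{reg}#0")) == len(mesh.region_triangles(reg))

    def test_two_equal_outlets_split_strip_in_halves(self):
        mesh = strip_mesh(n=30)
        graph = build_surface_graph(mesh)
        outlets = pd.DataFrame(
            [
                {"outlet": "left", "region": "R MCA", "radius_mm": 0.5,
                 "x": 0.0, "y": 5.0, "z": 0.0},
                {"outlet": "right", "region": "R MCA", "radius_mm": 0.5,
                 "x": 300.0, "y": 5.0, "z": 0.0},
            ]
        )
        asg = assign_territories(graph, mesh, outlets, seed=0)
        left = asg.triangles_of("left")
        right = asg.triangles_of("right")
        assert len(left) == len(right) == 30
        # split at the geometric midline
        assert graph.centroids[left][:, 0].max() < graph.centroids[right][:, 0].min()

    def test_murray_area_scaling(self, assigned):
        from scipy import stats

        mesh, _, outlets, asg = assigned
        areas = asg.territory_areas(mesh)
        xs, ys = [], []
        for reg in REGION_LABELS:
            grp = outlets[outlets["region"] == reg]
            for i in range(len(grp)):
                for j in range(len(grp)):
                    if i != j:
                        a, b = grp.iloc[i], grp.iloc[j]
                        xs.append((a.radius_mm / b.radius_mm) ** 3)
                        ys.append(areas[a.outlet] / areas[b.outlet])
        fit = stats.linregress(xs, ys)
        assert fit.slope == pytest.approx(1.0, abs=0.1)
        assert fit.rvalue**2 > 0.95

    def test_disconnected_region_raises(self):
        mesh = strip_mesh(n=10)
        mesh.region[8:12] = "other"  # cuts 'R MCA' in two
        graph = build_surface_graph(mesh)
        outlets = pd.DataFrame(
            [{"outlet": "a", "region": "R MCA", "radius_mm": 0.5}]
        )
        from strokeflow.territories import RegionError

        with pytest.raises(RegionError, match="R MCA"):
            assign_territories(graph, mesh, outlets, seed=0)


class TestFlowMapping:
    def test_uniform_flux_and_exact_split(self):
        mesh = strip_mesh(n=5)
        graph = build_surface_graph(mesh)
        outlets = pd.DataFrame([{"outlet": "o", "region": "R MCA", "radius_mm": 0.5}])
        asg = assign_territories(graph, mesh, outlets, seed=0)
        fm = map_flow_to_surface(asg, {"o": 10.0}, mesh)
        flows = fm.table["flow_ml_min"]
        assert flows.sum() == pytest.approx(10.0)
        assert np.allclose(flows, 10.0 / mesh.n_triangles)
        assert np.allclose(fm.table["flux_ml_min_mm2"], 10.0 / mesh.areas.sum())

    def test_total_flow_conserved_across_regions(self):
        mesh = generate_synthetic_pial_mesh(subdivisions=2, seed=1)
        graph = build_surface_graph(mesh)
        outlets = TestAssignment._outlets(nper=2, seed=3)
        asg = assign_territories(graph, mesh, outlets, seed=1)
        flows = {o: 1.0 + i for i, o in enumerate(asg.outlet_ids)}
        fm = map_flow_to_surface(asg, flows, mesh)
        assert fm.table["flow_ml_min"].sum() == pytest.approx(sum(flows.values()))

    def test_missing_flow_record_rejected(self):
        mesh = strip_mesh(n=5)
        graph = build_surface_graph(mesh)
        outlets = pd.DataFrame([{"outlet": "o", "region": "R MCA", "radius_mm": 0.5}])
        asg = assign_territories(graph, mesh, outlets, seed=0)
        with pytest.raises(ValidationError):
            map_flow_to_surface(asg, {}, mesh)


class TestMeshIO:
    @pytest.mark.parametrize("ext", ["stl", "obj", "vtk"])
    def test_round_trip(self, tmp_path, ext):
        mesh = generate_synthetic_pial_mesh(subdivisions=1, seed=0)
        path = tmp_path / f"m.{ext}"
        labels = tmp_path / "labels.csv"
        save_surface_mesh(mesh, path, labels_path=labels)
        back = load_surface_mesh(path, labels_path=labels)
        assert back.n_triangles == mesh.n_triangles
        assert back.areas.sum() == pytest.approx(mesh.areas.sum(), rel=1e-5)
        assert sorted(np.unique(back.region.astype(str))) == sorted(
            np.unique(mesh.region.astype(str))
        )

    def test_flow_map_vtk_appends_cell_data(self, tmp_path):
        from strokeflow.territories import save_flow_map_vtk

        mesh = strip_mesh(n=5)
        graph = build_surface_graph(mesh)
        outlets = pd.DataFrame([{"outlet": "o", "region": "R MCA", "radius_mm": 0.5}])
        asg = assign_territories(graph, mesh, outlets, seed=0)
        fm = map_flow_to_surface(asg, {"o": 10.0}, mesh)
        path = tmp_path / "flow.vtk"
        save_flow_map_vtk(mesh, fm, path)
        text = path.read_text()
        assert "SCALARS flow_ml_min" in text and "SCALARS flux_ml_min_mm2" in text
        back = load_surface_mesh(path)
        assert back.n_triangles == mesh.n_triangles

    def test_vtk_carries_labels_inline(self, tmp_path):
        mesh = generate_synthetic_pial_mesh(subdivisions=1, seed=0)
        path = tmp_path / "m.vtk"
        save_surface_mesh(mesh, path)
        back = load_surface_mesh(path)
        assert np.array_equal(back.region.astype(str), mesh.region.astype(str))
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
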