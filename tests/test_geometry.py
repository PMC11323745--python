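"""Globe cross-section construction and structured quadratic meshing."""

import numpy as np
import pytest

from sclerapuff.geometry import (
    GlobeParams,
    InvalidGeometryError,
    MeshingError,
    build_globe_cross_section,
    compute_axial_coordinates,
    generate_mesh,
    mesh_volume,
)


class TestCrossSection:
    def test_wall_thickness_constraints(self):
        cs = build_globe_cross_section(GlobeParams(AL=18, EL=19, THK=0.35))
        # THK at the equatorial extreme, fixed 0.6 mm at the posterior pole
        assert cs.wall_thickness(np.pi / 2) == pytest.approx(0.35)
        assert cs.wall_thickness(0.0) == pytest.approx(0.60)

    def test_total_axial_extent_is_al_plus_offset(self):
        p = GlobeParams(AL=18, apex_offset=1.0)
        cs = build_globe_cross_section(p)
        x_min = cs.curves["exterior_ellipse"][:, 0].min()
        x_max = cs.curves["cornea_outer"][:, 0].max()
        assert x_max - x_min == pytest.approx(19.0)

    def test_degenerate_circle_constant_thickness(self):
        p = GlobeParams(AL=18, EL=18, THK=0.6, t_post=0.6, include_cornea=False)
        cs = build_globe_cross_section(p)
        th = np.linspace(0, np.pi, 50)
        np.testing.assert_allclose(cs.wall_thickness(th), 0.6, rtol=1e-12)

    def test_thickness_monotone_equator_to_pole(self):
        cs = build_globe_cross_section(GlobeParams())
        th = np.linspace(0, np.pi / 2, 200)
        t = cs.wall_thickness(th)
        assert np.all(np.diff(t) < 0)  # 0.6 at pole down to THK at equator
        assert t.min() == pytest.approx(0.35) and t.max() == pytest.approx(0.6)

    @pytest.mark.parametrize(
        "kw",
        [
            {"THK": -0.1},
            {"THK": 10.0},
            {"AL": 0.0},
            {"cornea_angle": 190.0},
            {"AL": 1.0},  # interior semi-axis would be negative
        ],
    )
    def test_invalid_geometry_rejected(self, kw):
        with pytest.raises(InvalidGeometryError):
            GlobeParams(**kw)


class TestMesh:
    def test_default_element_count_near_target(self):
        mesh = generate_mesh(GlobeParams(), resolution=5000)
        assert abs(mesh.n_elems - 5000) / 5000 < 0.20

    def test_refinement_grows_count_and_keeps_invariants(self):
        m1 = generate_mesh(GlobeParams(), resolution=200)
        m2 = generate_mesh(GlobeParams(), resolution=800)
        assert 2.0 < m2.n_elems / m1.n_elems < 8.0
        for m in (m1, m2):
            for name, faces in m.face_sets.items():
                assert faces.shape[0] > 0, name
            for name, nodes in m.node_sets.items():
                if name != "symmetry_face_axial":
                    assert nodes.size > 0, name

    def test_at_least_two_elements_through_wall(self):
        mesh = generate_mesh(GlobeParams(), resolution=150)
        assert mesh.meta["n_radial"] >= 2
        with pytest.raises(MeshingError):
            generate_mesh(GlobeParams(), resolution=150, n_radial=1)

    def test_too_coarse_rejected(self):
        with pytest.raises(MeshingError):
            generate_mesh(GlobeParams(), resolution=10)

    def test_named_set_relations(self, globe_mesh):
        m = globe_mesh
        outer_nodes = set(np.unique(m.face_sets["outer_surface"]).tolist())
        patch_nodes = set(np.unique(m.face_sets["airpuff_patch"]).tolist())
        assert patch_nodes <= outer_nodes  # patch is part of the outer skin
        assert m.posterior_pole_node in set(m.node_sets["sagittal_section"].tolist())
        tol = 1e-6 * m.params.EL
        assert np.abs(m.nodes[m.node_sets["sagittal_section"], 2]).max() < tol
        # the pole node is the axial extreme
        assert m.nodes[m.posterior_pole_node, 0] == pytest.approx(
            m.nodes[:, 0].min()
        )

    def test_patch_centred_at_uppermost_point(self, globe_mesh):
        """The patch centroid sits at the uppermost equatorial point in the
        sagittal plane (its z offset is the quarter model holding only the
        z > 0 half of the footprint)."""
        m = globe_mesh
        cent = m.nodes[m.face_sets["airpuff_patch"][:, :4]].mean(axis=(0, 1))
        assert abs(cent[0]) < 1.0  # axially centred on the equator
        assert abs(cent[1] - m.params.b_out) < 1.0  # at the top of the globe

    def test_volume_converges_to_analytic(self):
        """Quadrature volume vs closed-form ellipsoid-shell volume (<1%)."""
        p = GlobeParams(include_cornea=False)
        va = (np.pi / 3) * (
            p.a_out * p.b_out**2 - p.a_in * p.b_in**2
        )  # quarter shell
        v = mesh_volume(generate_mesh(p, resolution=600))
        assert abs(v - va) / va < 0.01

    def test_half_model_option(self):
        m = generate_mesh(GlobeParams(), resolution=200, symmetry="half")
        assert m.node_sets["symmetry_face_axial"].size == 0
        # spans both signs of y
        assert m.nodes[:, 1].min() < -1.0 and m.nodes[:, 1].max() > 1.0


class TestAxialCoordinates:
    def test_definition_and_range(self, globe_mesh):
        ax = compute_axial_coordinates(globe_mesh)
        p = globe_mesh.params
        assert ax.x_f == pytest.approx(p.AL / 2, rel=1e-6)
        scl = globe_mesh.region == 0
        assert ax.x[scl].max() <= ax.x_f + 1e-9
        # equatorial elements sit near x = 0, the most posterior near x_f
        assert np.abs(ax.x[scl]).min() < 0.5
        assert ax.x[scl].max() > 0.9 * ax.x_f

    def test_circle_limit_xf(self):
        p = GlobeParams(AL=18, EL=18, THK=0.6, t_post=0.6, include_cornea=False)
        mesh = generate_mesh(p, resolution=200)
        ax = compute_axial_coordinates(mesh)
        assert ax.x_f == pytest.approx(9.0, rel=1e-6)


def test_vtk_export_round_numbers(tmp_path, globe_mesh):
    from sclerapuff.geometry import export_vtk

    path = tmp_path / "mesh.vtk"
    export_vtk(globe_mesh, path, point_data={"height": globe_mesh.nodes[:, 1]})
    text = path.read_text().splitlines()
    assert text[0].startswith("# vtk DataFile")
    assert any(line.startswith(f"POINTS {globe_mesh.n_nodes}") for line in text)
    assert any(line == "25" for line in text)  # quadratic hexahedron cells
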