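"""Nonlinear FE core: patch test, pressure loads, verification solves."""

import numpy as np
import pytest

from sclerapuff.fe import (
    MMHG_TO_MPA,
    BoundaryConditions,
    FEModel,
    PressureLoad,
    SolverConfig,
)
from sclerapuff.material import stress_and_tangent
from sclerapuff.shapefn import FACE_INNER, FACE_OUTER, HEX20_LOCAL, hex20_shape


def _single_hex(scale=1.0):
    """One reference 20-node hexahedron spanning [0, scale]^3."""
    nodes = 0.5 * scale * (HEX20_LOCAL + 1.0)
    elems = np.arange(20, dtype=np.int64)[None, :]
    return nodes, elems


def _cube_model(fix_all=False):
    nodes, elems = _single_hex()
    fixed = np.arange(60) if fix_all else np.array([], dtype=np.int64)
    return FEModel(
        nodes=nodes, elems=elems, mu_elem=np.array([0.083]),
        kappa_elem=np.array([0.083 * 40 * 1e3]), alpha=40.0, fixed_dofs=fixed,
    )


class TestElementAndPatch:
    def test_shape_functions_partition_of_unity(self, rng):
        pts = rng.uniform(-1, 1, size=(20, 3))
        N, dN = hex20_shape(pts)
        np.testing.assert_allclose(N.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(dN.sum(axis=1), 0.0, atol=1e-12)

    def test_patch_uniform_strain_constant_stress(self):
        """An affine nodal displacement must reproduce the exact constant
        deformation gradient and stress at every Gauss point."""
        model = _cube_model()
        A = np.array([[0.02, 0.005, 0.0], [0.0, -0.01, 0.003], [0.001, 0.0, 0.015]])
        u = (model.nodes @ A.T).ravel()
        F = model.deformation_gradients(u)
        np.testing.assert_allclose(
            F, np.broadcast_to(np.eye(3) + A, F.shape), atol=1e-12
        )
        sig = model.cauchy_stress(u)
        spread = np.abs(sig - sig[0, 0]).max()
        assert spread < 1e-10 * max(1.0, np.abs(sig).max())

    def test_zero_load_zero_displacement(self):
        nodes, elems = _single_hex()
        # fix one corner fully + enough dofs to kill rigid modes
        fixed = np.array([0, 1, 2, 4, 5, 8])
        model = FEModel(nodes=nodes, elems=elems, mu_elem=np.array([0.083]),
                        kappa_elem=np.array([3320.0]), alpha=40.0, fixed_dofs=fixed)
        model.add_load("p", PressureLoad.uniform(elems[:, FACE_OUTER], 1.0))
        sol = model.solve([{"p": 0.0}])
        assert np.abs(sol.final - sol.reference).max() == 0.0


class TestFollowerPressure:
    def test_closed_surface_zero_net_force(self):
        """Uniform pressure on all six faces of a free cube is
        self-equilibrated (closed-surface identity)."""
        model = _cube_model()
        # build all six outward faces of the hexahedron
        loc = HEX20_LOCAL
        faces = []
        for axis in range(3):
            for sign in (-1, 1):
                ids = [a for a in range(20) if loc[a, axis] == sign]
                corners = [a for a in ids if np.count_nonzero(loc[a]) == 3]
                mids = [a for a in ids if a not in corners]
                # order corners counter-clockwise seen from outside
                other = [i for i in range(3) if i != axis]
                u, v = other
                def key(a, u=u, v=v, sign=sign):
                    return np.arctan2(sign * loc[a, v], loc[a, u])
                corners.sort(key=key)
                ordered = corners + mids  # midside order fixed below
                # midsides between consecutive corners
                mid_sorted = []
                for i in range(4):
                    c0, c1 = corners[i], corners[(i + 1) % 4]
                    target = (loc[c0] + loc[c1]) / 2
                    mid_sorted.append(
                        next(a for a in mids if np.allclose(loc[a], target))
                    )
                faces.append(corners + mid_sorted)
        faces = np.array(faces)
        load = PressureLoad.uniform(faces, 0.01)
        model.add_load("p", load)
        f, _ = model.external(np.zeros(model.ndof), {"p": 1.0}, want_K=False)
        net = f.reshape(-1, 3).sum(axis=0)
        assert np.abs(net).max() < 1e-14

    def test_internal_pressure_expands_cavity(self, sphere_mesh):
        from sclerapuff.geometry import mesh_volume
        from sclerapuff.material import MaterialField

        field = MaterialField.from_mesh(sphere_mesh, mu=0.083)
        model = FEModel.from_mesh(
            sphere_mesh, field, BoundaryConditions.from_mesh(sphere_mesh)
        )
        model.add_load(
            "iop", PressureLoad.uniform(sphere_mesh.face_sets["inner_surface"], 1.0)
        )
        sol = model.solve([{"iop": 0.002}])
        v0 = mesh_volume(sphere_mesh)
        v1 = mesh_volume(sphere_mesh, coords=sol.final)
        assert v1 > v0  # positive internal pressure inflates

    def test_follower_force_rotates_with_configuration(self, rng):
        """A rigidly rotated pressurised configuration produces the same
        load vector, rotated."""
        model = _cube_model()
        faces = model.elems[:, FACE_OUTER]
        model.add_load("p", PressureLoad.uniform(faces, 0.01))
        u1 = 0.01 * rng.standard_normal((20, 3))
        f1, _ = model.external(u1.ravel(), {"p": 1.0}, want_K=False)
        Q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        x2 = (model.nodes + u1) @ Q.T
        f2, _ = model.external((x2 - model.nodes).ravel(), {"p": 1.0}, want_K=False)
        np.testing.assert_allclose(
            f2.reshape(-1, 3), f1.reshape(-1, 3) @ Q.T, atol=1e-12
        )


class TestVerificationSolves:
    def test_laplace_sphere_hoop_stress(self, sphere_mesh):
        """Thin pressurised spherical shell: mean wall hoop stress matches
        pR/(2t) = 18 kPa within 5%."""
        from sclerapuff.material import MaterialField
        from sclerapuff.shapefn import gauss_points

        field = MaterialField.from_mesh(sphere_mesh, mu=0.083)
        model = FEModel.from_mesh(
            sphere_mesh, field, BoundaryConditions.from_mesh(sphere_mesh)
        )
        model.add_load(
            "iop", PressureLoad.uniform(sphere_mesh.face_sets["inner_surface"], 1.0)
        )
        sol = model.solve([{"iop": 0.002}])
        u = (sol.final - sol.reference).ravel()
        sig = model.cauchy_stress(u)
        pts, _ = gauss_points(2, 3)
        N, _ = hex20_shape(pts)
        Xg = np.einsum("ga,eaj->egj", N, sphere_mesh.nodes[sphere_mesh.elems])
        n = Xg / np.linalg.norm(Xg, axis=-1, keepdims=True)
        srr = np.einsum("egi,egij,egj->eg", n, sig, n)
        hoop = 0.5 * (np.einsum("egii->eg", sig) - srr)
        assert hoop.mean() == pytest.approx(0.002 * 9.0 / (2 * 0.5), rel=0.05)

    def test_displacements_halve_when_stiffness_doubles(self, sphere_mesh):
        """In the small-load linear regime, u scales as 1/mu."""
        from sclerapuff.material import MaterialField

        bcs = BoundaryConditions.from_mesh(sphere_mesh)
        umax = {}
        for mu in (0.083, 0.166):
            field = MaterialField.from_mesh(sphere_mesh, mu=mu)
            m = FEModel.from_mesh(sphere_mesh, field, bcs)
            m.add_load(
                "iop",
                PressureLoad.uniform(sphere_mesh.face_sets["inner_surface"], 1.0),
            )
            s = m.solve([{"iop": 2e-4}])
            umax[mu] = np.linalg.norm(s.final - s.reference, axis=1).max()
        assert umax[0.083] / umax[0.166] == pytest.approx(2.0, rel=0.02)

    def test_bit_identical_repeat_solves(self, sphere_mesh):
        from sclerapuff.material import MaterialField

        bcs = BoundaryConditions.from_mesh(sphere_mesh)
        finals = []
        for _ in range(2):
            field = MaterialField.from_mesh(sphere_mesh, mu=0.083)
            m = FEModel.from_mesh(sphere_mesh, field, bcs)
            m.add_load(
                "iop",
                PressureLoad.uniform(sphere_mesh.face_sets["inner_surface"], 1.0),
            )
            finals.append(m.solve([{"iop": 0.002}]).final)
        assert np.array_equal(finals[0], finals[1])  # bit-identical

    def test_solver_failure_carries_last_state(self):
        """An unsolvable load reports failure with the last converged
        state attached rather than crashing."""
        from sclerapuff.fe import SolverError

        nodes, elems = _single_hex()
        model = FEModel(
            nodes=nodes, elems=elems, mu_elem=np.array([0.083]),
            kappa_elem=np.array([3320.0]), alpha=40.0,
            fixed_dofs=np.array([0, 1, 2, 4, 5, 8]),
            cfg=SolverConfig(max_newton_iters=8, min_substep=1 / 4),
        )
        model.add_load("p", PressureLoad.uniform(model.elems[:, FACE_OUTER], 1.0))
        with pytest.raises(SolverError) as exc_info:
            model.solve([{"p": 1e4}])  # absurd pressure: no equilibrium
        assert exc_info.value.last_u is not None


def test_solution_table_layout(sphere_mesh):
    from sclerapuff.material import MaterialField

    field = MaterialField.from_mesh(sphere_mesh, mu=0.083)
    m = FEModel.from_mesh(
        sphere_mesh, field, BoundaryConditions.from_mesh(sphere_mesh)
    )
    m.add_load(
        "iop", PressureLoad.uniform(sphere_mesh.face_sets["inner_surface"], 1.0)
    )
    sol = m.solve([{"iop": 1e-4}])
    df = sol.to_frame()
    assert list(df.columns) == ["node", "step", "x", "y", "z"]
    assert df["step"].nunique() == 2  # reference + one load step
    assert len(df) == 2 * sphere_mesh.n_nodes
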