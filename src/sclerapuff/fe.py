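"""Quasi-static nonlinear finite-element core.

Total-Lagrangian formulation on 20-node serendipity hexahedra with uniform
2x2x2 reduced integration, the Ogden material of :mod:`sclerapuff.material`,
follower (pressure) surface loads with their load-stiffness contribution,
and incremental load stepping with Newton iteration and automatic step
cutback.  The linear solver is a sparse direct LU factorisation (the
follower-load stiffness makes the tangent slightly nonsymmetric), giving
bit-reproducible solutions for identical inputs.

Units: mm - MPa - N throughout; 1 mmHg = 133.322 Pa exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._kernels import HAVE_NUMBA, fint_kernel
from .material import MaterialField, cauchy_from_pk2, stress_and_tangent
from .shapefn import gauss_points, hex20_shape, quad8_shape

__all__ = [
    "MMHG_TO_MPA",
    "SolverConfig",
    "BoundaryConditions",
    "PressureLoad",
    "Solution",
    "SolverError",
    "FEModel",
    "solve_static",
]

#: exact unit conversion for intraocular pressure
MMHG_TO_MPA = 133.322e-6


class SolverError(RuntimeError):
    """Newton iteration failed after all step cutbacks.

    Carries the last converged displacement field (``last_u``) and the load
    scales at which it was obtained, so callers can inspect partial results.
    """

    def __init__(self, msg, last_u=None, last_scales=None):
        super().__init__(msg)
        self.last_u = last_u
        self.last_scales = last_scales


@dataclass(frozen=True)
class SolverConfig:
    """Newton/stepping controls (solver parameters, not tissue physics)."""

    newton_tol: float = 1.0e-6
    #: generous cap: most iterations reuse the factorised tangent (cheap)
    max_newton_iters: int = 80
    #: iterations of no net progress before a load-step cutback
    stall_iters: int = 16
    max_cutbacks: int = 8
    min_substep: float = 1.0 / 256.0
    face_quad_order: int = 3
    #: secondary displacement criterion, mm: accept when the Newton update
    #: is this small (the force residual hits its assembly round-off floor
    #: long before the relative tolerance when the material is very stiff)
    u_stationary_tol: float = 1.0e-9

    def __post_init__(self):
        if self.newton_tol <= 0 or self.max_newton_iters < 1:
            raise ValueError("newton_tol must be > 0 and max_newton_iters >= 1")


@dataclass
class BoundaryConditions:
    """Homogeneous displacement constraints as a set of fixed dof indices."""

    fixed_dofs: np.ndarray

    @classmethod
    def from_mesh(cls, mesh) -> "BoundaryConditions":
        """Symmetry faces (zero normal displacement) + fixed posterior pole."""
        fixed = []
        sag = mesh.node_sets["symmetry_face_sagittal"]
        fixed.append(3 * sag + 2)  # u_z = 0 on the sagittal plane (z = 0)
        ax = mesh.node_sets["symmetry_face_axial"]
        if ax.size:
            fixed.append(3 * ax + 1)  # u_y = 0 on the axial plane (y = 0)
        pole = mesh.node_sets["posterior_pole_node"]
        for i in range(3):
            fixed.append(3 * pole + i)
        return cls(fixed_dofs=np.unique(np.concatenate(fixed)))


@dataclass
class PressureLoad:
    """Follower pressure on a quadratic-quad face set.

    ``p_gp`` holds the unit-scale pressure (MPa) at every face Gauss point;
    the face winding must put the tangent cross product out of the solid, so
    positive pressure pushes into the wall (cavity pressure inflates, an
    external puff indents).
    """

    faces: np.ndarray  # (F, 8) node ids
    p_gp: np.ndarray  # (F, Q) MPa

    @classmethod
    def uniform(cls, faces: np.ndarray, pressure: float, quad_order: int = 3):
        q = quad_order * quad_order
        return cls(faces=faces, p_gp=np.full((faces.shape[0], q), float(pressure)))


@dataclass
class Solution:
    """Converged nodal positions at every load step of one solve."""

    reference: np.ndarray  # (N, 3) reference (step-0) coordinates
    positions: list  # list of (N, 3), one per scheduled step incl. step 0
    converged: list
    load_scales: list  # list of {load name: scale}

    @property
    def final(self) -> np.ndarray:
        return self.positions[-1]

    def displacement(self, step: int = -1) -> np.ndarray:
        return self.positions[step] - self.reference

    def to_frame(self):
        """Long-format table (node, step, x, y, z) mirroring a per-step
        node-position export."""
        import pandas as pd

        rows = []
        for s, pos in enumerate(self.positions):
            df = pd.DataFrame(pos, columns=["x", "y", "z"])
            df.insert(0, "node", np.arange(pos.shape[0]))
            df.insert(1, "step", s)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


class FEModel:
    """Assembled FE problem: one reference geometry + material + loads.

    The reference coordinates may differ from the design mesh (the
    stress-free iteration re-bases the model); material grading is carried
    per element and never re-derived from the moving geometry.
    """

    def __init__(
        self,
        nodes: np.ndarray,
        elems: np.ndarray,
        mu_elem: np.ndarray,
        kappa_elem: np.ndarray,
        alpha: float,
        fixed_dofs: np.ndarray,
        cfg: SolverConfig | None = None,
    ):
        self.cfg = cfg or SolverConfig()
        self.nodes = np.asarray(nodes, dtype=float)
        self.elems = np.asarray(elems, dtype=np.int64)
        self.alpha = float(alpha)
        self.n_nodes = self.nodes.shape[0]
        self.ndof = 3 * self.n_nodes
        self.fixed = np.asarray(fixed_dofs, dtype=np.int64)
        free_mask = np.ones(self.ndof, dtype=bool)
        free_mask[self.fixed] = False
        self.free = np.where(free_mask)[0]
        self.loads: dict[str, PressureLoad] = {}

        # --- volume quadrature data (2x2x2 uniform reduced integration) ---
        pts, w = gauss_points(2, 3)
        _, dN = hex20_shape(pts)  # (8, 20, 3)
        X = self.nodes[self.elems]  # (E, 20, 3)
        J0 = np.einsum("gap,eaj->egpj", dN, X)
        detJ0 = np.linalg.det(J0)
        if np.any(detJ0 <= 0):
            raise ValueError("reference mesh has non-positive Jacobians")
        invJ0 = np.linalg.inv(J0)
        self.gradN = np.einsum("egjp,gap->egaj", invJ0, dN)  # dN_a/dX_j
        self.wdet = detJ0 * w[None, :]  # (E, 8)
        self.mu_gp = np.broadcast_to(
            np.asarray(mu_elem, dtype=float)[:, None], detJ0.shape
        )
        self.kappa_gp = np.broadcast_to(
            np.asarray(kappa_elem, dtype=float)[:, None], detJ0.shape
        )
        # contiguous copies + exponent for the compiled residual kernel
        self._mu_gp_c = np.ascontiguousarray(self.mu_gp)
        self._kap_gp_c = np.ascontiguousarray(self.kappa_gp)
        self._half_alpha = int(round(self.alpha / 2.0))
        # scatter indices for the 60x60 element matrices
        edof = (3 * self.elems[:, :, None] + np.arange(3)).reshape(-1, 60)
        self.edof = edof
        (self._Kpos, self._Kindices, self._Kindptr, self._Knnz) = _csr_pattern(
            self.elems.tobytes(), self.elems.shape[0], self.ndof
        )
        # bandwidth-reducing permutation of the free block (pattern is
        # constant): NATURAL ordering on the RCM-permuted matrix beats
        # fill-reducing column orderings at these sizes
        pat = sp.csr_matrix(
            (np.ones(self._Knnz), self._Kindices, self._Kindptr),
            shape=(self.ndof, self.ndof),
        )[self.free, :][:, self.free].tocsc()
        from scipy.sparse.csgraph import reverse_cuthill_mckee

        self._rcm = np.asarray(reverse_cuthill_mckee(pat, symmetric_mode=True))
        self._rcm_inv = np.argsort(self._rcm)
        # gather map: full-pattern data slot -> reduced RCM-permuted CSC
        # slot, so one fancy index replaces slicing + permuting per solve
        rows_full = np.repeat(np.arange(self.ndof), np.diff(self._Kindptr))
        cols_full = self._Kindices
        self._fullkey = rows_full * self.ndof + cols_full  # sorted
        rank = -np.ones(self.ndof, dtype=np.int64)
        rank[self.free] = np.arange(self.free.size)
        rr, cc = rank[rows_full], rank[cols_full]
        keep = (rr >= 0) & (cc >= 0)
        src = np.where(keep)[0]
        pr = self._rcm_inv[rr[keep]]
        pc = self._rcm_inv[cc[keep]]
        order = np.lexsort((pr, pc))  # CSC: by column, then row
        self._gather = src[order]
        self._red_indices = pr[order]
        self._red_indptr = np.searchsorted(pc[order], np.arange(self.free.size + 1))
        self._loadpos: dict[str, np.ndarray] = {}
        # constant strain-displacement matrices B[(iJ),(bk)] = d_ik dN_b/dX_J
        ne, ng = self.wdet.shape
        B = np.zeros((ng, ne, 9, 60))
        gT = self.gradN.transpose(1, 0, 3, 2)  # (g, e, J, b)
        for i in range(3):
            B[:, :, 3 * i : 3 * i + 3, i::3] = gT
        self._B = B
        # quadrature weights folded into B^T: Ke = sum_g BTw @ (A @ B)
        self._BTw = (
            B.transpose(0, 1, 3, 2) * self.wdet.T[:, :, None, None]
        ).copy()

        # --- face quadrature (shared by all pressure loads) ---
        fq = self.cfg.face_quad_order
        fpts, fw = gauss_points(fq, 2)
        self.Nf, self.dNf = quad8_shape(fpts)  # (Q, 8), (Q, 8, 2)
        self.fw = fw

    @classmethod
    def from_mesh(cls, mesh, fieldm: MaterialField, bcs: BoundaryConditions,
                  cfg: SolverConfig | None = None, reference=None) -> "FEModel":
        return cls(
            nodes=mesh.nodes if reference is None else reference,
            elems=mesh.elems,
            mu_elem=fieldm.mu_elem,
            kappa_elem=fieldm.kappa_elem,
            alpha=fieldm.alpha,
            fixed_dofs=bcs.fixed_dofs,
            cfg=cfg,
        )

    def add_load(self, name: str, load: PressureLoad) -> None:
        if load.faces.shape[0] == 0:
            raise ValueError(f"load {name!r} has an empty face set")
        if not np.all(np.isfinite(load.p_gp)):
            raise ValueError(f"load {name!r} has non-finite pressures")
        self.loads[name] = load

    # ------------------------------------------------------------------ #
    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.elems]
        F = np.einsum("eai,egaJ->egiJ", ue, self.gradN)
        F += np.eye(3)
        return F

    def internal(self, u: np.ndarray, want_K: bool = True):
        """Internal force vector and (optionally) tangent stiffness."""
        if not want_K and HAVE_NUMBA:
            ue = np.ascontiguousarray(u.reshape(-1, 3)[self.elems])
            f, mindet = fint_kernel(
                self.gradN, self.wdet, ue, self._mu_gp_c, self._kap_gp_c,
                self._half_alpha,
            )
            if mindet <= 0:
                raise FloatingPointError(
                    "element inversion: non-positive deformation Jacobian"
                )
            fint = np.zeros(self.ndof)
            np.add.at(fint, self.edof.reshape(-1, 20, 3), f)
            return fint, None
        F = self.deformation_gradients(u)
        S, DD = stress_and_tangent(
            F, self.mu_gp, self.alpha, self.kappa_gp, want_tangent=want_K
        )
        P = np.einsum("egiJ,egJK->egiK", F, S)
        f = np.einsum("eg,egiJ,egaJ->eai", self.wdet, P, self.gradN)
        fint = np.zeros(self.ndof)
        np.add.at(fint, self.edof.reshape(-1, 20, 3), f)
        if not want_K:
            return fint, None
        data = self._tangent_data(F, S, DD)
        K = sp.csr_matrix(
            (data, self._Kindices, self._Kindptr), shape=(self.ndof, self.ndof)
        )
        return fint, K

    def _tangent_data(self, F, S, DD) -> np.ndarray:
        """Assembled tangent values on the precomputed CSR pattern."""
        # A_iJkL = F_iM DD_MJNL F_kN + delta_ik S_JL via batched matmuls
        ne, ng = self.wdet.shape
        tmp = (F @ DD.reshape(ne, ng, 3, 27)).reshape(ne, ng, 3, 3, 3, 3)
        # contract the second F over N: rearrange (i,J,N,L) -> (i,J,L,N)
        tmp = tmp.transpose(0, 1, 2, 3, 5, 4).reshape(ne, ng, 27, 3)
        A = (tmp @ F.transpose(0, 1, 3, 2)).reshape(ne, ng, 3, 3, 3, 3)
        A = A.transpose(0, 1, 2, 3, 5, 4).copy()  # (i,J,L,k) -> (i,J,k,L)
        for i in range(3):
            A[:, :, i, :, i, :] += S
        # Ke = sum_g w detJ B^T A B with B[(iJ),(bk)] = delta_ik dN_b/dX_J
        Amat = A.reshape(ne, ng, 9, 9)
        Ke = np.zeros((ne, 60, 60))
        for g in range(ng):
            Ke += self._BTw[g] @ (Amat[:, g] @ self._B[g])
        data = np.zeros(self._Knnz)
        np.add.at(data, self._Kpos, Ke.reshape(-1))
        return data

    def external(self, u: np.ndarray, scales: dict, want_K: bool = True):
        """Follower pressure forces on the current configuration."""
        coords = self.nodes + u.reshape(-1, 3)
        fext = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        for name, load in self.loads.items():
            s = float(scales.get(name, 0.0))
            if s == 0.0:
                continue
            xf = coords[load.faces]  # (F, 8, 3)
            a1 = np.einsum("ga,fai->fgi", self.dNf[:, :, 0], xf)
            a2 = np.einsum("ga,fai->fgi", self.dNf[:, :, 1], xf)
            gvec = np.cross(a1, a2)  # out of the solid, area-weighted
            pw = s * load.p_gp * self.fw[None, :]  # (F, Q)
            fe = -np.einsum("fg,ga,fgi->fai", pw, self.Nf, gvec)
            np.add.at(fext, (3 * load.faces[:, :, None] + np.arange(3)), fe)
            if want_K:
                Kf = self._face_stiffness(a1, a2, pw)
                fd = (3 * load.faces[:, :, None] + np.arange(3)).reshape(-1, 24)
                rows.append(np.repeat(fd, 24, axis=1).ravel())
                cols.append(np.tile(fd, (1, 24)).ravel())
                vals.append(Kf.reshape(load.faces.shape[0], -1).ravel())
        if not want_K:
            return fext, None
        if rows:
            Kext = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.ndof, self.ndof),
            ).tocsr()
        else:
            Kext = sp.csr_matrix((self.ndof, self.ndof))
        return fext, Kext

    def _face_stiffness(self, a1, a2, pw):
        """Follower load-stiffness blocks (F, 8, 3, 8, 3) for one face set.

        d(a1 x a2)_i/dx_bl = eps_ilk dN_b0 a2_k + eps_ijl a1_j dN_b1.
        """
        eps = _levi_civita()
        dg = np.einsum("ilk,gb,fgk->fgibl", eps, self.dNf[:, :, 0], a2)
        dg += np.einsum("ijl,fgj,gb->fgibl", eps, a1, self.dNf[:, :, 1])
        return -np.einsum("fg,ga,fgibl->faibl", pw, self.Nf, dg)

    def _load_positions(self, name: str) -> np.ndarray:
        """Full-pattern data slots of one load's face-stiffness entries."""
        if name not in self._loadpos:
            load = self.loads[name]
            fd = (3 * load.faces[:, :, None] + np.arange(3)).reshape(-1, 24)
            rows = np.repeat(fd, 24, axis=1).ravel()
            cols = np.tile(fd, (1, 24)).ravel()
            keys = rows.astype(np.int64) * self.ndof + cols
            self._loadpos[name] = np.searchsorted(self._fullkey, keys)
        return self._loadpos[name]

    # ------------------------------------------------------------------ #
    def _factorize(self, u, scales):
        """LU of the tangent on the free dofs (RCM-permuted, low fill).

        Assembles straight into the precomputed reduced-CSC layout: element
        tangents and follower load stiffness land in one data array, then a
        single gather reorders it — no sparse slicing or permutation.
        """
        try:
            F = self.deformation_gradients(u)
            S, DD = stress_and_tangent(
                F, self.mu_gp, self.alpha, self.kappa_gp, want_tangent=True
            )
            data = self._tangent_data(F, S, DD)
            coords = self.nodes + u.reshape(-1, 3)
            for name, load in self.loads.items():
                s = float(scales.get(name, 0.0))
                if s == 0.0:
                    continue
                xf = coords[load.faces]
                a1 = np.einsum("ga,fai->fgi", self.dNf[:, :, 0], xf)
                a2 = np.einsum("ga,fai->fgi", self.dNf[:, :, 1], xf)
                pw = s * load.p_gp * self.fw[None, :]
                Kf = self._face_stiffness(a1, a2, pw)
                np.subtract.at(data, self._load_positions(name), Kf.reshape(-1))
            n = self.free.size
            Kp = sp.csc_matrix(
                (data[self._gather], self._red_indices, self._red_indptr),
                shape=(n, n),
            )
            lu = spla.splu(Kp, permc_spec="NATURAL", diag_pivot_thresh=0.01)
        except FloatingPointError as exc:  # element inversion -> cutback
            raise _Diverged(str(exc)) from exc
        except RuntimeError as exc:  # singular factorisation
            raise _Diverged(str(exc)) from exc
        return _PermutedLU(lu, self._rcm, self._rcm_inv)

    def _residual(self, u: np.ndarray, scales: dict):
        fint, _ = self.internal(u, want_K=False)
        fext, _ = self.external(u, scales, want_K=False)
        r = fint - fext
        free = self.free
        ref = max(np.linalg.norm(fext[free]), 1e-12)
        rn = np.linalg.norm(r[free])
        return r, rn, ref

    def _newton(self, u0: np.ndarray, scales: dict) -> np.ndarray:
        """Newton iteration with lagged-tangent reuse.

        Undamped updates (quadratic near the solution); the factorisation
        is reused while the residual keeps contracting and refreshed when
        it stalls.  Divergence (blow-up, inversion, stall, iteration cap)
        triggers a load-step cutback in the caller — for this steeply
        stiffening material, smaller well-converged load increments beat
        damped crawling from far away.
        """
        cfg = self.cfg
        u = u0.copy()
        free = self.free
        lu = None
        rn_prev = np.inf
        rn0 = None
        for it in range(cfg.max_newton_iters):
            try:
                r, rn, ref = self._residual(u, scales)
            except FloatingPointError as exc:  # element inversion -> cutback
                raise _Diverged(str(exc)) from exc
            if not np.isfinite(rn):
                raise _Diverged("non-finite residual")
            if it > 0 and rn <= cfg.newton_tol * ref:
                return u
            if rn <= 1e-14:  # identically unloaded state
                return u
            if rn0 is None:
                rn0 = rn
            if rn > 1e3 * max(rn0, ref):  # blown far past the load level
                raise _Diverged("residual blow-up")
            if it >= cfg.stall_iters and rn > 0.9 * rn0:  # no net progress
                raise _Diverged("stalled")
            # commit to the reused factorisation while the residual keeps
            # contracting at all — a reused iteration costs ~1/10th of a
            # refactorisation and the strongly stiffening material gains
            # little from fresh tangents far from the solution
            if lu is None or rn > 0.97 * rn_prev:
                lu = self._factorize(u, scales)
            du = lu.solve(-r[free])
            if not np.all(np.isfinite(du)):
                raise _Diverged("non-finite Newton update")
            if np.abs(du).max() <= cfg.u_stationary_tol:
                return u  # displacement-stationary (round-off floor)
            u[free] += du
            rn_prev = rn
        raise _Diverged(f"no convergence in {cfg.max_newton_iters} iterations")

    def solve(self, schedule: list[dict], u0: np.ndarray | None = None) -> Solution:
        """March through ``schedule`` (list of {load name: scale}).

        Each scheduled step is solved by Newton iteration from the previous
        converged state; a failed step is retried with bisected load
        increments down to ``cfg.min_substep`` of the step.
        """
        u = np.zeros(self.ndof) if u0 is None else u0.astype(float).copy()
        prev_scales = {name: 0.0 for name in self.loads}
        positions = [self.nodes + u.reshape(-1, 3)]
        converged = [True]
        applied = [dict(prev_scales)]
        u_before = None  # state at the start of the previous step
        dt0 = 1.0  # adaptive increment carried across scheduled steps
        for k, target in enumerate(schedule):
            tgt = {name: float(target.get(name, 0.0)) for name in self.loads}
            u_start = u.copy()
            try:
                u, dt0 = self._march(
                    u, prev_scales, tgt, seed_prev=u_before, dt0=min(1.0, 2 * dt0)
                )
            except SolverError:
                if k == 0 and u0 is not None and np.any(u0):
                    # a warm start inconsistent with partial loads can
                    # poison the continuation: retry cold
                    u, dt0 = self._march(np.zeros(self.ndof), prev_scales, tgt)
                else:
                    raise
            u_before = u_start
            prev_scales = tgt
            positions.append(self.nodes + u.reshape(-1, 3))
            converged.append(True)
            applied.append(dict(tgt))
        return Solution(
            reference=self.nodes.copy(),
            positions=positions,
            converged=converged,
            load_scales=applied,
        )

    def _march(self, u, frm: dict, to: dict, seed_prev=None, dt0: float = 1.0):
        """Adaptive incremental continuation between two load levels.

        Each accepted increment seeds the next with a linear extrapolation
        of the displacement path (secant predictor); ``seed_prev`` (the
        state one equal-sized scheduled step earlier) seeds the predictor
        for the very first increment, and ``dt0`` (carried across
        scheduled steps) avoids re-probing increments that just failed.
        Returns ``(u, last accepted dt)``.
        """
        cfg = self.cfg
        t = 0.0
        dt = dt0
        dt_last = dt0
        u_prev = seed_prev
        dt_prev = 1.0 if seed_prev is not None else None
        while t < 1.0 - 1e-12:
            dt = min(dt, 1.0 - t)
            tt = t + dt
            scales = {k: frm[k] + tt * (to[k] - frm[k]) for k in to}
            if u_prev is not None and dt_prev is not None and dt_prev > 0:
                guess = u + (u - u_prev) * (dt / dt_prev)
            else:
                guess = u
            try:
                u_new = self._newton(guess, scales)
            except _Diverged:
                try:  # predictor may overshoot: retry from the last state
                    u_new = self._newton(u, scales) if guess is not u else None
                except _Diverged:
                    u_new = None
                if u_new is None:
                    dt *= 0.5
                    if dt < cfg.min_substep:
                        raise SolverError(
                            f"step cutback exhausted at t={t:.4f}",
                            last_u=u,
                            last_scales={
                                k: frm[k] + t * (to[k] - frm[k]) for k in to
                            },
                        )
                    continue
            u_prev, dt_prev = u, dt
            u = u_new
            t = tt
            dt_last = dt
            dt *= 2.0
        return u, dt_last

    # ------------------------------------------------------------------ #
    def cauchy_stress(self, u: np.ndarray):
        """Cauchy stress at every volume Gauss point, (E, 8, 3, 3), MPa."""
        F = self.deformation_gradients(u)
        S, _ = stress_and_tangent(
            F, self.mu_gp, self.alpha, self.kappa_gp, want_tangent=False
        )
        return cauchy_from_pk2(F, S)


class _Diverged(Exception):
    pass


class _PermutedLU:
    """LU of the RCM-permuted free block, solving in the original order."""

    __slots__ = ("lu", "perm", "iperm")

    def __init__(self, lu, perm, iperm):
        self.lu = lu
        self.perm = perm
        self.iperm = iperm

    def solve(self, b):
        return self.lu.solve(b[self.perm])[self.iperm]


from functools import lru_cache  # noqa: E402


@lru_cache(maxsize=16)
def _csr_pattern(elems_bytes: bytes, n_elems: int, ndof: int):
    """Precompute the CSR sparsity pattern of the assembled tangent.

    Keyed on the raw connectivity so the several models built per study
    evaluation (stress-free iterates, preload, puff) share one pattern;
    per-assembly scatter is then a single deterministic add.at.
    """
    elems = np.frombuffer(elems_bytes, dtype=np.int64).reshape(n_elems, 20)
    edof = (3 * elems[:, :, None] + np.arange(3)).reshape(-1, 60)
    rows = np.repeat(edof, 60, axis=1).ravel()
    cols = np.tile(edof, (1, 60)).ravel()
    order = np.lexsort((cols, rows))
    rs, cs = rows[order], cols[order]
    newgrp = np.concatenate([[True], (rs[1:] != rs[:-1]) | (cs[1:] != cs[:-1])])
    gid = np.cumsum(newgrp) - 1
    pos = np.empty(order.size, dtype=np.int64)
    pos[order] = gid
    indices = cs[newgrp]
    indptr = np.searchsorted(rs[newgrp], np.arange(ndof + 1))
    return pos, indices, indptr, int(newgrp.sum())


def _levi_civita() -> np.ndarray:
    eps = np.zeros((3, 3, 3))
    eps[0, 1, 2] = eps[1, 2, 0] = eps[2, 0, 1] = 1.0
    eps[0, 2, 1] = eps[2, 1, 0] = eps[1, 0, 2] = -1.0
    return eps


def solve_static(mesh, fieldm, bcs, loads: dict, schedule: list[dict],
                 cfg: SolverConfig | None = None, reference=None,
                 u0=None) -> Solution:
    """One-call static solve: build the model, attach loads, run a schedule.

    ``loads`` maps name -> PressureLoad (unit scale); ``schedule`` is a list
    of {name: scale} per load step.
    """
    model = FEModel.from_mesh(mesh, fieldm, bcs, cfg, reference=reference)
    for name, load in loads.items():
        model.add_load(name, load)
    return model.solve(schedule, u0=u0)
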