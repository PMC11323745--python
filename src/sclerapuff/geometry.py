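"""Parametric rabbit-globe geometry and structured quadratic meshing.

The globe is a shell between two ellipsoids of revolution about the optical
(axial) axis: the exterior has horizontal diameter ``AL`` and vertical
diameter ``EL``; the interior is chosen so the wall is ``THK`` thick at the
equator and ``t_post`` (0.6 mm) thick at the posterior pole.  The cornea is
a spherical cap of thickness ``t_cornea`` (0.4 mm) whose junction with the
sclera sits at ``cornea_angle`` (120 deg) from the optic nerve and whose apex
protrudes ``apex_offset`` (1 mm) beyond the exterior ellipse, so the total
axial extent is ``AL + apex_offset``.

Coordinate convention (used everywhere in the package): origin at the globe
centre; the axial/optical axis is global x with the posterior pole at
negative x; global y is the equatorial (vertical) direction, so the
"uppermost point" — the air-puff centre — is (0, EL/2, 0); global z is out
of the sagittal plane.  The default mesh is a quarter model (z >= 0 and
y >= 0 boundaries are symmetry planes); a half model (sagittal symmetry
only) is available for non-symmetric load placements.

Meshing is structured: meridian stations x azimuth x radial layers of
20-node serendipity hexahedra, with collapsed (wedge) elements at the two
poles, meridian/azimuth node clustering around the air-puff site, and named
node/face sets for boundary conditions, cavity pressure, and the air-puff
patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shapefn import FACE_INNER, FACE_OUTER, gauss_points, hex20_shape

__all__ = [
    "GlobeParams",
    "Mesh",
    "AxialCoordinateMap",
    "CrossSection",
    "build_globe_cross_section",
    "generate_mesh",
    "compute_axial_coordinates",
    "mesh_volume",
    "export_vtk",
]


class InvalidGeometryError(ValueError):
    """Raised when the parametric globe geometry is degenerate."""


class MeshingError(ValueError):
    """Raised when a requested mesh cannot resolve the geometry."""


@dataclass(frozen=True)
class GlobeParams:
    """The six study inputs plus fixed geometric constants of one virtual eye.

    AL/EL are the axial/equatorial exterior diameters (mm), THK the scleral
    wall thickness at the equator (mm).  ``include_cornea=False`` builds a
    closed ellipsoidal shell (posterior thickness at both poles), used for
    fore-aft-symmetry checks.
    """

    AL: float = 18.0
    EL: float = 19.0
    THK: float = 0.35
    t_post: float = 0.6
    t_cornea: float = 0.4
    cornea_angle: float = 120.0
    apex_offset: float = 1.0
    include_cornea: bool = True

    def __post_init__(self) -> None:
        if self.AL <= 0 or self.EL <= 0:
            raise InvalidGeometryError("AL and EL must be positive")
        if not 0 < self.THK < self.EL / 2:
            raise InvalidGeometryError("THK must lie in (0, EL/2)")
        if min(self.t_post, self.t_cornea, self.apex_offset) <= 0:
            raise InvalidGeometryError("t_post, t_cornea, apex_offset must be positive")
        if not 0 < self.cornea_angle < 180:
            raise InvalidGeometryError("cornea_angle must lie in (0, 180) degrees")
        if self.AL / 2 - self.t_post <= 0 or self.EL / 2 - self.THK <= 0:
            raise InvalidGeometryError("interior ellipse has non-positive semi-axis")

    # exterior / interior semi-axes (a along the optical axis, b equatorial)
    @property
    def a_out(self) -> float:
        return self.AL / 2

    @property
    def b_out(self) -> float:
        return self.EL / 2

    @property
    def a_in(self) -> float:
        return self.AL / 2 - self.t_post

    @property
    def b_in(self) -> float:
        return self.EL / 2 - self.THK


@dataclass
class CrossSection:
    """Sagittal-plane boundary curves of the globe outline (z = 0, y >= 0)."""

    curves: dict[str, np.ndarray]  # name -> (n, 2) arrays of (x, y), mm
    theta_junction: float  # scleral polar angle of the limbus, rad
    cornea_center_x: float
    cornea_radius: float
    psi_junction: float  # corneal cap half-angle at the limbus, rad

    def wall_thickness(self, theta) -> np.ndarray:
        """Scleral wall thickness at parametric polar angle(s) theta."""
        p = self._params
        d = np.stack(
            [
                (p.a_out - p.a_in) * np.cos(theta),
                (p.b_out - p.b_in) * np.sin(theta),
            ],
            axis=-1,
        )
        return np.linalg.norm(d, axis=-1)

    _params: GlobeParams = None  # set by the builder


def _cornea_sphere(p: GlobeParams) -> tuple[float, float, float]:
    """(center_x, radius, psi_junction) of the corneal cap."""
    th_c = np.deg2rad(p.cornea_angle)
    xj = -p.a_out * np.cos(th_c)
    rhoj = p.b_out * np.sin(th_c)
    d = p.a_out + p.apex_offset - xj
    if d <= 0:
        raise InvalidGeometryError("corneal apex lies behind the limbus")
    R = (d * d + rhoj * rhoj) / (2 * d)
    if R <= p.t_cornea:
        raise InvalidGeometryError("corneal radius smaller than corneal thickness")
    xc = p.a_out + p.apex_offset - R
    psi_j = np.arctan2(rhoj, xj - xc)
    return xc, R, psi_j


def build_globe_cross_section(params: GlobeParams) -> CrossSection:
    """Planar sagittal boundary curves: scleral ellipse arcs + corneal arcs.

    The polar angle theta runs from 0 at the posterior pole (x = -AL/2) to
    pi at the anterior pole; the sclera occupies [0, cornea_angle].
    """
    p = params
    th_c = np.deg2rad(p.cornea_angle) if p.include_cornea else np.pi
    th = np.linspace(0.0, th_c, 181)
    ext = np.stack([-p.a_out * np.cos(th), p.b_out * np.sin(th)], axis=-1)
    itr = np.stack([-p.a_in * np.cos(th), p.b_in * np.sin(th)], axis=-1)
    curves = {"exterior_ellipse": ext, "interior_ellipse": itr}
    xc = R = psi_j = float("nan")
    if p.include_cornea:
        xc, R, psi_j = _cornea_sphere(p)
        psi = np.linspace(psi_j, 0.0, 61)
        curves["cornea_outer"] = np.stack(
            [xc + R * np.cos(psi), R * np.sin(psi)], axis=-1
        )
        curves["cornea_inner"] = np.stack(
            [xc + (R - p.t_cornea) * np.cos(psi), (R - p.t_cornea) * np.sin(psi)],
            axis=-1,
        )
    cs = CrossSection(
        curves=curves,
        theta_junction=th_c,
        cornea_center_x=xc,
        cornea_radius=R,
        psi_junction=psi_j,
    )
    cs._params = p
    return cs


@dataclass
class Mesh:
    """Quadratic solid mesh of the globe shell.

    ``face_sets`` hold (F, 8) quadratic-quad connectivity wound so the face
    normal (t1 x t2) points out of the solid; ``node_sets`` hold node ids.
    Region tag 0 = sclera, 1 = cornea.
    """

    nodes: np.ndarray  # (N, 3) mm
    elems: np.ndarray  # (E, 20) int
    region: np.ndarray  # (E,) int
    face_sets: dict[str, np.ndarray]
    node_sets: dict[str, np.ndarray]
    params: GlobeParams
    symmetry: str = "quarter"
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    @property
    def posterior_pole_node(self) -> int:
        return int(self.node_sets["posterior_pole_node"][0])


def _clustered_knots(s: np.ndarray, n: int, centers, sigma: float, amp: float):
    """n+1 knots over the arc-length array ``s`` with Gaussian refinement.

    ``s`` is a dense monotone arc-length sample; knots are equal-quantile
    points of the density 1 + amp * sum_c exp(-(s-c)^2 / (2 sigma^2)).
    Returns fractional indices into ``s`` (for interpolating any companion
    parameter array).
    """
    w = np.ones_like(s)
    for c in centers:
        w = w + amp * np.exp(-((s - c) ** 2) / (2 * sigma * sigma))
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(s))])
    targets = np.linspace(0.0, cum[-1], n + 1)
    return np.interp(targets, cum, np.arange(s.size, dtype=float))


def _meridian_stations(p: GlobeParams, n_scl: int, n_cor: int):
    """Half-step meridian stations: list of ('s', theta) / ('c', psi) pairs."""
    th_c = np.deg2rad(p.cornea_angle) if p.include_cornea else np.pi
    th_fine = np.linspace(0.0, th_c, 2001)
    xy = np.stack([-p.a_out * np.cos(th_fine), p.b_out * np.sin(th_fine)], axis=-1)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_eq = np.interp(np.pi / 2, th_fine, s)
    idx = _clustered_knots(s, n_scl, [s_eq], sigma=2.0, amp=2.5)
    # half-step stations (element boundaries + midsides)
    idx_half = np.interp(np.arange(2 * n_scl + 1) / 2.0, np.arange(n_scl + 1), idx)
    th_knots = np.interp(idx_half, np.arange(th_fine.size), th_fine)
    stations = [("s", float(t)) for t in th_knots]
    if p.include_cornea:
        _, _, psi_j = _cornea_sphere(p)
        psi = np.linspace(psi_j, 0.0, 2 * n_cor + 1)[1:]  # junction shared
        stations += [("c", float(v)) for v in psi]
    return stations


def generate_mesh(
    params: GlobeParams,
    resolution: int = 5000,
    n_radial: int = 2,
    symmetry: str = "quarter",
    patch_radius: float = 4.0,
) -> Mesh:
    """Mesh the globe shell into 20-node hexahedra.

    ``resolution`` is a target solid-element count (met within ~20%);
    ``n_radial`` is the number of element layers through the wall (>= 2, so
    the scleral wall is always resolved by at least two elements).
    """
    p = params
    if n_radial < 2:
        raise MeshingError("need at least 2 elements through the wall thickness")
    if resolution < 24:
        raise MeshingError("resolution too coarse to resolve the globe")
    if symmetry not in ("quarter", "half"):
        raise ValueError(f"unknown symmetry mode {symmetry!r}")

    cs = build_globe_cross_section(p)
    azim_span = np.pi / 2 if symmetry == "quarter" else np.pi
    # split the element budget: meridian/azimuth ratio from arc lengths
    n_surf = resolution / n_radial
    mer_len = 0.75 * np.pi * (p.a_out + p.b_out) / 2  # rough meridian arc
    az_len = p.b_out * azim_span
    n_phi = max(3, int(round(np.sqrt(n_surf * az_len / mer_len))))
    # the meridian carries the output profile: never starve it at small
    # budgets (>= 12 elements along it before giving azimuth more)
    n_phi = max(3, min(n_phi, int(n_surf // 12)))
    n_u = max(6, int(round(n_surf / n_phi)))
    if p.include_cornea:
        n_cor = max(2, n_u // 6)
        n_scl = n_u - n_cor
    else:
        n_cor, n_scl = 0, n_u

    stations = _meridian_stations(p, n_scl, n_cor)
    n_u = n_scl + n_cor  # elements along the meridian

    # azimuth stations, clustered near phi = 0 (the sagittal plane)
    phi_fine = np.linspace(0.0, azim_span, 1001)
    s_phi = p.b_out * phi_fine
    centers = [0.0] if symmetry == "quarter" else [0.0, s_phi[-1]]
    idxp = _clustered_knots(s_phi, n_phi, centers, sigma=2.0, amp=2.5)
    idxp_half = np.interp(np.arange(2 * n_phi + 1) / 2.0, np.arange(n_phi + 1), idxp)
    phi_st = np.interp(idxp_half, np.arange(phi_fine.size), phi_fine)

    r_st = np.linspace(0.0, 1.0, 2 * n_radial + 1)

    xc, Rc, psi_j = (cs.cornea_center_x, cs.cornea_radius, cs.psi_junction)
    # inner-surface blend band: first corneal element ring after the limbus
    if p.include_cornea:
        psi_b = stations[2 * n_scl + 2][1]  # one element past the junction

    def line_points(stat, phi):
        """(inner, outer) endpoints of the radial mesh line at a station."""
        kind, ang = stat
        cphi, sphi = np.cos(phi), np.sin(phi)
        if kind == "s":
            th = ang
            outer = np.array(
                [-p.a_out * np.cos(th), p.b_out * np.sin(th) * cphi, p.b_out * np.sin(th) * sphi]
            )
            inner = np.array(
                [-p.a_in * np.cos(th), p.b_in * np.sin(th) * cphi, p.b_in * np.sin(th) * sphi]
            )
        else:
            psi = ang
            d = np.array([np.cos(psi), np.sin(psi) * cphi, np.sin(psi) * sphi])
            ctr = np.array([xc, 0.0, 0.0])
            outer = ctr + Rc * d
            inner = ctr + (Rc - p.t_cornea) * d
            if psi > psi_b:  # blend toward the scleral inner surface
                lam = (psi_j - psi) / (psi_j - psi_b)
                dj = np.array([np.cos(psi_j), np.sin(psi_j) * cphi, np.sin(psi_j) * sphi])
                scl_inner = np.array(
                    [
                        -p.a_in * np.cos(cs.theta_junction),
                        p.b_in * np.sin(cs.theta_junction) * cphi,
                        p.b_in * np.sin(cs.theta_junction) * sphi,
                    ]
                )
                delta = scl_inner - (ctr + (Rc - p.t_cornea) * dj)
                inner = inner + (1.0 - lam) * delta
        return inner, outer

    # lattice of candidate nodes: (U, P, R) half-step indices; serendipity
    # keeps nodes with at most one odd (midside) index
    nU, nP, nR = 2 * n_u + 1, 2 * n_phi + 1, 2 * n_radial + 1
    coords = {}

    def lattice_node(U, P, R):
        key = (U, P, R)
        if key in coords:
            return coords[key]
        inner, outer = line_points(stations[U], phi_st[P])
        s = r_st[R]
        coords[key] = inner + s * (outer - inner)
        return coords[key]

    # local xi -> azimuth, eta -> meridian, zeta -> radial (right-handed)
    from .shapefn import HEX20_LOCAL

    offs = [(int(ly) + 1, int(lx) + 1, int(lz) + 1) for lx, ly, lz in HEX20_LOCAL]
    elems = []
    region = []
    layer = []
    for I in range(n_u):
        for Jf in range(n_phi):
            for K in range(n_radial):
                conn = [(2 * I + du, 2 * Jf + dp, 2 * K + dr) for du, dp, dr in offs]
                elems.append(conn)
                region.append(1 if I >= n_scl else 0)
                layer.append(K)

    # resolve lattice keys to deduplicated node ids (poles collapse)
    keys = sorted({k for conn in elems for k in conn})
    pts = np.array([lattice_node(*k) for k in keys])
    rounded = np.round(pts, 8)
    uniq, inv = np.unique(rounded, axis=0, return_inverse=True)
    # map each lattice key to a unique node id, keep first exact coordinate
    node_of_key = {}
    first_pt = np.zeros((uniq.shape[0], 3))
    seen = np.zeros(uniq.shape[0], dtype=bool)
    for k, key in enumerate(keys):
        nid = int(inv[k])
        node_of_key[key] = nid
        if not seen[nid]:
            first_pt[nid] = pts[k]
            seen[nid] = True
    nodes = first_pt
    elems_id = np.array(
        [[node_of_key[k] for k in conn] for conn in elems], dtype=np.int64
    )
    region = np.array(region, dtype=np.int64)
    layer = np.array(layer, dtype=np.int64)

    # drop fully collapsed elements (can only happen at absurd coarseness)
    ok = np.array([len(set(c)) >= 6 for c in elems_id])
    elems_id, region, layer = elems_id[ok], region[ok], layer[ok]

    # ---- named sets -------------------------------------------------------
    def radial_faces(layer_k, face_ids):
        out = []
        for conn in elems_id[layer == layer_k]:
            f = conn[face_ids]
            if len(set(f[:4].tolist())) >= 3:  # drop fully collapsed slivers
                out.append(f)
        return np.array(out, dtype=np.int64)

    inner_faces = radial_faces(0, FACE_INNER)
    outer_faces = radial_faces(n_radial - 1, FACE_OUTER)
    puff_center = np.array([0.0, p.b_out, 0.0])
    centroids = nodes[outer_faces[:, :4]].mean(axis=1)
    patch = outer_faces[np.linalg.norm(centroids - puff_center, axis=1) <= patch_radius]
    if patch.shape[0] == 0:
        raise MeshingError("air-puff patch is empty; refine the mesh")

    tol = 1e-6 * max(p.AL, p.EL)
    sagittal = np.where(np.abs(nodes[:, 2]) < tol)[0]
    axial = np.where(np.abs(nodes[:, 1]) < tol)[0]
    pole = np.array([int(np.argmin(nodes[:, 0]))])

    face_sets = {
        "inner_surface": inner_faces,
        "outer_surface": outer_faces,
        "airpuff_patch": patch,
    }
    node_sets = {
        "sagittal_section": sagittal,
        "symmetry_face_sagittal": sagittal,
        "symmetry_face_axial": axial if symmetry == "quarter" else np.array([], int),
        "posterior_pole_node": pole,
    }

    mesh = Mesh(
        nodes=nodes,
        elems=elems_id,
        region=region,
        face_sets=face_sets,
        node_sets=node_sets,
        params=p,
        symmetry=symmetry,
        meta={
            "n_u": n_u,
            "n_phi": n_phi,
            "n_radial": n_radial,
            "n_scl": n_scl,
            "n_cor": n_cor,
            "resolution": resolution,
        },
    )
    _check_jacobians(mesh)
    return mesh


def _check_jacobians(mesh: Mesh) -> None:
    pts, _ = gauss_points(2, 3)
    _, dN = hex20_shape(pts)
    X = mesh.nodes[mesh.elems]  # (E, 20, 3)
    J = np.einsum("gap,eaj->egpj", dN, X)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = int(np.sum(np.any(detJ <= 0, axis=1)))
        raise MeshingError(f"{bad} elements with non-positive Jacobian")


@dataclass
class AxialCoordinateMap:
    """Signed axial distance of each element centroid from the equator.

    x > 0 toward the posterior pole; x_f is the distance from the equator to
    the most posterior scleral material point (used by the stiffness
    grading).  Anterior elements carry x < 0.
    """

    x: np.ndarray  # (E,) mm
    x_f: float  # mm


def compute_axial_coordinates(mesh: Mesh) -> AxialCoordinateMap:
    """Element-centroid axial coordinates for the material grading."""
    cent = mesh.nodes[mesh.elems[:, :8]].mean(axis=1)
    x = -cent[:, 0]  # posterior pole at negative global x
    scl_nodes = np.unique(mesh.elems[mesh.region == 0])
    x_f = float(-mesh.nodes[scl_nodes, 0].min())
    if x_f <= 0:
        raise InvalidGeometryError("degenerate geometry: x_f <= 0")
    return AxialCoordinateMap(x=x, x_f=x_f)


def mesh_volume(mesh: Mesh, coords: np.ndarray | None = None) -> float:
    """Total solid volume by 3x3x3 Gauss quadrature, mm^3."""
    pts, w = gauss_points(3, 3)
    _, dN = hex20_shape(pts)
    X = (coords if coords is not None else mesh.nodes)[mesh.elems]
    J = np.einsum("gap,eaj->egpj", dN, X)
    return float(np.einsum("eg,g->", np.linalg.det(J), w))


def export_vtk(mesh: Mesh, path, point_data: dict | None = None) -> None:
    """Write a legacy-ASCII VTK unstructured grid (quadratic hexahedra)."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nsclerapuff globe mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for xyz in mesh.nodes:
            fh.write(f"{xyz[0]:.9g} {xyz[1]:.9g} {xyz[2]:.9g}\n")
        e = mesh.n_elems
        fh.write(f"CELLS {e} {e * 21}\n")
        for conn in mesh.elems:
            fh.write("20 " + " ".join(str(int(i)) for i in conn) + "\n")
        fh.write(f"CELL_TYPES {e}\n")
        fh.write("\n".join(["25"] * e) + "\n")
        fh.write(f"CELL_DATA {e}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(r)) for r in mesh.region) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
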