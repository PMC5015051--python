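"""Finite-element mechanics of the cupula as a clamped Mindlin plate.

Each cupula is idealised as a flat plate of its central cross-section,
clamped along the whole outline (crista below, ampulla walls and roof
around), loaded by the homogeneous trans-cupular pressure differential
(default 0.05 Pa).  Transverse shear matters because cupulae are thick
(h/a up to ~0.5), so the plate is solved under Mindlin-Reissner theory
with MITC (mixed interpolation of tensorial components) elements, which
avoid the spurious shear locking of naively integrated elements in the
thin limit.  The primary element is the 4-node MITC4 quadrilateral; a
3-node MITC3 triangle is available as a fallback for irregular meshes.

Outputs feeding the torsion-pendulum model:

* volume displacement ``dV`` under the pressure step, giving the cupula
  stiffness ``k = dP/dV`` (Pa / mm^3 == g.s^-2.mm^-4);
* the cilia transfer factor ``eps = dTheta/dV`` (mdeg per nL), where
  ``dTheta`` is the mean deflection angle ``arctan(w/l)`` over the band
  of the cross-section within cilia reach ``l`` of the outline.

The degrees of freedom per node are (w, theta_x, theta_y) with shear
strains ``gamma = grad(w) - theta``; curvatures are the symmetric
gradient of theta; shear correction factor 5/6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from shapely.geometry import Polygon

from .constants import CILIA_LENGTHS_MM

SHEAR_CORRECTION = 5.0 / 6.0

#: Gauss points/weights for 2x2 quadrature on [-1, 1]^2.
_G = 1.0 / np.sqrt(3.0)
_GAUSS4 = [(-_G, -_G), (_G, -_G), (_G, _G), (-_G, _G)]


class GeometryError(ValueError):
    """Raised for invalid or unmeshable cross-section polygons."""


@dataclass
class CupulaCrossSection:
    """Central cross-section of one cupula, in the plate plane (mm).

    ``outline`` is a closed simple polygon; ``band_heights`` are the
    cilia reach options measured inward from the outline (the mesh
    places conforming strip boundaries at each height, so no element
    straddles a band border).
    """

    outline: np.ndarray
    band_heights: tuple[float, ...] = CILIA_LENGTHS_MM
    duct: str = ""

    def __post_init__(self) -> None:
        self.outline = np.asarray(self.outline, dtype=float).reshape(-1, 2)
        if len(self.outline) >= 2 and np.allclose(self.outline[0], self.outline[-1]):
            self.outline = self.outline[:-1]
        if len(self.outline) < 3:
            raise GeometryError("outline needs at least 3 distinct points")
        poly = Polygon(self.outline)
        if not poly.is_valid:
            raise GeometryError("outline polygon is self-intersecting or degenerate")
        if poly.exterior.is_ccw is False:
            self.outline = self.outline[::-1].copy()
        self.band_heights = tuple(sorted(float(h) for h in self.band_heights))
        if any(h <= 0 for h in self.band_heights):
            raise GeometryError("band heights must be positive")

    @property
    def area(self) -> float:
        return float(Polygon(self.outline).area)


@dataclass
class CupulaModel:
    """A cupula ready for plate analysis."""

    section: CupulaCrossSection
    thickness: float              # mean thickness h, mm
    gamma: float = 1.44           # shear modulus, Pa
    nu: float = 0.48              # Poisson ratio
    mesh: "PlateMesh | None" = None

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if not 0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")

    @property
    def youngs_modulus(self) -> float:
        return 2.0 * self.gamma * (1.0 + self.nu)

    @property
    def bending_rigidity(self) -> float:
        e = self.youngs_modulus
        return e * self.thickness**3 / (12.0 * (1.0 - self.nu**2))


@dataclass
class PlateMesh:
    """Conforming quadrilateral mesh of a cross-section.

    ``strip`` labels each element with -1 (main region) or the index of
    the boundary-offset strip it occupies: strip 0 lies between the
    outline and the first band height, strip 1 between the first and
    second, and so on.  The band of cilia reach ``l`` is the union of
    strips whose outer offset is <= ``l``.
    """

    nodes: np.ndarray            # (n, 2)
    quads: np.ndarray            # (m, 4)
    strip: np.ndarray            # (m,), int
    boundary_nodes: np.ndarray   # node ids on the clamped outline
    band_heights: tuple[float, ...] = CILIA_LENGTHS_MM

    def band_elements(self, cilia_length: float) -> np.ndarray:
        """Element ids within cilia reach ``cilia_length`` of the outline."""
        heights = np.asarray(self.band_heights)
        if not np.any(np.isclose(heights, cilia_length)):
            raise ValueError(
                f"cilia length {cilia_length} does not match any band height "
                f"{self.band_heights}"
            )
        n_strips = int(np.sum(heights <= cilia_length + 1e-12))
        return np.flatnonzero((self.strip >= 0) & (self.strip < n_strips))

    def min_angle_deg(self) -> float:
        q = self.nodes[self.quads]
        angles = []
        for k in range(4):
            a = q[:, (k - 1) % 4] - q[:, k]
            b = q[:, (k + 1) % 4] - q[:, k]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))

    @property
    def triangles(self) -> tuple[np.ndarray, np.ndarray]:
        """Split every quad into two triangles (for the MITC3 path)."""
        t1 = self.quads[:, [0, 1, 2]]
        t2 = self.quads[:, [0, 2, 3]]
        tris = np.vstack([t1, t2])
        strip = np.concatenate([self.strip, self.strip])
        return tris, strip


@dataclass
class PlateSolution:
    """Static plate response to a uniform pressure."""

    mesh: PlateMesh
    w: np.ndarray                # transverse deflection per node, mm
    theta: np.ndarray            # (n, 2) section rotations, rad
    pressure: float              # applied pressure, Pa
    element: str = "mitc4"
    tris: np.ndarray | None = None
    tri_strip: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Meshing


def _radius_function(outline: np.ndarray, centre: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Distance from ``centre`` to the outline along each unit direction.

    Requires the polygon to be star-shaped about ``centre`` (exactly one
    boundary crossing per ray), which holds for cupula cross-sections.
    """
    p = outline
    q = np.roll(outline, -1, axis=0)
    e = q - p  # (ne, 2)
    radii = np.empty(len(directions))
    for j, u in enumerate(directions):
        # solve centre + t*u = p + s*e  for each edge
        denom = u[0] * (-e[:, 1]) - u[1] * (-e[:, 0])
        rhs = p - centre
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (rhs[:, 0] * (-e[:, 1]) - rhs[:, 1] * (-e[:, 0])) / denom
            s = (u[0] * rhs[:, 1] - u[1] * rhs[:, 0]) / denom
        hits = t[(t > 1e-12) & (s >= -1e-12) & (s < 1.0 - 1e-12) & np.isfinite(t)]
        if len(hits) == 0:
            raise GeometryError("ray from centre misses the outline")
        hits = np.unique(np.round(hits, 9))
        if len(hits) > 1:
            raise GeometryError(
                "outline is not star-shaped about its centroid; "
                "cannot build a structured plate mesh"
            )
        radii[j] = hits[0]
    return radii


def mesh_cross_section(section: CupulaCrossSection, target_size: float) -> PlateMesh:
    """Quadrilateral O-grid mesh of a star-shaped cross-section.

    A square core around the centroid is surrounded by rings of
    quadrilaterals reaching the outline; ring boundaries are pinned to
    the cilia band heights so every element lies wholly inside one
    subregion.  Element size approximately follows ``target_size``
    except across the thin bands, which always get at least one element
    through their width.
    """
    if target_size <= 0:
        raise ValueError("target size must be positive")
    poly = Polygon(section.outline)
    centre = np.array(poly.centroid.coords[0])

    perimeter = poly.exterior.length
    n_rays = max(16, int(4 * round(perimeter / target_size / 4.0)))
    n0 = n_rays // 4

    # core square
    probe = np.stack(
        [np.cos(np.linspace(0, 2 * np.pi, 64, endpoint=False)),
         np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False))], axis=1
    )
    rho_min = _radius_function(section.outline, centre, probe).min()
    h_max = section.band_heights[-1]
    if h_max >= 0.5 * rho_min:
        raise GeometryError("band heights reach past the centre of the section")
    w0 = 0.3 * rho_min

    xs = np.linspace(-w0, w0, n0 + 1)
    core_xy = np.stack(np.meshgrid(xs, xs, indexing="ij"), axis=-1)  # (n0+1, n0+1, 2)
    core_ids = -np.ones((n0 + 1, n0 + 1), dtype=int)
    nodes: list[np.ndarray] = []

    def add_node(p: np.ndarray) -> int:
        nodes.append(p)
        return len(nodes) - 1

    for i in range(n0 + 1):
        for j in range(n0 + 1):
            core_ids[i, j] = add_node(centre + core_xy[i, j])

    quads: list[list[int]] = []
    strips: list[int] = []
    for i in range(n0):
        for j in range(n0):
            quads.append(
                [core_ids[i, j], core_ids[i + 1, j], core_ids[i + 1, j + 1], core_ids[i, j + 1]]
            )
            strips.append(-1)

    # core boundary, counter-clockwise from the (+w0, -w0) corner
    ring0 = []
    for j in range(n0):                      # right edge, bottom -> top
        ring0.append(core_ids[n0, j])
    for i in range(n0, 0, -1):               # top edge, right -> left
        ring0.append(core_ids[i, n0])
    for j in range(n0, 0, -1):               # left edge, top -> bottom
        ring0.append(core_ids[0, j])
    for i in range(n0):                      # bottom edge, left -> right
        ring0.append(core_ids[i, 0])
    ring0 = np.array(ring0)
    assert len(ring0) == n_rays

    ray_pts = np.array([nodes[i] for i in ring0])
    dirs = ray_pts - centre
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    rho = _radius_function(section.outline, centre, dirs)
    r0 = np.linalg.norm(ray_pts - centre, axis=1)

    # radial layer fractions: interior layers, then band strips (outermost last)
    heights = [0.0] + list(section.band_heights)  # offsets from the outline
    inner_extent = float(np.median(rho - r0)) - h_max
    n_inner = max(2, int(np.ceil(inner_extent / target_size)))
    layers: list[tuple[str, float, float, int]] = [("inner", h_max, None, n_inner)]
    strip_layers: list[tuple[int, float, float, int]] = []
    for s_idx in range(len(section.band_heights) - 1, -1, -1):
        lo, hi = heights[s_idx], heights[s_idx + 1]  # offsets, hi further from wall
        n_sub = max(1, int(np.ceil((hi - lo) / target_size)))
        strip_layers.append((s_idx, lo, hi, n_sub))

    rings = [ring0]
    # interior rings from the core to the innermost band border
    for k in range(1, n_inner + 1):
        t = k / n_inner
        radii = r0 + t * ((rho - h_max) - r0)
        ring = np.array([add_node(centre + radii[j] * dirs[j]) for j in range(n_rays)])
        rings.append(ring)
    # band strip rings, working outward to the outline
    ring_strip_label: list[int] = [-1] * n_inner
    for s_idx, lo, hi, n_sub in strip_layers:
        for k in range(1, n_sub + 1):
            off = hi - (hi - lo) * k / n_sub  # offset from outline
            radii = rho - off
            ring = np.array([add_node(centre + radii[j] * dirs[j]) for j in range(n_rays)])
            rings.append(ring)
            ring_strip_label.append(s_idx)

    for k in range(len(rings) - 1):
        inner, outer = rings[k], rings[k + 1]
        for j in range(n_rays):
            jn = (j + 1) % n_rays
            quads.append([inner[j], outer[j], outer[jn], inner[jn]])
            strips.append(ring_strip_label[k])

    mesh = PlateMesh(
        nodes=np.array(nodes),
        quads=np.array(quads, dtype=int),
        strip=np.array(strips, dtype=int),
        boundary_nodes=rings[-1].copy(),
        band_heights=section.band_heights,
    )
    min_angle = mesh.min_angle_deg()
    if min_angle < 20.0:
        warnings.warn(
            f"plate mesh contains elements with minimum angle {min_angle:.1f} deg",
            stacklevel=2,
        )
    return mesh


# ---------------------------------------------------------------------------
# MITC4 / MITC3 elements


def _quad_shape(r: float, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = 0.25 * np.array(
        [(1 - r) * (1 - s), (1 + r) * (1 - s), (1 + r) * (1 + s), (1 - r) * (1 + s)]
    )
    dnr = 0.25 * np.array([-(1 - s), (1 - s), (1 + s), -(1 + s)])
    dns = 0.25 * np.array([-(1 - r), -(1 + r), (1 + r), (1 - r)])
    return n, dnr, dns


def _covariant_shear_row(
    xe: np.ndarray, r: float, s: float, direction: int
) -> np.ndarray:
    """Row of the covariant shear strain (gamma_r or gamma_s) in nodal DOFs."""
    n, dnr, dns = _quad_shape(r, s)
    dn = dnr if direction == 0 else dns
    gvec = xe.T @ dn  # d(x,y)/d(r or s)
    row = np.zeros(12)
    row[0::3] = dn
    row[1::3] = -n * gvec[0]
    row[2::3] = -n * gvec[1]
    return row


def _mitc4_element(
    xe: np.ndarray, db: np.ndarray, ds: float, q: float, mitc: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Stiffness (12x12) and load (12,) of one Mindlin plate quad.

    With ``mitc=False`` the transverse shear is interpolated directly
    from the nodal field (a naively integrated bilinear element), which
    locks in the thin limit -- retained only as a reference for
    demonstrating why the MITC interpolation is required.
    """
    ke = np.zeros((12, 12))
    fe = np.zeros(12)
    if mitc:
        row_rt = _covariant_shear_row(xe, 0.0, 1.0, 0)
        row_rb = _covariant_shear_row(xe, 0.0, -1.0, 0)
        row_sr = _covariant_shear_row(xe, 1.0, 0.0, 1)
        row_sl = _covariant_shear_row(xe, -1.0, 0.0, 1)
    for r, s in _GAUSS4:
        n, dnr, dns = _quad_shape(r, s)
        jac = np.array([xe.T @ dnr, xe.T @ dns])  # [[x_r, y_r], [x_s, y_s]]
        det = np.linalg.det(jac)
        if det <= 0:
            raise GeometryError("inverted quadrilateral element")
        jinv = np.linalg.inv(jac)
        dn_xy = jinv @ np.array([dnr, dns])  # (2, 4)
        bb = np.zeros((3, 12))
        bb[0, 1::3] = dn_xy[0]
        bb[1, 2::3] = dn_xy[1]
        bb[2, 1::3] = dn_xy[1]
        bb[2, 2::3] = dn_xy[0]
        if mitc:
            row_r = 0.5 * (1 + s) * row_rt + 0.5 * (1 - s) * row_rb
            row_s = 0.5 * (1 + r) * row_sr + 0.5 * (1 - r) * row_sl
            bs = jinv @ np.vstack([row_r, row_s])
        else:
            row_r = _covariant_shear_row(xe, r, s, 0)
            row_s = _covariant_shear_row(xe, r, s, 1)
            bs = jinv @ np.vstack([row_r, row_s])
        ke += det * (bb.T @ db @ bb + ds * (bs.T @ bs))
        fe[0::3] += det * q * n
    return ke, fe


def _tri_shear_row(xe: np.ndarray, r: float, s: float, direction: int) -> np.ndarray:
    n = np.array([1 - r - s, r, s])
    dn = np.array([-1.0, 1.0, 0.0]) if direction == 0 else np.array([-1.0, 0.0, 1.0])
    gvec = xe.T @ dn
    row = np.zeros(9)
    row[0::3] = dn
    row[1::3] = -n * gvec[0]
    row[2::3] = -n * gvec[1]
    return row


def _mitc3_element(
    xe: np.ndarray, db: np.ndarray, ds: float, q: float
) -> tuple[np.ndarray, np.ndarray]:
    """Stiffness (9x9) and load (9,) of one MITC3 plate triangle.

    The assumed covariant shear field is ``gamma_r = a + c*s``,
    ``gamma_s = b - c*r``, tied to the displacement-based strains at the
    three edge midpoints.
    """
    jac = np.array([xe.T @ np.array([-1.0, 1.0, 0.0]), xe.T @ np.array([-1.0, 0.0, 1.0])])
    det = np.linalg.det(jac)
    if det <= 0:
        raise GeometryError("inverted triangle element")
    jinv = np.linalg.inv(jac)

    # constant bending strain
    dn_xy = jinv @ np.array([[-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
    bb = np.zeros((3, 9))
    bb[0, 1::3] = dn_xy[0]
    bb[1, 2::3] = dn_xy[1]
    bb[2, 1::3] = dn_xy[1]
    bb[2, 2::3] = dn_xy[0]

    row_a = _tri_shear_row(xe, 0.5, 0.0, 0)   # gamma_r at edge 1-2 midpoint
    row_b = _tri_shear_row(xe, 0.0, 0.5, 1)   # gamma_s at edge 1-3 midpoint
    row_cr = _tri_shear_row(xe, 0.5, 0.5, 0)  # gamma_r at hypotenuse midpoint
    row_cs = _tri_shear_row(xe, 0.5, 0.5, 1)
    row_c = row_b - row_a - row_cs + row_cr

    ke = det * 0.5 * (bb.T @ db @ bb)
    fe = np.zeros(9)
    for r, s in [(0.5, 0.0), (0.5, 0.5), (0.0, 0.5)]:
        row_r = row_a + s * row_c
        row_s = row_b - r * row_c
        bs = jinv @ np.vstack([row_r, row_s])
        ke += (det / 6.0) * ds * (bs.T @ bs)
        n = np.array([1 - r - s, r, s])
        fe[0::3] += (det / 6.0) * q * n
    return ke, fe


def solve_plate(
    model: CupulaModel,
    pressure: float = 0.05,
    element: str = "mitc4",
    mitc: bool = True,
    target_size: float | None = None,
) -> PlateSolution:
    """Solve the clamped Mindlin plate under uniform pressure (Pa).

    The outline is fully clamped (w = 0, rotations = 0).  ``element``
    selects "mitc4" quadrilaterals or "mitc3" triangles (each quad split
    in two).  The linear solve is checked to a relative residual of
    1e-10.
    """
    mesh = model.mesh
    if mesh is None:
        size = target_size or _default_target_size(model)
        mesh = model.mesh = mesh_cross_section(model.section, size)
    db = model.bending_rigidity * np.array(
        [[1.0, model.nu, 0.0], [model.nu, 1.0, 0.0], [0.0, 0.0, 0.5 * (1.0 - model.nu)]]
    )
    ds = SHEAR_CORRECTION * model.gamma * model.thickness  # kappa * G * h

    n_nodes = len(mesh.nodes)
    rows, cols, vals = [], [], []
    rhs = np.zeros(3 * n_nodes)

    if element == "mitc4":
        conn_list, elem_fn = mesh.quads, lambda xe: _mitc4_element(xe, db, ds, pressure, mitc)
    elif element == "mitc3":
        tris, _ = mesh.triangles
        conn_list, elem_fn = tris, lambda xe: _mitc3_element(xe, db, ds, pressure)
    else:
        raise ValueError(f"unknown element type {element!r}")

    for conn in conn_list:
        xe = mesh.nodes[conn]
        ke, fe = elem_fn(xe)
        dof = np.concatenate([[3 * c, 3 * c + 1, 3 * c + 2] for c in conn])
        rows.append(np.repeat(dof, len(dof)))
        cols.append(np.tile(dof, len(dof)))
        vals.append(ke.ravel())
        np.add.at(rhs, dof, fe)

    kmat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n_nodes, 3 * n_nodes),
    ).tocsr()

    fixed = np.zeros(3 * n_nodes, dtype=bool)
    for b in mesh.boundary_nodes:
        fixed[3 * b : 3 * b + 3] = True
    if fixed.all() or not fixed.any():
        raise GeometryError("clamped boundary is empty or covers all nodes")
    free = ~fixed
    kff = kmat[free][:, free].tocsc()
    b = rhs[free]
    # Jacobi equilibration: w and rotation DOFs differ by orders of
    # magnitude in stiffness for thin plates; symmetric diagonal scaling
    # keeps the direct solve well conditioned
    dscale = 1.0 / np.sqrt(kff.diagonal())
    kss = sp.diags(dscale) @ kff @ sp.diags(dscale)
    bs = b * dscale
    lu = spla.factorized(kss.tocsc())
    sol = lu(bs)
    norm_a = spla.norm(kss, np.inf)

    def backward_error(x):
        # normwise relative residual ||b - A x|| / (||A|| ||x|| + ||b||)
        denom = norm_a * np.linalg.norm(x) + np.linalg.norm(bs)
        return np.linalg.norm(bs - kss @ x) / denom if denom > 0 else 0.0

    for _ in range(5):  # iterative refinement of the direct solve
        if backward_error(sol) <= 1e-10:
            break
        sol = sol + lu(bs - kss @ sol)
    else:
        raise RuntimeError(
            f"plate solve did not converge: relative residual {backward_error(sol):.2e}"
        )
    sol = sol * dscale

    u = np.zeros(3 * n_nodes)
    u[free] = sol
    out = PlateSolution(
        mesh=mesh,
        w=u[0::3],
        theta=np.stack([u[1::3], u[2::3]], axis=1),
        pressure=pressure,
        element=element,
    )
    if element == "mitc3":
        out.tris, out.tri_strip = mesh.triangles
    return out


def _default_target_size(model: CupulaModel) -> float:
    # aim for ~20 elements across the section
    return float(np.sqrt(model.section.area) / 20.0)


# ---------------------------------------------------------------------------
# Post-processing


def _integrate_w(sol: PlateSolution, elements: np.ndarray | None = None, func=None):
    """Integrate ``func(w)`` (default w itself) over elements; returns (integral, area)."""
    func = func or (lambda w: w)
    total = 0.0
    area = 0.0
    if sol.element == "mitc4":
        conn_all = sol.mesh.quads if elements is None else sol.mesh.quads[elements]
        for conn in conn_all:
            xe = sol.mesh.nodes[conn]
            we = sol.w[conn]
            for r, s in _GAUSS4:
                n, dnr, dns = _quad_shape(r, s)
                det = np.linalg.det(np.array([xe.T @ dnr, xe.T @ dns]))
                total += det * func(float(n @ we))
                area += det
    else:
        tris, _ = sol.mesh.triangles
        conn_all = tris if elements is None else tris[elements]
        for conn in conn_all:
            xe = sol.mesh.nodes[conn]
            we = sol.w[conn]
            jac = np.array(
                [xe.T @ np.array([-1.0, 1.0, 0.0]), xe.T @ np.array([-1.0, 0.0, 1.0])]
            )
            det = np.linalg.det(jac)
            for r, s in [(0.5, 0.0), (0.5, 0.5), (0.0, 0.5)]:
                n = np.array([1 - r - s, r, s])
                total += (det / 6.0) * func(float(n @ we))
                area += det / 6.0
    return total, area


def volume_displacement(sol: PlateSolution) -> float:
    """Displaced cupula volume ``dV = integral of w dA`` in mm^3."""
    total, _ = _integrate_w(sol)
    return float(total)


def cupula_stiffness(pressure: float, volume_displaced: float) -> float:
    """Stiffness ``k = dP/dV`` in g.s^-2.mm^-4 (== Pa/mm^3)."""
    if volume_displaced <= 0:
        raise ValueError("volume displacement must be positive")
    return float(pressure / volume_displaced)


def band_deflection_angle(sol: PlateSolution, cilia_length: float) -> float:
    """Mean cilia deflection angle over the band of reach ``cilia_length``.

    ``dTheta`` is the area-weighted mean of ``arctan(w / l)`` over the
    part of the cross-section within ``l`` of the outline, in radians:
    the tilt of a cilium of length ``l`` whose tip follows the local
    cupula displacement.
    """
    if sol.element == "mitc4":
        elems = sol.mesh.band_elements(cilia_length)
    else:
        tris, tri_strip = sol.mesh.triangles
        heights = np.asarray(sol.mesh.band_heights)
        if not np.any(np.isclose(heights, cilia_length)):
            raise ValueError(f"no band at cilia length {cilia_length}")
        n_strips = int(np.sum(heights <= cilia_length + 1e-12))
        elems = np.flatnonzero((tri_strip >= 0) & (tri_strip < n_strips))
    if len(elems) == 0:
        raise ValueError("empty cilia band")
    total, area = _integrate_w(sol, elems, func=lambda w: np.arctan(w / cilia_length))
    return float(total / area)


def cilia_transfer_factor(sol: PlateSolution, cilia_length: float) -> float:
    """Transfer factor ``eps = dTheta/dV`` in mdeg per nL.

    Linear in neither quantity's amplitude: both scale with the applied
    pressure, so eps is a pressure-independent property of the cupula
    (asserted to rounding in the small-angle regime).
    """
    dtheta = band_deflection_angle(sol, cilia_length)           # rad
    dv = volume_displacement(sol)                               # mm^3
    dtheta_mdeg = np.degrees(dtheta) * 1e3
    dv_nl = dv * 1e3
    return float(dtheta_mdeg / dv_nl)


# ---------------------------------------------------------------------------
# Axisymmetric closed forms (clamped circular plate, uniform pressure)


def kirchhoff_disc_center_deflection(q: float, a: float, d: float) -> float:
    """Thin-plate centre deflection ``q a^4 / (64 D)``."""
    return q * a**4 / (64.0 * d)


def kirchhoff_disc_volume(q: float, a: float, d: float) -> float:
    """Thin-plate volume displacement ``q pi a^6 / (192 D)``."""
    return q * np.pi * a**6 / (192.0 * d)


def mindlin_disc_deflection(
    r: np.ndarray | float, q: float, a: float, d: float, shear_ds: float
) -> np.ndarray | float:
    """Exact axisymmetric Mindlin deflection of a clamped disc.

    ``w(r) = q (a^2 - r^2)^2 / (64 D) + q (a^2 - r^2) / (4 kappa G h)``,
    the Kirchhoff bending profile plus the transverse shear sag;
    ``shear_ds`` is ``kappa*G*h``.
    """
    r2 = np.square(r)
    return q * (a**2 - r2) ** 2 / (64.0 * d) + q * (a**2 - r2) / (4.0 * shear_ds)


def mindlin_disc_volume(q: float, a: float, d: float, shear_ds: float) -> float:
    """Volume displacement of the clamped Mindlin disc (exact)."""
    return q * np.pi * a**6 / (192.0 * d) + q * np.pi * a**4 / (8.0 * shear_ds)


def export_solution_vtk(sol: PlateSolution, path) -> None:
    """Write the deflection field as a legacy ASCII VTK polydata file."""
    mesh = sol.mesh
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncupula plate solution\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.nodes)} float\n")
        for (x, y), w in zip(mesh.nodes, sol.w):
            fh.write(f"{x:.9g} {y:.9g} {w:.9g}\n")
        fh.write(f"POLYGONS {len(mesh.quads)} {5 * len(mesh.quads)}\n")
        for q4 in mesh.quads:
            fh.write("4 " + " ".join(str(i) for i in q4) + "\n")
        fh.write(f"POINT_DATA {len(mesh.nodes)}\n")
        fh.write("SCALARS deflection float 1\nLOOKUP_TABLE default\n")
        for w in sol.w:
            fh.write(f"{w:.9g}\n")
        fh.write("VECTORS rotation float\n")
        for tx, ty in sol.theta:
            fh.write(f"{tx:.9g} {ty:.9g} 0\n")
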