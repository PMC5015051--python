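"""Morphometry of the semicircular duct system.

Every quantity feeding the torsion-pendulum model is derived here from
per-part volumes ``V``, wetted wall areas ``S`` and streamline lengths
``L``:

* mean cross-section ``a = V/L`` and mean wall perimeter ``p = S/L``;
* the equivalent elliptic cross-section ``(A, B)`` solving
  ``pi*A*B = a`` with Ramanujan perimeter equal to ``p``;
* the laminar wall-shape drag factor ``lambda = 4*pi*(A^2+B^2)/(A*B)``
  of Poiseuille flow in an elliptic tube (``8*pi`` for a circle);
* per-circuit enclosed vector areas, ``g`` vectors, radii of curvature,
  and the inertia/damping coefficients ``m = rho * sum L/a`` and
  ``c = mu * sum lambda*L/a^2`` (piecewise-constant cross-section per
  part).

The three duct circuits are closed loops composed from the 11 parts;
the anterior circuit shares the common crus with the posterior one and
the anterior utricle with the lateral one, which is what couples the
three pendulum equations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DUCTS, PhysiologyConstants
from .mesh_io import (
    DuctSystemGeometry,
    LandmarkPolyline,
    closed_mesh_volume,
    mesh_surface_area,
)

#: Default composition of the three flow circuits from canonical parts.
DEFAULT_CIRCUITS: dict[str, tuple[str, ...]] = {
    "anterior": ("duct_ant", "amp_ant", "utricle_ant", "crus_common"),
    "posterior": ("duct_post", "amp_post", "utricle_post", "crus_common"),
    "lateral": ("duct_lat", "amp_lat", "crus_simple", "utricle_common", "utricle_ant"),
}

#: Parts traversed by two circuits: part -> (circuit pair).  The common
#: crus couples anterior/posterior, the anterior utricle couples
#: anterior/lateral; there is no posterior/lateral shared segment.
SHARED_PARTS: dict[str, tuple[str, str]] = {
    "crus_common": ("anterior", "posterior"),
    "utricle_ant": ("anterior", "lateral"),
}

CIRCLE_DRAG = 8.0 * np.pi


class ConnectivityError(ValueError):
    """Raised when part streamlines cannot be chained into a closed loop."""


@dataclass
class PartMorphometry:
    """Scalar morphometry of one duct part (units mm, mm^2, mm^3)."""

    part: str
    length: float
    volume: float
    surface: float
    area: float          # mean cross-section a = V/L
    perimeter: float     # mean wall perimeter p = S/L
    semi_major: float    # ellipse semi-axis A
    semi_minor: float    # ellipse semi-axis B
    drag_factor: float   # lambda, dimensionless (>= 8*pi)


@dataclass
class CircuitMorphometry:
    """Per-circuit quantities of one semicircular duct."""

    duct: str
    loop: np.ndarray                 # closed streamline, (n, 3), mm
    vector_area: np.ndarray          # A_vec, mm^2
    g: np.ndarray                    # 2*rho*A_vec, mg.mm^-1
    radius_of_curvature: float       # sqrt(|A_vec|/pi), mm
    m: float                         # inertia coefficient, mg.mm^-4
    c: float                         # damping coefficient, g.s^-1.mm^-4
    parts: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Elementary measures


def polyline_length(line: LandmarkPolyline | np.ndarray) -> float:
    """Total length of a polyline in mm."""
    pts = line.points if isinstance(line, LandmarkPolyline) else np.asarray(line, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0.0:
        warnings.warn("polyline has zero length (repeated points)", stacklevel=2)
    return total


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's first approximation to the ellipse perimeter."""
    return np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def ellipse_from_area_perimeter(area: float, perimeter: float) -> tuple[float, float]:
    """Semi-axes (A, B) with ``pi*A*B = area`` and Ramanujan perimeter.

    Solved by bisection on the axis ratio ``t = B/A`` in (0, 1]; for a
    perimeter below the circular minimum ``2*sqrt(pi*area)`` (possible
    only through measurement noise) the circle is returned with a
    warning.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    r_circle = np.sqrt(area / np.pi)
    p_circle = 2.0 * np.pi * r_circle
    if perimeter <= p_circle * (1.0 + 1e-12):
        if perimeter < p_circle * (1.0 - 1e-9):
            warnings.warn(
                "perimeter below the circular minimum for this area; "
                "clamping cross-section to a circle",
                stacklevel=2,
            )
        return r_circle, r_circle

    def perim_of_ratio(t: float) -> float:
        a = np.sqrt(area / (np.pi * t))
        return ramanujan_perimeter(a, t * a)

    lo, hi = 1e-12, 1.0  # perimeter decreases monotonically with t
    while hi - lo > 1e-10 * hi:
        mid = 0.5 * (lo + hi)
        if perim_of_ratio(mid) > perimeter:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    a = np.sqrt(area / (np.pi * t))
    return float(a), float(t * a)


def drag_factor(a: float, b: float) -> float:
    """Wall-shape drag factor of an elliptic lumen.

    From the exact laminar (Poiseuille) solution in an elliptic tube,
    whose viscous resistance per unit length is
    ``4*mu*(A^2+B^2) / (pi*A^3*B^3)``; normalising by ``mu/a^2`` with
    ``a = pi*A*B`` gives ``lambda = 4*pi*(A^2+B^2)/(A*B)``.  Symmetric
    in (A, B), minimised at ``8*pi`` for a circle.
    """
    return float(4.0 * np.pi * (a * a + b * b) / (a * b))


def part_morphometry(part: str, volume: float, surface: float, length: float) -> PartMorphometry:
    """Derive the mean-tube description of one part from V, S, L."""
    if volume <= 0 or surface <= 0 or length <= 0:
        raise ValueError(f"part {part!r}: V, S and L must be positive")
    area = volume / length
    perimeter = surface / length
    semi_a, semi_b = ellipse_from_area_perimeter(area, perimeter)
    return PartMorphometry(
        part=part,
        length=length,
        volume=volume,
        surface=surface,
        area=area,
        perimeter=perimeter,
        semi_major=semi_a,
        semi_minor=semi_b,
        drag_factor=drag_factor(semi_a, semi_b),
    )


def measure_part(geometry: DuctSystemGeometry, part: str) -> PartMorphometry:
    pg = geometry.parts[part]
    volume = closed_mesh_volume(pg.volume_mesh)
    surface = sum(mesh_surface_area(m) for m in pg.surface_meshes)
    length = polyline_length(pg.landmarks)
    return part_morphometry(part, volume, surface, length)


# ---------------------------------------------------------------------------
# Circuits


def circuit_streamline(
    geometry: DuctSystemGeometry,
    duct: str,
    circuits: dict[str, tuple[str, ...]] | None = None,
    join_tol: float | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Chain the part streamlines of one duct into a closed loop.

    Parts may be listed in any order; they are chained by matching
    endpoints within ``join_tol`` (default: 5 voxel sizes).  Returns the
    closed polyline (first point repeated at the end) and the part order
    actually traversed.
    """
    circuits = circuits or DEFAULT_CIRCUITS
    if duct not in circuits:
        raise KeyError(f"unknown duct {duct!r}")
    part_names = circuits[duct]
    missing = [p for p in part_names if p not in geometry.parts]
    if missing:
        raise ConnectivityError(f"circuit {duct!r} is missing parts {missing}")
    tol = join_tol if join_tol is not None else 5.0 * geometry.voxel_size_mm

    remaining = {p: geometry.parts[p].landmarks.points for p in part_names}
    first = part_names[0]
    chain = [remaining.pop(first)]
    order = [first]
    while remaining:
        tail = chain[-1][-1]
        best, best_d, best_flip = None, np.inf, False
        for name, pts in remaining.items():
            d0 = np.linalg.norm(pts[0] - tail)
            d1 = np.linalg.norm(pts[-1] - tail)
            if d0 < best_d:
                best, best_d, best_flip = name, d0, False
            if d1 < best_d:
                best, best_d, best_flip = name, d1, True
        if best_d > tol:
            raise ConnectivityError(
                f"cannot connect part {order[-1]!r} to any remaining part of "
                f"duct {duct!r} (nearest endpoint {best_d:.4g} mm > tolerance "
                f"{tol:.4g} mm, candidate {best!r})"
            )
        pts = remaining.pop(best)
        chain.append(pts[::-1] if best_flip else pts)
        order.append(best)
    gap = np.linalg.norm(chain[-1][-1] - chain[0][0])
    if gap > tol:
        raise ConnectivityError(
            f"duct {duct!r} does not close: gap of {gap:.4g} mm between "
            f"{order[-1]!r} and {order[0]!r}"
        )
    # concatenate, dropping duplicated junction points
    pieces = [chain[0]]
    for pts in chain[1:]:
        if np.linalg.norm(pts[0] - pieces[-1][-1]) < 1e-9:
            pts = pts[1:]
        pieces.append(pts)
    loop = np.vstack(pieces)
    if np.linalg.norm(loop[0] - loop[-1]) > 1e-9:
        loop = np.vstack([loop, loop[0]])
    return loop, tuple(order)


def circuit_vector_area(loop: np.ndarray) -> np.ndarray:
    """Vector area ``A_vec = 1/2 * sum r_i x r_{i+1}`` of a closed loop.

    Independent of the choice of origin; its magnitude is the maximal
    area enclosed by the circuit and its direction the normal of the
    plane of maximal response.
    """
    loop = np.asarray(loop, dtype=float)
    if np.linalg.norm(loop[0] - loop[-1]) > 1e-6:
        raise ValueError("loop must be closed (first point == last point)")
    r0 = loop[:-1]
    r1 = loop[1:]
    return 0.5 * np.cross(r0, r1).sum(axis=0)


def g_vector(loop: np.ndarray, rho: float = 1.0) -> np.ndarray:
    """Forcing vector ``g = rho * sum r x dr = 2*rho*A_vec``.

    With rho in mg.mm^-3 the result is in mg.mm^-1.  Its direction is
    the rotation axis that optimally displaces the endolymph of this
    circuit; its magnitude, the ease of that displacement.  It depends
    only on the streamline, so dilating or contracting the duct walls
    leaves it unchanged.
    """
    return 2.0 * rho * circuit_vector_area(loop)


def radius_of_curvature(vector_area: np.ndarray) -> float:
    """Equivalent circular radius ``R = sqrt(|A_vec|/pi)`` in mm."""
    mag = float(np.linalg.norm(vector_area))
    if mag <= 0:
        raise ValueError("degenerate loop: zero enclosed area")
    return float(np.sqrt(mag / np.pi))


def inertia_coefficient(parts: list[PartMorphometry], rho: float) -> float:
    """``m = rho * sum L/a`` over a flow path, in mg.mm^-4 for rho in mg.mm^-3."""
    if not parts:
        raise ValueError("empty flow path")
    if any(p.area <= 0 for p in parts):
        raise ValueError("zero cross-section in flow path")
    return float(rho * sum(p.length / p.area for p in parts))


def damping_coefficient(parts: list[PartMorphometry], mu: float) -> float:
    """``c = mu * sum lambda*L/a^2`` over a flow path, in g.s^-1.mm^-4."""
    if not parts:
        raise ValueError("empty flow path")
    if any(p.area <= 0 for p in parts):
        raise ValueError("zero cross-section in flow path")
    return float(mu * sum(p.drag_factor * p.length / p.area**2 for p in parts))


def measure_circuit(
    geometry: DuctSystemGeometry,
    duct: str,
    constants: PhysiologyConstants,
    part_morph: dict[str, PartMorphometry] | None = None,
    circuits: dict[str, tuple[str, ...]] | None = None,
) -> CircuitMorphometry:
    circuits = circuits or DEFAULT_CIRCUITS
    if part_morph is None:
        part_morph = {p: measure_part(geometry, p) for p in circuits[duct]}
    loop, order = circuit_streamline(geometry, duct, circuits)
    a_vec = circuit_vector_area(loop)
    morphs = [part_morph[p] for p in circuits[duct]]
    return CircuitMorphometry(
        duct=duct,
        loop=loop,
        vector_area=a_vec,
        g=g_vector(loop, constants.rho),
        radius_of_curvature=radius_of_curvature(a_vec),
        m=inertia_coefficient(morphs, constants.rho),
        c=damping_coefficient(morphs, constants.mu),
        parts=order,
    )


def orient_circuits(
    circuits: dict[str, CircuitMorphometry],
    geometry: DuctSystemGeometry,
    shared: dict[str, tuple[str, str]] | None = None,
) -> dict[str, CircuitMorphometry]:
    """Flip loop orientations so flows agree in the shared segments.

    The anterior circuit fixes the sign convention; the posterior and
    lateral loops are reversed where needed so that both circuits
    traverse their shared part (common crus, anterior utricle) in the
    same direction.  Reversing a loop flips its vector area and g.
    """
    shared = shared or SHARED_PARTS
    out = dict(circuits)
    for part, (ref, other) in shared.items():
        seg = geometry.parts[part].landmarks.points
        sense = {}
        for duct in (ref, other):
            loop = out[duct].loop
            n = len(loop) - 1  # last point duplicates the first
            i0 = int(np.argmin(np.linalg.norm(loop[:-1] - seg[0], axis=1)))
            i1 = int(np.argmin(np.linalg.norm(loop[:-1] - seg[-1], axis=1)))
            forward = (i1 - i0) % n
            sense[duct] = 1.0 if forward <= n - forward else -1.0
        if sense[ref] != sense[other]:
            cm = out[other]
            out[other] = CircuitMorphometry(
                duct=cm.duct,
                loop=cm.loop[::-1].copy(),
                vector_area=-cm.vector_area,
                g=-cm.g,
                radius_of_curvature=cm.radius_of_curvature,
                m=cm.m,
                c=cm.c,
                parts=tuple(reversed(cm.parts)),
            )
    return out


def shared_coefficients(
    part_morph: dict[str, PartMorphometry],
    constants: PhysiologyConstants,
    shared: dict[str, tuple[str, str]] | None = None,
) -> dict[str, dict[str, float]]:
    """Coupling coefficients (m, c) of each shared segment.

    Returns ``{"cc": {"m": ..., "c": ...}, "uc": {...}}`` with m in
    mg.mm^-4 and c in g.s^-1.mm^-4.
    """
    shared = shared or SHARED_PARTS
    label = {"crus_common": "cc", "utricle_ant": "uc"}
    out = {}
    for part in shared:
        pm = [part_morph[part]]
        out[label.get(part, part)] = {
            "m": inertia_coefficient(pm, constants.rho),
            "c": damping_coefficient(pm, constants.mu),
        }
    return out


# ---------------------------------------------------------------------------
# Segmentation precision


def area_variation_to_offset(area_change: float, semi_major: float, semi_minor: float) -> float:
    """Surface offset producing a given relative cross-section change.

    Treating the cross-section as an ellipse with semi-axes (A, B), the
    offset ``delta`` applied all around the perimeter solves
    ``pi*(A+delta)*(B+delta) = pi*A*B*(1+area_change)``; the root of
    smaller magnitude of the quadratic
    ``delta^2 + (A+B)*delta - A*B*area_change = 0`` is returned.  This
    converts observed segmentation variation of duct lumina into the
    normal surface offset used by :func:`semiduct.mesh_io.offset_mesh`.
    """
    if 1.0 + area_change <= 0:
        raise ValueError("area change beyond total collapse")
    a, b = semi_major, semi_minor
    disc = (a + b) ** 2 + 4.0 * a * b * area_change
    if disc < 0:
        raise ValueError("no real offset: contraction beyond collapse")
    sq = np.sqrt(disc)
    roots = np.array([(-(a + b) + sq) / 2.0, (-(a + b) - sq) / 2.0])
    return float(roots[np.argmin(np.abs(roots))])


def system_morphometry(
    geometry: DuctSystemGeometry,
    constants: PhysiologyConstants | None = None,
    circuits: dict[str, tuple[str, ...]] | None = None,
) -> tuple[dict[str, PartMorphometry], dict[str, CircuitMorphometry], dict[str, dict[str, float]]]:
    """Full morphometric pass: parts, oriented circuits, shared couplings."""
    constants = constants or PhysiologyConstants()
    circuits = circuits or DEFAULT_CIRCUITS
    part_morph = {p: measure_part(geometry, p) for p in geometry.parts}
    circ = {
        d: measure_circuit(geometry, d, constants, part_morph, circuits) for d in DUCTS
    }
    circ = orient_circuits(circ, geometry)
    coupling = shared_coefficients(part_morph, constants)
    return part_morph, circ, coupling
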