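"""Synthetic torus-labyrinth and cupula fixtures with analytic truth.

The generator emulates the file layout of a segmented specimen (11
part volume meshes, 12 surface meshes, 11 landmark streamlines, a
manifest) for a fully characterised idealised labyrinth, so that every
pipeline stage can be validated against closed forms without specimen
data.

Construction.  The three duct circuits are circles of radius R_k lying
in three mutually orthogonal planes (anterior x=0, posterior y=0,
lateral z=0).  The common crus is realised as a straight segment on the
z axis (the intersection line of the anterior and posterior planes)
whose endpoints lie on both circles; each circuit replaces the small
arc it subtends by that shared chord.  The anterior utricle couples the
anterior and lateral circuits the same way on the y axis.  Both
circuits list the identical chord polyline, exactly as a segmented
common crus is a single part traversed by two flow circuits.  All loops
stay planar, so every morphometric quantity has a closed form: arc
lengths R*dpsi, chord lengths 2*R*sin(phi/2), enclosed area
pi*R^2 - sum (R^2/2)(phi - sin phi) per replaced arc, tube volumes and
walls by Pappus (pi r^2 L, 2 pi r L).

Part tubes have circular cross-sections with per-part radii (slender
duct r; ampullae bulged; utricular parts wide), so the piecewise-
constant cross-section model of the morphometry stage is exact and the
drag factor is exactly 8*pi everywhere.

Each duct carries a disc cupula whose clamped-plate response is known
exactly under axisymmetric Mindlin theory, giving reference stiffness
and transfer factors, hence reference time constants and sensitivities
for the end-to-end pipeline test.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml
from scipy.integrate import quad

from .constants import CILIA_LENGTHS_MM, PhysiologyConstants
from .cupula_fea import (
    CupulaCrossSection,
    mindlin_disc_deflection,
    mindlin_disc_volume,
    SHEAR_CORRECTION,
)

DUCT_ORDER = ("anterior", "posterior", "lateral")


class SpecError(ValueError):
    """Raised for geometrically impossible fixture specifications."""


@dataclass
class CupulaDiscSpec:
    radius: float = 0.50       # mm
    thickness: float = 0.25    # mm
    n_outline: int = 720


@dataclass
class TorusLabyrinthSpec:
    """Parameters of the synthetic labyrinth.

    Circuit radii and tube radius are primate-like (circuit radii of a
    few mm, slender-duct lumen radius 0.15 mm); the shared-segment arc
    fractions are the fraction of the anterior circle replaced by each
    chord.  ``seed`` drives the optional vertex jitter and is recorded
    in the manifest.
    """

    radius_anterior: float = 3.0
    radius_posterior: float = 2.8
    radius_lateral: float = 2.6
    tube_radius: float = 0.15
    cc_fraction: float = 0.06
    uc_fraction: float = 0.06
    ampulla_bulge: float = 2.5
    crus_common_factor: float = 1.4
    crus_simple_factor: float = 1.2
    utricle_factor: float = 3.0
    n_circumference: int = 64
    landmarks_per_mm: float = 8.0
    mesh_points_per_mm: float = 6.0
    jitter: float = 0.0
    seed: int = 0
    cupulae: dict[str, CupulaDiscSpec] = field(
        default_factory=lambda: {
            "anterior": CupulaDiscSpec(0.50, 0.25),
            "posterior": CupulaDiscSpec(0.48, 0.24),
            "lateral": CupulaDiscSpec(0.52, 0.26),
        }
    )

    def __post_init__(self) -> None:
        for r in (self.radius_anterior, self.radius_posterior, self.radius_lateral):
            if r <= 5.0 * self.tube_radius:
                raise SpecError("circuit radius must exceed 5x the tube radius")
        for f in (self.cc_fraction, self.uc_fraction):
            if not 0.0 < f < 0.2:
                raise SpecError("shared-segment arc fractions must lie in (0, 0.2)")
        if self.ampulla_bulge < 1.0:
            raise SpecError("ampulla bulge factor must be >= 1")


@dataclass
class GroundTruth:
    """Closed-form reference values attached to a synthetic fixture."""

    parts: dict[str, dict[str, float]]
    circuits: dict[str, dict]
    couplings: dict[str, dict[str, float]]
    cupulae: dict[str, dict[str, float]]
    matrices: dict[str, list]
    tau1: dict[str, float]
    tau2: dict[str, float]
    sensitivity: dict[str, float]
    constants: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Centreline construction


@dataclass
class _Segment:
    """A planar centreline piece: circular arc or straight chord."""

    kind: str                 # "arc" | "chord"
    center: np.ndarray        # arc center (3,)
    e1: np.ndarray            # in-plane basis
    e2: np.ndarray
    radius: float
    ang0: float
    ang1: float               # traversal from ang0 to ang1 (may decrease)
    p0: np.ndarray = None
    p1: np.ndarray = None     # chord endpoints

    @property
    def length(self) -> float:
        if self.kind == "arc":
            return abs(self.ang1 - self.ang0) * self.radius
        return float(np.linalg.norm(self.p1 - self.p0))

    def sample(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """n+1 points plus unit tangents along the traversal."""
        t = np.linspace(0.0, 1.0, n + 1)
        if self.kind == "arc":
            ang = self.ang0 + (self.ang1 - self.ang0) * t
            pts = (
                self.center
                + self.radius * np.cos(ang)[:, None] * self.e1
                + self.radius * np.sin(ang)[:, None] * self.e2
            )
            sgn = np.sign(self.ang1 - self.ang0)
            tan = sgn * (-np.sin(ang)[:, None] * self.e1 + np.cos(ang)[:, None] * self.e2)
            return pts, tan
        pts = self.p0 + (self.p1 - self.p0) * t[:, None]
        d = (self.p1 - self.p0) / np.linalg.norm(self.p1 - self.p0)
        return pts, np.tile(d, (len(t), 1))


def _build_centrelines(spec: TorusLabyrinthSpec):
    """Per-part centreline segments plus exact circuit-level records."""
    ra, rp, rl = spec.radius_anterior, spec.radius_posterior, spec.radius_lateral
    phi_a_cc = 2.0 * np.pi * spec.cc_fraction
    phi_a_uc = 2.0 * np.pi * spec.uc_fraction
    h_cc = ra * np.sin(phi_a_cc / 2.0)
    h_uc = ra * np.sin(phi_a_uc / 2.0)
    if h_cc >= rp or h_uc >= rl:
        raise SpecError("shared chord longer than a partner circuit diameter")
    phi_p = 2.0 * np.arcsin(h_cc / rp)
    phi_l = 2.0 * np.arcsin(h_uc / rl)

    cy = -ra * np.cos(phi_a_cc / 2.0)   # anterior centre (0, cy, cz)
    cz = -ra * np.cos(phi_a_uc / 2.0)
    cxp = -rp * np.cos(phi_p / 2.0)     # posterior centre (cxp, 0, cz)
    cxl = -rl * np.cos(phi_l / 2.0)     # lateral centre  (cxl, cy, 0)

    ex, ey, ez = np.eye(3)
    c_a = np.array([0.0, cy, cz])
    c_p = np.array([cxp, 0.0, cz])
    c_l = np.array([cxl, cy, 0.0])

    p1 = np.array([0.0, 0.0, cz + h_cc])   # cc chord endpoints (z axis)
    p2 = np.array([0.0, 0.0, cz - h_cc])
    q1 = np.array([0.0, cy + h_uc, 0.0])   # uc chord endpoints (y axis)
    q2 = np.array([0.0, cy - h_uc, 0.0])

    def arc(center, e1, e2, r, a0, a1):
        return _Segment("arc", center, e1, e2, r, a0, a1)

    chord_cc = _Segment("chord", c_a, ey, ez, 0.0, 0.0, 0.0, p0=p2, p1=p1)
    chord_uc = _Segment("chord", c_a, ey, ez, 0.0, 0.0, 0.0, p0=q1, p1=q2)

    # anterior circle in (ey, ez); counter-clockwise traversal
    a_lo, a_hi = phi_a_cc / 2.0, np.pi / 2.0 - phi_a_uc / 2.0
    parts: dict[str, list[_Segment]] = {
        "amp_ant": [arc(c_a, ey, ez, ra, a_lo, a_hi)],
        "duct_ant": [arc(c_a, ey, ez, ra, np.pi / 2.0 + phi_a_uc / 2.0, 2.0 * np.pi - phi_a_cc / 2.0)],
        "utricle_ant": [chord_uc],
        "crus_common": [chord_cc],
    }
    # posterior circle in (ex, ez): from P1 (chi=+phi/2) CCW to P2
    chi0, chi1 = phi_p / 2.0, 2.0 * np.pi - phi_p / 2.0
    fr = {"duct_post": 0.55, "amp_post": 0.15, "utricle_post": 0.30}
    edges = np.cumsum([0.0] + list(fr.values()))
    for (name, _), t0, t1 in zip(fr.items(), edges[:-1], edges[1:]):
        parts[name] = [
            arc(c_p, ex, ez, rp, chi0 + t0 * (chi1 - chi0), chi0 + t1 * (chi1 - chi0))
        ]
    # lateral circle in (ex, ey): from Q2 (omega=-phi/2) clockwise to Q1,
    # i.e. omega decreasing from 2*pi - phi/2 down to phi/2
    w0, w1 = 2.0 * np.pi - phi_l / 2.0, phi_l / 2.0
    fl = {"amp_lat": 0.15, "duct_lat": 0.50, "crus_simple": 0.15, "utricle_common": 0.20}
    edges = np.cumsum([0.0] + list(fl.values()))
    for (name, _), t0, t1 in zip(fl.items(), edges[:-1], edges[1:]):
        parts[name] = [
            arc(c_l, ex, ey, rl, w0 + t0 * (w1 - w0), w0 + t1 * (w1 - w0))
        ]

    def segment_cut(r, phi):
        return 0.5 * r * r * (phi - np.sin(phi))

    circuits = {
        "anterior": {
            "order": ["crus_common", "duct_ant", "amp_ant", "utricle_ant"],
            "area": np.pi * ra**2 - segment_cut(ra, phi_a_cc) - segment_cut(ra, phi_a_uc),
            "normal": ex,
            "length": ra * (2.0 * np.pi - phi_a_cc - phi_a_uc) + 2.0 * h_cc + 2.0 * h_uc,
        },
        "posterior": {
            "order": ["crus_common", "duct_post", "amp_post", "utricle_post"],
            "area": np.pi * rp**2 - segment_cut(rp, phi_p),
            "normal": -ey,
            "length": rp * (2.0 * np.pi - phi_p) + 2.0 * h_cc,
        },
        "lateral": {
            "order": ["utricle_ant", "amp_lat", "duct_lat", "crus_simple", "utricle_common"],
            "area": np.pi * rl**2 - segment_cut(rl, phi_l),
            "normal": -ez,
            "length": rl * (2.0 * np.pi - phi_l) + 2.0 * h_uc,
        },
    }
    return parts, circuits


def part_tube_radius(spec: TorusLabyrinthSpec, part: str) -> float:
    r = spec.tube_radius
    if part.startswith("amp_"):
        return r * spec.ampulla_bulge
    if part == "crus_common":
        return r * spec.crus_common_factor
    if part == "crus_simple":
        return r * spec.crus_simple_factor
    if part.startswith("utricle"):
        return r * spec.utricle_factor
    return r


# ---------------------------------------------------------------------------
# Tube meshing


def _tube_mesh(
    pts: np.ndarray,
    tans: np.ndarray,
    radius: float,
    n_circ: int,
    plane_normal: np.ndarray,
    caps: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Swept circular tube around a planar centreline.

    Ring frames use the (constant) centreline plane normal and the
    local binormal, so the tube is an exact surface of revolution
    sample with no twist.
    """
    n = np.asarray(plane_normal, float)
    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ
    rings = []
    for p, t in zip(pts, tans):
        b = np.cross(t, n)
        b /= np.linalg.norm(b)
        ring = p + radius * (np.cos(theta)[:, None] * n + np.sin(theta)[:, None] * b)
        rings.append(ring)
    verts = np.vstack(rings)
    faces = []
    n_ax = len(pts)
    for i in range(n_ax - 1):
        for j in range(n_circ):
            jn = (j + 1) % n_circ
            a = i * n_circ + j
            bb = i * n_circ + jn
            c = (i + 1) * n_circ + jn
            d = (i + 1) * n_circ + j
            faces.append([a, bb, c])
            faces.append([a, c, d])
    if caps:
        c0 = len(verts)
        verts = np.vstack([verts, pts[0][None, :], pts[-1][None, :]])
        c1 = c0 + 1
        for j in range(n_circ):
            jn = (j + 1) % n_circ
            faces.append([c0, jn, j])                                  # start cap
            base = (n_ax - 1) * n_circ
            faces.append([c1, base + j, base + jn])                    # end cap
    return verts, np.asarray(faces, dtype=np.int64)


def _write_stl(path: Path, verts: np.ndarray, faces: np.ndarray) -> None:
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    path.write_bytes(trimesh.exchange.stl.export_stl_ascii(mesh).encode("ascii"))


# ---------------------------------------------------------------------------
# Cupula fixtures


def make_cupula_disc(
    radius: float,
    thickness: float,
    gamma: float = 1.44,
    nu: float = 0.48,
    band_heights: tuple[float, ...] = CILIA_LENGTHS_MM,
    pressure: float = 0.05,
    n_outline: int = 720,
    duct: str = "",
) -> tuple[CupulaCrossSection, dict[str, float]]:
    """Disc cupula cross-section plus its exact analytic record.

    The record holds the Kirchhoff (thin) and Mindlin (exact for any
    thickness) centre deflections and volume displacements under the
    given uniform pressure, the resulting stiffness, and the transfer
    factor per band computed by quadrature of the exact Mindlin radial
    profile -- all independent of the finite-element path.
    """
    if max(band_heights) >= radius:
        raise SpecError("cilia band taller than the cupula radius")
    theta = np.linspace(0.0, 2.0 * np.pi, n_outline, endpoint=False)
    outline = radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    section = CupulaCrossSection(outline, band_heights=band_heights, duct=duct)

    e = 2.0 * gamma * (1.0 + nu)
    d = e * thickness**3 / (12.0 * (1.0 - nu**2))
    ds = SHEAR_CORRECTION * gamma * thickness
    dv = mindlin_disc_volume(pressure, radius, d, ds)
    record: dict[str, float] = {
        "radius": radius,
        "thickness": thickness,
        "gamma": gamma,
        "nu": nu,
        "pressure": pressure,
        "bending_rigidity": d,
        "center_deflection_kirchhoff": pressure * radius**4 / (64.0 * d),
        "volume_displacement_kirchhoff": pressure * np.pi * radius**6 / (192.0 * d),
        "center_deflection": float(mindlin_disc_deflection(0.0, pressure, radius, d, ds)),
        "volume_displacement": dv,
        "stiffness": pressure / dv,
    }
    for h in band_heights:
        num = quad(
            lambda r: np.arctan(mindlin_disc_deflection(r, pressure, radius, d, ds) / h)
            * 2.0 * np.pi * r,
            radius - h,
            radius,
        )[0]
        den = np.pi * (radius**2 - (radius - h) ** 2)
        dtheta = num / den
        record[f"band_area_{round(h * 1e3)}um"] = den
        record[f"dtheta_{round(h * 1e3)}um"] = dtheta
        record[f"eps_{round(h * 1e3)}um"] = float(np.degrees(dtheta) * 1e3 / (dv * 1e3))
    return section, record


# ---------------------------------------------------------------------------
# Main generator


def make_torus_labyrinth(
    spec: TorusLabyrinthSpec,
    outdir: str | Path,
    constants: PhysiologyConstants | None = None,
) -> tuple[Path, GroundTruth]:
    """Write a complete synthetic labyrinth fixture; return the truth.

    Emits 11 closed volume STLs, 12 open surface STLs (the lateral
    ampulla wall is split in two), 11 landmark files, three cupula
    outline files, ``manifest.yaml`` and ``ground_truth.json``.
    Regeneration with the same spec is byte-identical.
    """
    constants = constants or PhysiologyConstants()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    part_segments, circuit_info = _build_centrelines(spec)
    _check_overlaps(spec, part_segments)

    manifest_parts: dict[str, dict] = {}
    truth_parts: dict[str, dict[str, float]] = {}
    for part, segments in part_segments.items():
        r_tube = part_tube_radius(spec, part)
        length = sum(s.length for s in segments)
        # landmarks
        lm_pts = _sample_polyline(segments, spec.landmarks_per_mm)
        np.savetxt(outdir / f"{part}_landmarks.txt", lm_pts, fmt="%.9f")
        # meshes
        mesh_pts, mesh_tans = _sample_with_tangents(segments, spec.mesh_points_per_mm)
        normal = _plane_normal(segments)
        vv, vf = _tube_mesh(mesh_pts, mesh_tans, r_tube, spec.n_circumference, normal, caps=True)
        sv, sf = _tube_mesh(mesh_pts, mesh_tans, r_tube, spec.n_circumference, normal, caps=False)
        if spec.jitter > 0:
            vv = vv + rng.normal(0.0, spec.jitter, vv.shape)
            sv = sv + rng.normal(0.0, spec.jitter, sv.shape)
        _write_stl(outdir / f"{part}_volume.stl", vv, vf)
        if part == "amp_lat":
            half = (len(sf) // 2) & ~1
            for tag, fsel in (("a", sf[:half]), ("b", sf[half:])):
                used = np.unique(fsel)
                remap = -np.ones(len(sv), dtype=np.int64)
                remap[used] = np.arange(len(used))
                _write_stl(outdir / f"{part}_surface_{tag}.stl", sv[used], remap[fsel])
            surface_entry: str | list[str] = [
                f"{part}_surface_a.stl",
                f"{part}_surface_b.stl",
            ]
        else:
            _write_stl(outdir / f"{part}_surface.stl", sv, sf)
            surface_entry = f"{part}_surface.stl"
        manifest_parts[part] = {
            "surface": surface_entry,
            "volume": f"{part}_volume.stl",
            "landmarks": f"{part}_landmarks.txt",
        }
        area = np.pi * r_tube**2
        truth_parts[part] = {
            "length": length,
            "volume": area * length,
            "surface": 2.0 * np.pi * r_tube * length,
            "area": area,
            "perimeter": 2.0 * np.pi * r_tube,
            "drag_factor": 8.0 * np.pi,
            "tube_radius": r_tube,
        }

    # cupulae
    manifest_cupulae: dict[str, dict] = {}
    truth_cupulae: dict[str, dict[str, float]] = {}
    for duct in DUCT_ORDER:
        cs = spec.cupulae[duct]
        section, record = make_cupula_disc(
            cs.radius, cs.thickness, constants.gamma, constants.nu,
            n_outline=cs.n_outline, duct=duct,
        )
        fname = f"cupula_{duct}.txt"
        np.savetxt(outdir / fname, section.outline, fmt="%.9f")
        manifest_cupulae[duct] = {"outline": fname, "thickness": cs.thickness}
        truth_cupulae[duct] = record

    manifest = {
        "specimen": f"synthetic-torus-seed{spec.seed}",
        "side": "left",
        "voxel_size_mm": 0.01,
        "parts": manifest_parts,
        "cupulae": manifest_cupulae,
    }
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    truth = _ground_truth(spec, constants, truth_parts, circuit_info, truth_cupulae)
    truth.to_json(outdir / "ground_truth.json")
    return manifest_path, truth


def _plane_normal(segments: list[_Segment]) -> np.ndarray:
    s = segments[0]
    if s.kind == "arc":
        return np.cross(s.e1, s.e2)
    d = s.p1 - s.p0
    d = d / np.linalg.norm(d)
    # any unit vector orthogonal to the chord
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n = np.cross(d, ref)
    return n / np.linalg.norm(n)


def _sample_polyline(segments: list[_Segment], per_mm: float) -> np.ndarray:
    pts = []
    for i, s in enumerate(segments):
        n = max(2, int(np.ceil(s.length * per_mm)))
        p, _ = s.sample(n)
        pts.append(p if i == 0 else p[1:])
    return np.vstack(pts)


def _sample_with_tangents(
    segments: list[_Segment], per_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    pts, tans = [], []
    for i, s in enumerate(segments):
        n = max(2, int(np.ceil(s.length * per_mm)))
        p, t = s.sample(n)
        if i > 0:
            p, t = p[1:], t[1:]
        pts.append(p)
        tans.append(t)
    return np.vstack(pts), np.vstack(tans)


def _check_overlaps(spec: TorusLabyrinthSpec, part_segments) -> None:
    """Fail when non-shared centrelines pass closer than two tube widths."""
    samples = {}
    for part, segs in part_segments.items():
        samples[part] = _sample_polyline(segs, 4.0)
    radii = {d: part_tube_radius(spec, d) for d in samples}
    names = list(samples)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pa, pb = samples[a], samples[b]
            ends_a = pa[[0, -1]]
            ends_b = pb[[0, -1]]
            if np.min(np.linalg.norm(ends_a[:, None] - ends_b[None, :], axis=2)) < 1e-6:
                continue  # adjacent parts meet at a junction by construction
            dmin = np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2))
            reach = 0.5 * (radii[a] + radii[b])
            if dmin < reach:
                raise SpecError(
                    f"parts {a!r} and {b!r} overlap beyond the shared segments "
                    f"(centreline distance {dmin:.3f} mm < {reach:.3f} mm)"
                )


def _ground_truth(
    spec: TorusLabyrinthSpec,
    constants: PhysiologyConstants,
    truth_parts: dict[str, dict[str, float]],
    circuit_info: dict[str, dict],
    truth_cupulae: dict[str, dict[str, float]],
) -> GroundTruth:
    circuits: dict[str, dict] = {}
    coeffs: dict[str, dict[str, float]] = {}
    for duct, info in circuit_info.items():
        m = constants.rho * sum(
            truth_parts[p]["length"] / truth_parts[p]["area"] for p in info["order"]
        )
        c = constants.mu * sum(
            8.0 * np.pi * truth_parts[p]["length"] / truth_parts[p]["area"] ** 2
            for p in info["order"]
        )
        area = float(info["area"])
        g = 2.0 * constants.rho * area
        circuits[duct] = {
            "length": float(info["length"]),
            "area": area,
            "normal": [float(v) for v in info["normal"]],
            "g": g,
            "radius_of_curvature": float(np.sqrt(area / np.pi)),
            "m": m,
            "c": c,
        }
        lkey = f"eps_{round(constants.cilia_length_mm * 1e3)}um"
        coeffs[duct] = {
            "m": m,
            "c": c,
            "k": truth_cupulae[duct]["stiffness"],
            "g": g,
            "eps": truth_cupulae[duct][lkey],
        }
    couplings = {}
    for tag, part in (("cc", "crus_common"), ("uc", "utricle_ant")):
        couplings[tag] = {
            "m": constants.rho * truth_parts[part]["length"] / truth_parts[part]["area"],
            "c": constants.mu * 8.0 * np.pi * truth_parts[part]["length"]
            / truth_parts[part]["area"] ** 2,
        }

    # reference torsion-pendulum matrices and responses; the coefficient
    # values above are in reporting units (mg-based m and g, eps per nL)
    from .biomech import TorsionPendulumModel, sensitivities, time_constants

    normals = np.array([circuits[d]["normal"] for d in DUCT_ORDER])
    model = TorsionPendulumModel.from_coefficients(
        m=np.array([coeffs[d]["m"] for d in DUCT_ORDER]),
        c=np.array([coeffs[d]["c"] for d in DUCT_ORDER]),
        k=np.array([coeffs[d]["k"] for d in DUCT_ORDER]),
        g=np.array([coeffs[d]["g"] for d in DUCT_ORDER]),
        eps=np.array([coeffs[d]["eps"] for d in DUCT_ORDER]),
        m_cc=couplings["cc"]["m"],
        m_uc=couplings["uc"]["m"],
        c_cc=couplings["cc"]["c"],
        c_uc=couplings["uc"]["c"],
        g_directions=normals,
        table_units=True,
    )
    tau1, tau2 = time_constants(model)
    sens, _ = sensitivities(model)
    return GroundTruth(
        parts=truth_parts,
        circuits=circuits,
        couplings=couplings,
        cupulae=truth_cupulae,
        matrices={
            "M": model.M.tolist(),
            "C": model.C.tolist(),
            "K": model.K.tolist(),
            "G": model.G.tolist(),
            "eps": model.eps.tolist(),
        },
        tau1={d: float(tau1[d]) for d in DUCT_ORDER},
        tau2={d: float(tau2[d]) for d in DUCT_ORDER},
        sensitivity={d: float(sens[d]) for d in DUCT_ORDER},
        constants={
            "rho": constants.rho,
            "mu": constants.mu,
            "gamma": constants.gamma,
            "nu": constants.nu,
            "cilia_length_mm": constants.cilia_length_mm,
        },
    )
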