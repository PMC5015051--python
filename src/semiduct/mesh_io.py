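"""Reading, validation and geometric correction of duct-system meshes.

The segmented endolymphatic fill of one labyrinth is divided into 11
anatomical parts.  Each part is described by a closed *volume* mesh
(used for endolymph volume), one or more open *surface* meshes (the
inner duct wall, used for wetted area), and a landmark polyline tracing
the central streamline.  A manifest file maps arbitrary file names onto
the canonical part identifiers below.

Canonical part identifiers
--------------------------
``duct_ant, duct_post, duct_lat`` - the slender ducts;
``amp_ant, amp_post, amp_lat``    - the ampullae;
``crus_common``                   - shared by anterior and posterior circuits;
``crus_simple``                   - the simple crus of the lateral duct;
``utricle_ant``                   - anterior utricle, shared by anterior and
                                    lateral circuits;
``utricle_post, utricle_common``  - the remaining utricular portions.

By convention the lateral ampulla is exported as two surface files
(``amp_lat`` wall plus ``amp_lat_crista``), because the crista region
interrupts its wall; this yields the 12 surface / 11 volume file layout.
All coordinates are in mm (STL itself is unitless; the manifest declares
the unit and the loader trusts it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import trimesh
import yaml

CANONICAL_PARTS = (
    "duct_ant",
    "duct_post",
    "duct_lat",
    "amp_ant",
    "amp_post",
    "amp_lat",
    "crus_common",
    "crus_simple",
    "utricle_ant",
    "utricle_post",
    "utricle_common",
)

#: Vertex-merge tolerance in mm.
MERGE_TOL = 1e-9


class MeshFormatError(ValueError):
    """Raised for unreadable or degenerate mesh files."""


class MeshPreconditionError(ValueError):
    """Raised when an operation's geometric precondition is violated."""


class ManifestError(ValueError):
    """Raised for structurally invalid manifests."""


@dataclass
class PartMesh:
    """A triangle surface mesh of one anatomical part.

    ``vertices`` is an (n, 3) float array in mm, ``faces`` an (m, 3)
    integer array of vertex indices.  ``closed`` is true when every edge
    is shared by exactly two faces (a watertight volume mesh).
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    closed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshFormatError(
                f"face indices out of range for part {self.name!r}"
            )

    def copy(self) -> "PartMesh":
        return PartMesh(self.vertices.copy(), self.faces.copy(), self.name, self.closed)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]


@dataclass
class LandmarkPolyline:
    """Ordered 3D landmarks tracing a central streamline, in mm."""

    part: str
    points: np.ndarray
    closed_circuit: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError(f"polyline {self.part!r} needs at least 2 points")

    def copy(self) -> "LandmarkPolyline":
        return LandmarkPolyline(self.part, self.points.copy(), self.closed_circuit)


@dataclass
class PartGeometry:
    """Volume mesh, surface mesh(es) and streamline of one part."""

    volume_mesh: PartMesh
    surface_meshes: list[PartMesh]
    landmarks: LandmarkPolyline


@dataclass
class Manifest:
    """Maps canonical part names onto the per-part input files."""

    specimen: str
    side: str
    voxel_size_mm: float
    parts: dict[str, dict]
    cupulae: dict[str, dict] = field(default_factory=dict)
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ManifestError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.voxel_size_mm <= 0:
            raise ManifestError("voxel size must be positive")
        missing = set(CANONICAL_PARTS) - set(self.parts)
        extra = set(self.parts) - set(CANONICAL_PARTS)
        if missing or extra:
            raise ManifestError(
                f"manifest must list exactly the 11 canonical parts; "
                f"missing={sorted(missing)}, unknown={sorted(extra)}"
            )
        n_surf = sum(len(self._surfaces(p)) for p in self.parts)
        if n_surf != 12:
            raise ManifestError(f"expected 12 surface entries, found {n_surf}")

    def _surfaces(self, part: str) -> list[str]:
        s = self.parts[part].get("surface", [])
        return [s] if isinstance(s, str) else list(s)

    def surface_paths(self, part: str) -> list[Path]:
        return [self.root / s for s in self._surfaces(part)]

    def volume_path(self, part: str) -> Path:
        return self.root / self.parts[part]["volume"]

    def landmark_path(self, part: str) -> Path:
        return self.root / self.parts[part]["landmarks"]


@dataclass
class DuctSystemGeometry:
    """The full per-part geometry of one labyrinth."""

    parts: dict[str, PartGeometry]
    specimen: str = ""
    side: str = "left"
    voxel_size_mm: float = 0.01

    def all_points(self) -> np.ndarray:
        chunks = []
        for pg in self.parts.values():
            chunks.append(pg.volume_mesh.vertices)
            chunks.extend(m.vertices for m in pg.surface_meshes)
            chunks.append(pg.landmarks.points)
        return np.vstack(chunks)


# ---------------------------------------------------------------------------
# Loading


def read_triangle_mesh(path: str | Path, name: str | None = None) -> PartMesh:
    """Load an ASCII or binary STL file into a :class:`PartMesh`.

    Duplicate vertices are merged within ``MERGE_TOL`` (1e-9 mm); for
    closed meshes the face orientation is normalised so that the signed
    volume is positive (outward normals).
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    try:
        raw = trimesh.load(str(path), file_type="stl", force="mesh", process=False)
        vertices = np.asarray(raw.vertices, dtype=float)
        faces = np.asarray(raw.faces, dtype=np.int64)
    except Exception as exc:  # pragma: no cover - depends on corrupt input
        raise MeshFormatError(f"cannot parse STL file {path} (byte offset unknown): {exc}")
    if faces.size == 0:
        raise MeshFormatError(f"no triangles in {path}")
    vertices, faces = _merge_vertices(vertices, faces, MERGE_TOL)
    mesh = PartMesh(vertices, faces, name=name or path.stem)
    mesh.closed = is_closed(mesh)
    if mesh.closed and _signed_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def _merge_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged = vertices[first]
    new_faces = inverse[faces]
    # drop degenerate triangles created by the merge
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return merged, new_faces[ok]


def is_closed(mesh: PartMesh) -> bool:
    """True when every edge is shared by exactly two faces."""
    f = mesh.faces
    edges = np.sort(
        np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(len(counts) and np.all(counts == 2))


def read_landmarks(path: str | Path, part: str = "") -> LandmarkPolyline:
    """Load a plain-text ``x y z`` landmark file (one point per line, mm)."""
    path = Path(path)
    pts = np.loadtxt(path, ndmin=2)
    if pts.shape[1] != 3:
        raise MeshFormatError(f"landmark file {path} must have 3 columns")
    closed = bool(np.linalg.norm(pts[0] - pts[-1]) < 1e-6)
    return LandmarkPolyline(part or path.stem, pts, closed_circuit=closed)


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return Manifest(
            specimen=doc.get("specimen", path.stem),
            side=doc.get("side", "left"),
            voxel_size_mm=float(doc["voxel_size_mm"]),
            parts=doc["parts"],
            cupulae=doc.get("cupulae", {}),
            root=path.parent,
        )
    except KeyError as exc:
        raise ManifestError(f"manifest {path} missing required key {exc}")


def load_geometry(manifest: Manifest | str | Path) -> DuctSystemGeometry:
    """Load every part referenced by a manifest."""
    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    parts = {}
    for part in CANONICAL_PARTS:
        vol = read_triangle_mesh(manifest.volume_path(part), name=part)
        if not vol.closed:
            raise MeshFormatError(f"volume mesh of part {part!r} is not closed")
        surfs = [
            read_triangle_mesh(p, name=p.stem) for p in manifest.surface_paths(part)
        ]
        lm = read_landmarks(manifest.landmark_path(part), part=part)
        parts[part] = PartGeometry(vol, surfs, lm)
    return DuctSystemGeometry(
        parts,
        specimen=manifest.specimen,
        side=manifest.side,
        voxel_size_mm=manifest.voxel_size_mm,
    )


# ---------------------------------------------------------------------------
# Measures and corrections


def _signed_volume(mesh: PartMesh) -> float:
    t = mesh.triangles
    return float(np.einsum("ij,ij->", t[:, 0], np.cross(t[:, 1], t[:, 2]))) / 6.0


def closed_mesh_volume(mesh: PartMesh) -> float:
    """Volume of a closed mesh in mm^3 (divergence theorem).

    Invariant to rigid motion and vertex ordering.  Raises for open
    meshes, whose 'volume' would depend on the choice of origin.
    """
    if not mesh.closed:
        raise MeshPreconditionError(
            f"volume of part {mesh.name!r} requires a closed mesh"
        )
    return abs(_signed_volume(mesh))


def mesh_surface_area(mesh: PartMesh) -> float:
    """Total triangle area in mm^2."""
    t = mesh.triangles
    return float(
        0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1).sum()
    )


def vertex_normals(mesh: PartMesh) -> np.ndarray:
    """Area-weighted unit vertex normals.

    Face normals (whose magnitude is twice the face area, hence the
    area weighting) are accumulated onto their vertices and normalised.
    """
    t = mesh.triangles
    fn = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1)
    norms[norms == 0] = 1.0
    return vn / norms[:, None]


def min_edge_length(mesh: PartMesh) -> float:
    f = mesh.faces
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    d = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    return float(d.min())


def offset_mesh(mesh: PartMesh, delta: float) -> PartMesh:
    """Displace every vertex by ``delta`` mm along its outward normal.

    Positive delta dilates, negative contracts; topology is unchanged.
    This is the operation used to propagate segmentation imprecision
    (an observer drawing the endolymph boundary slightly wide or tight)
    into the morphometric and biomechanical output.
    """
    if abs(delta) > min_edge_length(mesh) / 10.0:
        warnings.warn(
            f"offset {delta} mm exceeds a tenth of the minimum edge length of "
            f"part {mesh.name!r}; the offset surface may self-intersect",
            stacklevel=2,
        )
    out = mesh.copy()
    out.vertices = mesh.vertices + delta * vertex_normals(mesh)
    flipped = _count_flipped_faces(mesh, out)
    if flipped:
        warnings.warn(
            f"{flipped} faces inverted after offsetting part {mesh.name!r} "
            f"by {delta} mm (local self-intersection)",
            stacklevel=2,
        )
    return out


def _count_flipped_faces(before: PartMesh, after: PartMesh) -> int:
    tb, ta = before.triangles, after.triangles
    nb = np.cross(tb[:, 1] - tb[:, 0], tb[:, 2] - tb[:, 0])
    na = np.cross(ta[:, 1] - ta[:, 0], ta[:, 2] - ta[:, 0])
    return int(np.sum(np.einsum("ij,ij->i", nb, na) < 0))


def apply_shrinkage_correction(
    geometry: DuctSystemGeometry, linear_factor: float
) -> DuctSystemGeometry:
    """Undo isotropic tissue shrinkage by scaling all coordinates.

    ``linear_factor`` is the linear shrinkage the specimen underwent
    (e.g. 0.9 means the tissue shrank to 90% of its in-vivo linear
    size); coordinates are scaled by ``1/linear_factor`` about the
    centroid of the whole geometry, so lengths scale as 1/f, areas as
    1/f^2 and volumes as 1/f^3 downstream.
    """
    if linear_factor <= 0:
        raise ValueError("shrinkage factor must be positive")
    scale = 1.0 / linear_factor
    centroid = geometry.all_points().mean(axis=0)

    def _scale(points: np.ndarray) -> np.ndarray:
        return centroid + (points - centroid) * scale

    parts = {}
    for name, pg in geometry.parts.items():
        vol = pg.volume_mesh.copy()
        vol.vertices = _scale(vol.vertices)
        surfs = []
        for m in pg.surface_meshes:
            mm = m.copy()
            mm.vertices = _scale(mm.vertices)
            surfs.append(mm)
        lm = pg.landmarks.copy()
        lm.points = _scale(lm.points)
        parts[name] = PartGeometry(vol, surfs, lm)
    return replace(geometry, parts=parts)
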