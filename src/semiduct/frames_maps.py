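"""Vestibular frame of reference and directional sensitivity maps.

The vestibular frame is the functional coordinate system of head
rotation sensing: its z (yaw) axis is the normal of the functional
plane of the lateral semicircular ducts, its x (roll) axis points
anteriorly along the intersection of that plane with the mid-sagittal
plane, and y (pitch) completes the right-handed triad.  Geometry,
landmarks and response axes are transferred from the scanner frame into
this frame for comparable standard views across specimens.

Directional sensitivity is mapped over all rotation axes: for each axis
u on a longitude/latitude grid the signed mid-band velocity gain of
every duct, ``eps_k [C^-1 G u]_k (pi/180)``, is evaluated (sign by the
right-hand rule) and combined into a total; plotted in Mercator-style
longitude/latitude coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .biomech import DEG, TorsionPendulumModel
from .mesh_io import DuctSystemGeometry, PartGeometry


class FrameError(ValueError):
    """Raised when a vestibular frame cannot be constructed."""


@dataclass
class Plane:
    """A plane ``normal . x = offset`` with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("zero plane normal")
        self.normal = self.normal / n


@dataclass
class VestibularFrame:
    """Right-handed orthonormal frame (rows of ``axes`` are x, y, z)."""

    origin: np.ndarray
    axes: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise FrameError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise FrameError("frame is left-handed")

    @property
    def x(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[2]


def fit_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane through a 3D point cloud.

    The normal is the singular vector of the centred points with the
    smallest singular value.  Raises for fewer than 3 points or
    (numerically) collinear input.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("plane fit needs at least 3 points")
    centred = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    if svals[1] < 1e-12 * max(svals[0], 1e-300):
        raise ValueError("points are collinear; plane is undetermined")
    normal = vt[2]
    return Plane(normal=normal, offset=float(normal @ pts.mean(axis=0)))


def build_vestibular_frame(
    lateral_loops: list[np.ndarray],
    sagittal_plane: Plane | None = None,
    anterior_hint: np.ndarray | None = None,
) -> VestibularFrame:
    """Construct the vestibular frame from lateral-duct streamlines.

    ``lateral_loops`` holds the closed lateral-circuit streamline(s) of
    one or both ears.  With a single ear the mid-sagittal plane must be
    supplied; with both ears it defaults to the symmetry plane through
    the midpoint of the two centroids.  ``anterior_hint`` is any point
    known to lie anteriorly of the origin and disambiguates the sign of
    the x axis (without it the sign is arbitrary and a warning is
    raised).
    """
    if not lateral_loops:
        raise FrameError("at least one lateral circuit is required")
    loops = []
    for l in lateral_loops:
        l = np.asarray(l, dtype=float)
        if len(l) > 1 and np.allclose(l[0], l[-1]):
            l = l[:-1]  # drop the duplicated closing point
        loops.append(l)
    centroids = [l.mean(axis=0) for l in loops]
    origin = np.mean(centroids, axis=0)
    if sagittal_plane is None:
        if len(loops) < 2:
            raise FrameError(
                "single-ear mode requires an explicit mid-sagittal plane"
            )
        d = centroids[1] - centroids[0]
        if np.linalg.norm(d) < 1e-9:
            raise FrameError("labyrinth centroids coincide; no symmetry plane")
        sagittal_plane = Plane(normal=d, offset=float(d @ origin / np.linalg.norm(d)))

    lateral_plane = fit_plane(np.vstack(loops))
    z = lateral_plane.normal
    # orient z consistently with the traversal sense of the first loop
    a_vec = 0.5 * np.cross(loops[0][:-1], loops[0][1:]).sum(axis=0)
    if z @ a_vec < 0:
        z = -z

    x = np.cross(z, sagittal_plane.normal)
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise FrameError(
            "lateral-duct plane normal is parallel to the sagittal normal; "
            "frame is degenerate"
        )
    x = x / nx
    if anterior_hint is not None:
        if x @ (np.asarray(anterior_hint, float) - origin) < 0:
            x = -x
    else:
        warnings.warn(
            "no anterior landmark supplied; the sign of the roll (x) axis "
            "is arbitrary",
            stacklevel=2,
        )
    y = np.cross(z, x)
    return VestibularFrame(
        origin=origin,
        axes=np.vstack([x, y, z]),
        source="bilateral" if len(loops) > 1 else "single-ear+sagittal",
    )


# ---------------------------------------------------------------------------
# Transforms and standard views


def transform_points(points: np.ndarray, frame: VestibularFrame) -> np.ndarray:
    """Map world coordinates into frame coordinates."""
    return (np.asarray(points, float) - frame.origin) @ frame.axes.T


def transform_axes(vectors: np.ndarray, frame: VestibularFrame) -> np.ndarray:
    """Rotate direction vectors (no translation) into the frame."""
    return np.asarray(vectors, float) @ frame.axes.T


def transform_geometry(
    geometry: DuctSystemGeometry, frame: VestibularFrame
) -> DuctSystemGeometry:
    """Rigidly transform a full geometry into the vestibular frame."""
    parts = {}
    for name, pg in geometry.parts.items():
        vol = pg.volume_mesh.copy()
        vol.vertices = transform_points(vol.vertices, frame)
        surfs = []
        for m in pg.surface_meshes:
            mm = m.copy()
            mm.vertices = transform_points(mm.vertices, frame)
            surfs.append(mm)
        lm = pg.landmarks.copy()
        lm.points = transform_points(lm.points, frame)
        parts[name] = PartGeometry(vol, surfs, lm)
    return replace(geometry, parts=parts)


def view_matrix(view_direction: np.ndarray, up_hint: np.ndarray | None = None) -> np.ndarray:
    """4x4 row-major view matrix looking along ``view_direction``.

    The third row of the rotation block is the (unit) view direction;
    the first two rows span the screen plane, with the screen 'up'
    taken from ``up_hint`` (default +z, or +y when degenerate).
    """
    d = np.asarray(view_direction, float)
    d = d / np.linalg.norm(d)
    up = np.array([0.0, 0.0, 1.0]) if up_hint is None else np.asarray(up_hint, float)
    if abs(up @ d) > 1.0 - 1e-6:
        up = np.array([0.0, 1.0, 0.0])
    right = np.cross(up, d)
    right /= np.linalg.norm(right)
    screen_up = np.cross(d, right)
    m = np.eye(4)
    m[:3, :3] = np.vstack([right, screen_up, d])
    return m


def standard_views(
    max_axes: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Pitch/roll/yaw view matrices plus per-duct in-plane views.

    Expressed in vestibular-frame coordinates, where the roll view
    looks along +x, pitch along +y, yaw along +z; an in-plane view of a
    duct looks along its maximal response axis, so the projected
    streamline encloses maximal area.
    """
    axes = np.eye(3)
    views = {
        "roll": view_matrix(axes[0]),
        "pitch": view_matrix(axes[1]),
        "yaw": view_matrix(axes[2], up_hint=np.array([0.0, 1.0, 0.0])),
    }
    for duct, u in (max_axes or {}).items():
        views[f"in_plane_{duct}"] = view_matrix(u)
    return views


# ---------------------------------------------------------------------------
# Sensitivity maps


@dataclass
class SensitivityMap:
    """Directional mechanical sensitivity over all rotation axes.

    ``lon``/``lat`` are grid edges in degrees; ``total`` and each entry
    of ``per_duct`` are (n_lat, n_lon) arrays in mdeg per deg/s.
    Per-duct values are signed by the right-hand rule (positive when
    rotation about +u excites the duct in its positive flow sense); the
    total combines their magnitudes with ``rule``.
    """

    lon: np.ndarray
    lat: np.ndarray
    total: np.ndarray
    per_duct: dict[str, np.ndarray]
    rule: str = "l2"
    grid_step: float = 2.0


_RULES = {
    "l2": lambda s: np.sqrt(np.sum(np.square(s), axis=0)),
    "l1": lambda s: np.sum(np.abs(s), axis=0),
    "max": lambda s: np.max(np.abs(s), axis=0),
}


def duct_gain_matrix(model: TorsionPendulumModel) -> np.ndarray:
    """Rows of signed mid-band velocity gain per unit rotation axis.

    ``gain = eps * (C^-1 G) * pi/180``: row k dotted with a unit axis u
    gives duct k's signed plateau gain in mdeg per deg/s.
    """
    return model.eps[:, None] * np.linalg.solve(model.C, model.G) * DEG


def sensitivity_map(
    models: TorsionPendulumModel | list[TorsionPendulumModel],
    grid_step: float = 2.0,
    rule: str = "l2",
    labels: list[str] | None = None,
) -> SensitivityMap:
    """Map the mid-band sensitivity over a longitude/latitude axis grid.

    ``models`` holds one labyrinth or both (left and right); the models
    must already be expressed in the vestibular frame.  Longitude is
    measured in the x-y plane from +x, latitude from the x-y plane
    toward +z.
    """
    if isinstance(models, TorsionPendulumModel):
        models = [models]
    if rule not in _RULES:
        raise ValueError(f"unknown combination rule {rule!r}; use one of {list(_RULES)}")
    if labels is None:
        labels = [""] * len(models) if len(models) == 1 else ["left_", "right_"]
    lon = np.arange(-180.0, 180.0 + grid_step / 2, grid_step)
    lat = np.arange(-90.0, 90.0 + grid_step / 2, grid_step)
    lon_r, lat_r = np.radians(lon), np.radians(lat)
    u = np.stack(
        [
            np.cos(lat_r)[:, None] * np.cos(lon_r)[None, :],
            np.cos(lat_r)[:, None] * np.sin(lon_r)[None, :],
            np.sin(lat_r)[:, None] * np.ones_like(lon_r)[None, :],
        ],
        axis=0,
    )  # (3, n_lat, n_lon)

    per_duct: dict[str, np.ndarray] = {}
    stack = []
    for model, tag in zip(models, labels):
        gm = duct_gain_matrix(model)  # (3, 3)
        signed = np.einsum("kj,jab->kab", gm, u)
        for k, duct in enumerate(model.ducts):
            per_duct[f"{tag}{duct}"] = signed[k]
            stack.append(signed[k])
    total = _RULES[rule](np.array(stack))
    return SensitivityMap(
        lon=lon, lat=lat, total=total, per_duct=per_duct, rule=rule, grid_step=grid_step
    )


def map_to_frame_rows(smap: SensitivityMap):
    """Yield tidy (lon, lat, total, per-duct...) rows for CSV export."""
    ducts = list(smap.per_duct)
    yield ["lon_deg", "lat_deg", "total"] + ducts
    for i, la in enumerate(smap.lat):
        for j, lo in enumerate(smap.lon):
            yield [lo, la, smap.total[i, j]] + [smap.per_duct[d][i, j] for d in ducts]
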