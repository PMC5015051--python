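"""Shared fixtures: synthetic labyrinth (generated once per session) and
simple geometric primitives."""

from __future__ import annotations

import numpy as np
import pytest

from semiduct.constants import PhysiologyConstants
from semiduct.pipeline import RunConfig, run_all
from semiduct.synthetic import TorusLabyrinthSpec, make_torus_labyrinth


def disc_outline(radius: float = 0.5, n: int = 720) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)


def cube_mesh():
    """Unit cube as 8 vertices / 12 outward-oriented triangles."""
    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2],        # x = 0
            [4, 6, 7], [4, 7, 5],        # x = 1
            [0, 4, 5], [0, 5, 1],        # y = 0
            [2, 3, 7], [2, 7, 6],        # y = 1
            [0, 2, 6], [0, 6, 4],        # z = 0
            [1, 5, 7], [1, 7, 3],        # z = 1
        ]
    )
    return v, f


def icosphere(radius: float = 1.0, subdivisions: int = 3):
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return np.asarray(m.vertices), np.asarray(m.faces)


def torus_mesh(big_radius: float = 3.0, tube_radius: float = 0.1, n_u: int = 200, n_v: int = 64):
    """Closed torus triangulation (analytic volume 2 pi^2 R r^2)."""
    u = 2.0 * np.pi * np.arange(n_u) / n_u
    v = 2.0 * np.pi * np.arange(n_v) / n_v
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (big_radius + tube_radius * np.cos(vv)) * np.cos(uu)
    y = (big_radius + tube_radius * np.cos(vv)) * np.sin(uu)
    z = tube_radius * np.sin(vv)
    verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    faces = []
    for i in range(n_u):
        for j in range(n_v):
            a = i * n_v + j
            b = i * n_v + (j + 1) % n_v
            c = ((i + 1) % n_u) * n_v + (j + 1) % n_v
            d = ((i + 1) % n_u) * n_v + j
            faces.append([a, c, b])
            faces.append([a, d, c])
    return verts, np.asarray(faces)


@pytest.fixture(scope="session")
def labyrinth_fixture(tmp_path_factory):
    """Default synthetic labyrinth written once; returns (manifest, truth)."""
    outdir = tmp_path_factory.mktemp("labyrinth")
    spec = TorusLabyrinthSpec(seed=7)
    manifest, truth = make_torus_labyrinth(spec, outdir)
    return manifest, truth


@pytest.fixture(scope="session")
def pipeline_run(labyrinth_fixture, tmp_path_factory):
    """Full pipeline output on the session labyrinth."""
    manifest, truth = labyrinth_fixture
    outdir = tmp_path_factory.mktemp("report")
    cfg = RunConfig(manifest=manifest, output_dir=outdir, seed=7)
    out = run_all(cfg)
    return out, truth


@pytest.fixture()
def constants():
    return PhysiologyConstants()
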