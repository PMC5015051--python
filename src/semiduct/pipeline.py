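"""One-button pipeline: geometry in, tables and maps out.

``run_all`` chains the stages -- mesh loading, morphometry, cupula
finite elements, torsion-pendulum assembly, frame construction and
sensitivity mapping -- and writes the full report bundle (tidy CSV
tables, Bode curves, the Mercator sensitivity grid and a JSON run log
echoing the configuration, versions and seed).  Each stage can also be
driven individually through the library API or the ``semiduct`` CLI.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomech import BiomechResult, TorsionPendulumModel, analyze, frequency_response
from .constants import DUCTS, PhysiologyConstants
from .cupula_fea import (
    CupulaCrossSection,
    CupulaModel,
    cilia_transfer_factor,
    cupula_stiffness,
    solve_plate,
    volume_displacement,
)
from .frames_maps import (
    Plane,
    build_vestibular_frame,
    map_to_frame_rows,
    sensitivity_map,
    transform_axes,
)
from .mesh_io import (
    DuctSystemGeometry,
    Manifest,
    apply_shrinkage_correction,
    load_geometry,
    offset_mesh,
    read_manifest,
)
from .morphometry import system_morphometry
from .tables import model_to_frame, result_to_frame

log = logging.getLogger("semiduct")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    manifest: Path
    constants: PhysiologyConstants = field(default_factory=PhysiologyConstants)
    shrinkage_factor: float = 1.0
    offsets_mm: tuple[float, ...] = ()
    output_dir: Path = Path("semiduct_out")
    map_grid_step: float = 2.0
    fea_target_size: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.output_dir = Path(self.output_dir)
        if not self.manifest.exists():
            raise FileNotFoundError(f"manifest not found: {self.manifest}")
        if not all(np.isfinite(self.offsets_mm)):
            raise ValueError("offset sweep values must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(overrides)
        const_keys = {"rho", "mu", "gamma", "nu", "cilia_length_mm"}
        const = {k: doc.pop(k) for k in list(doc) if k in const_keys}
        doc["constants"] = PhysiologyConstants(**const)
        if "offsets_mm" in doc:
            doc["offsets_mm"] = tuple(doc["offsets_mm"])
        base = Path(path).parent
        doc["manifest"] = base / doc["manifest"]
        return cls(**doc)


def cupula_analysis(
    manifest: Manifest,
    constants: PhysiologyConstants,
    pressure: float = 0.05,
    target_size: float | None = None,
) -> dict[str, dict[str, float]]:
    """Per-duct cupula stiffness k and transfer factor eps via FEA."""
    if not manifest.cupulae:
        raise StageError("fea", "manifest lists no cupula cross-sections")
    out = {}
    for duct in DUCTS:
        entry = manifest.cupulae.get(duct)
        if entry is None:
            raise StageError("fea", f"no cupula entry for duct {duct!r}")
        outline = np.loadtxt(manifest.root / entry["outline"], ndmin=2)
        section = CupulaCrossSection(outline, duct=duct)
        model = CupulaModel(
            section,
            thickness=float(entry["thickness"]),
            gamma=constants.gamma,
            nu=constants.nu,
        )
        sol = solve_plate(model, pressure=pressure, target_size=target_size)
        dv = volume_displacement(sol)
        out[duct] = {
            "k": cupula_stiffness(pressure, dv),
            "eps": cilia_transfer_factor(sol, constants.cilia_length_mm),
            "dV": dv,
            "thickness": model.thickness,
            "section_area": section.area,
        }
    return out


def assemble_from_geometry(
    geometry: DuctSystemGeometry,
    cupula: dict[str, dict[str, float]],
    constants: PhysiologyConstants,
):
    """Morphometry + cupula results -> assembled torsion-pendulum model."""
    part_morph, circuits, couplings = system_morphometry(geometry, constants)
    coeffs = {
        d: {"m": circuits[d].m, "c": circuits[d].c, "k": cupula[d]["k"]}
        for d in DUCTS
    }
    gmat = np.array([circuits[d].g for d in DUCTS])
    eps = np.array([cupula[d]["eps"] for d in DUCTS])
    model = TorsionPendulumModel.from_coefficients(
        m=np.array([coeffs[d]["m"] for d in DUCTS]),
        c=np.array([coeffs[d]["c"] for d in DUCTS]),
        k=np.array([coeffs[d]["k"] for d in DUCTS]),
        g=gmat,
        eps=eps,
        m_cc=couplings["cc"]["m"],
        m_uc=couplings["uc"]["m"],
        c_cc=couplings["cc"]["c"],
        c_uc=couplings["uc"]["c"],
        table_units=True,
    )
    return model, part_morph, circuits, couplings


def _offset_geometry(geometry: DuctSystemGeometry, delta: float) -> DuctSystemGeometry:
    """Offset every wall mesh by delta; streamlines are untouched."""
    parts = {}
    for name, pg in geometry.parts.items():
        parts[name] = dataclasses.replace(
            pg,
            volume_mesh=offset_mesh(pg.volume_mesh, delta),
            surface_meshes=[offset_mesh(m, delta) for m in pg.surface_meshes],
        )
    return dataclasses.replace(geometry, parts=parts)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the assembled model, the biomechanical result
    and the output paths.  Any stage failure raises :class:`StageError`
    naming the stage; outputs written before the failure are kept.
    """
    t0 = time.time()
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    np.random.seed(config.seed % 2**31)
    constants = config.constants

    def stage(name, fn, *args, **kw):
        log.info("stage %s ...", name)
        try:
            return fn(*args, **kw)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    manifest = stage("manifest", read_manifest, config.manifest)
    geometry = stage("load", load_geometry, manifest)
    if config.shrinkage_factor != 1.0:
        geometry = stage(
            "shrinkage", apply_shrinkage_correction, geometry, config.shrinkage_factor
        )
    cupula = stage(
        "fea", cupula_analysis, manifest, constants, target_size=config.fea_target_size
    )
    model, part_morph, circuits, couplings = stage(
        "assemble", assemble_from_geometry, geometry, cupula, constants
    )
    result = stage("biomech", analyze, model)

    # offset sweep: parameter ranges under uniform wall dilation/contraction
    sweep_rows = []
    for delta in config.offsets_mm:
        geo_d = stage("offset", _offset_geometry, geometry, delta)
        model_d, _, circ_d, _ = stage(
            "assemble", assemble_from_geometry, geo_d, cupula, constants
        )
        res_d = stage("biomech", analyze, model_d)
        for d in DUCTS:
            sweep_rows.append(
                {
                    "delta_mm": delta,
                    "duct": d,
                    "m": circ_d[d].m,
                    "c": circ_d[d].c,
                    "g": float(np.linalg.norm(circ_d[d].g)),
                    "tau1_s": res_d.tau1[d],
                    "tau2_ms": res_d.tau2[d] * 1e3,
                    "sensitivity": res_d.sensitivity[d],
                }
            )

    # vestibular frame from the lateral circuit (+ manifest sagittal plane)
    frame = None
    with open(config.manifest) as fh:
        mdoc = yaml.safe_load(fh)
    sag = mdoc.get("sagittal_plane")
    if sag is not None:
        plane = Plane(normal=np.asarray(sag["normal"], float), offset=float(sag.get("offset", 0.0)))
        hint = mdoc.get("anterior_hint")
        frame = stage(
            "frame",
            build_vestibular_frame,
            [circuits["lateral"].loop],
            plane,
            np.asarray(hint, float) if hint is not None else None,
        )
        rot = frame.axes
        model_frame = TorsionPendulumModel(
            M=model.M, C=model.C, K=model.K,
            G=transform_axes(model.G, frame), eps=model.eps,
        )
    else:
        log.warning("no sagittal plane in manifest; maps use the scan frame")
        model_frame = model
    smap = stage("map", sensitivity_map, model_frame, config.map_grid_step)

    # ---- report bundle
    paths = {}

    def write_csv(name: str, df: pd.DataFrame):
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p

    write_csv(
        "parts.csv",
        pd.DataFrame([dataclasses.asdict(pm) for pm in part_morph.values()]),
    )
    circ_df = pd.DataFrame(
        [
            {
                "duct": d,
                "length_mm": float(np.sum(np.linalg.norm(np.diff(circuits[d].loop, axis=0), axis=1))),
                "enclosed_area_mm2": float(np.linalg.norm(circuits[d].vector_area)),
                "g_mg_mm": float(np.linalg.norm(circuits[d].g)),
                "radius_of_curvature_mm": circuits[d].radius_of_curvature,
            }
            for d in DUCTS
        ]
    )
    write_csv("circuits.csv", circ_df)
    write_csv("coefficients.csv", model_to_frame(model))
    write_csv("biomech.csv", result_to_frame(result))
    if sweep_rows:
        write_csv("offset_sweep.csv", pd.DataFrame(sweep_rows))

    bode_rows = []
    axes = {"pitch": (0, 1, 0), "roll": (1, 0, 0), "yaw": (0, 0, 1)}
    for d in DUCTS:
        axes[f"in_plane_{d}"] = tuple(result.max_axis[d])
    for name, u in axes.items():
        resp = frequency_response(model, np.asarray(u, float) / np.linalg.norm(u))
        for d in DUCTS:
            bode_rows.append(
                pd.DataFrame(
                    {
                        "stimulus": name,
                        "duct": d,
                        "freq_hz": resp["freq_hz"],
                        "gain_mdeg_per_deg_s": resp[f"gain_{d}"],
                        "phase_deg": resp[f"phase_{d}"],
                    }
                )
            )
    write_csv("bode.csv", pd.concat(bode_rows, ignore_index=True))

    map_path = outdir / "sensitivity_map.csv"
    with open(map_path, "w") as fh:
        for row in map_to_frame_rows(smap):
            fh.write(",".join(str(v) for v in row) + "\n")
    paths["sensitivity_map.csv"] = map_path

    runlog = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 3),
        "config": {
            "manifest": str(config.manifest),
            "shrinkage_factor": config.shrinkage_factor,
            "offsets_mm": list(config.offsets_mm),
            "map_grid_step": config.map_grid_step,
            "constants": dataclasses.asdict(constants),
        },
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(runlog, fh, indent=1, sort_keys=True)
    paths["run_log.json"] = outdir / "run_log.json"

    return {
        "model": model,
        "result": result,
        "circuits": circuits,
        "couplings": couplings,
        "cupula": cupula,
        "frame": frame,
        "map": smap,
        "paths": paths,
    }
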