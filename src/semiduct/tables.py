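"""Coefficient-table entry point and result export.

Besides the full geometric pipeline, the biomechanical analysis can be
entered directly at the coefficient level: a table of per-duct
torsion-pendulum coefficients (m, c, k, g, eps) plus the two shared
couplings (cc, uc) fully determines time constants and sensitivities.
This is how published coefficient tables are re-analysed without access
to the underlying meshes.

Table layout (CSV): columns ``species, duct, m, c, k, g, eps`` with one
row per duct (``anterior``/``posterior``/``lateral``) and one row each
for the couplings (``cc``, ``uc``; only m and c are meaningful there).
Units are the conventional reporting units: m in mg.mm^-4, c in
g.s^-1.mm^-4, k in g.s^-2.mm^-4, g in mg.mm^-1, eps in mdeg.nL^-1.

A table of published coefficients for three primate specimens (human,
rhesus macaque, squirrel monkey) ships with the package as
``primate_coefficients_path()``.  Because such tables print only the
magnitudes of the g vectors, the duct axes are taken as mutually
orthogonal when rebuilding the model from a table; this only affects
the maximal-response-axis directions, not the time constants, and
perturbs sensitivities by well under a percent (couplings are small).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .biomech import BiomechResult, TorsionPendulumModel, analyze
from .constants import DUCTS


def primate_coefficients_path() -> Path:
    """Path of the bundled primate coefficient table."""
    return Path(resources.files("semiduct") / "data" / "primate_duct_coefficients.csv")


def load_coefficient_table(path: str | Path | pd.DataFrame) -> pd.DataFrame:
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
    required = {"duct", "m", "c"}
    if not required.issubset(df.columns):
        raise ValueError(f"coefficient table needs columns {sorted(required)}")
    if "species" not in df.columns:
        df = df.assign(species="unnamed")
    return df


def model_from_table(
    table: str | Path | pd.DataFrame, species: str | None = None
) -> TorsionPendulumModel:
    """Build a :class:`TorsionPendulumModel` from one species of a table."""
    df = load_coefficient_table(table)
    names = df["species"].unique()
    if species is None:
        if len(names) > 1:
            raise ValueError(f"table holds several species {list(names)}; pick one")
        species = names[0]
    sub = df[df["species"] == species].set_index("duct")
    missing = [d for d in DUCTS if d not in sub.index]
    if missing:
        raise ValueError(f"species {species!r}: missing duct rows {missing}")
    for coupling in ("cc", "uc"):
        if coupling not in sub.index:
            raise ValueError(
                f"species {species!r}: missing coupling row {coupling!r} "
                "(use 0 for an uncoupled system)"
            )
    ducts = sub.loc[list(DUCTS)]
    return TorsionPendulumModel.from_coefficients(
        m=ducts["m"].to_numpy(float),
        c=ducts["c"].to_numpy(float),
        k=ducts["k"].to_numpy(float),
        g=ducts["g"].to_numpy(float),
        eps=ducts["eps"].to_numpy(float),
        m_cc=float(sub.loc["cc", "m"]),
        m_uc=float(sub.loc["uc", "m"]),
        c_cc=float(sub.loc["cc", "c"]),
        c_uc=float(sub.loc["uc", "c"]),
    )


def run_from_coefficients(
    table: str | Path | pd.DataFrame, species: str | None = None
) -> BiomechResult:
    """Time constants and sensitivities straight from a coefficient table."""
    return analyze(model_from_table(table, species))


def result_to_frame(result: BiomechResult) -> pd.DataFrame:
    """Tidy per-duct summary in reporting units (tau2 in ms)."""
    rows = []
    for duct in DUCTS:
        rows.append(
            {
                "duct": duct,
                "tau1_s": result.tau1[duct],
                "tau2_ms": result.tau2[duct] * 1e3,
                "sensitivity_mdeg_per_deg_s": result.sensitivity[duct],
                "relative_sensitivity_pct": result.relative_sensitivity[duct],
                "axis_x": result.max_axis[duct][0],
                "axis_y": result.max_axis[duct][1],
                "axis_z": result.max_axis[duct][2],
            }
        )
    return pd.DataFrame(rows)


def model_to_frame(model: TorsionPendulumModel) -> pd.DataFrame:
    """Export an assembled model back to the table layout (reporting units)."""
    rows = []
    for i, duct in enumerate(model.ducts):
        rows.append(
            {
                "duct": duct,
                "m": model.M[i, i] * 1e3,
                "c": model.C[i, i],
                "k": model.K[i, i],
                "g": float(np.linalg.norm(model.G[i])) * 1e3,
                "eps": model.eps[i] * 1e-3,
            }
        )
    rows.append({"duct": "cc", "m": model.M[0, 1] * 1e3, "c": model.C[0, 1]})
    rows.append({"duct": "uc", "m": model.M[0, 2] * 1e3, "c": model.C[0, 2]})
    return pd.DataFrame(rows)
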