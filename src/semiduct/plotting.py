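"""Matplotlib rendering of Bode curves, sensitivity maps and FEA fields."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .constants import DUCTS
from .frames_maps import SensitivityMap


def plot_bode(responses: dict[str, dict[str, np.ndarray]], path) -> None:
    """Gain/phase plot; ``responses`` maps curve label -> frequency_response dict."""
    fig, (ax_g, ax_p) = plt.subplots(2, 1, figsize=(6, 7), sharex=True)
    for label, resp in responses.items():
        for duct in DUCTS:
            ax_g.loglog(resp["freq_hz"], resp[f"gain_{duct}"], label=f"{label} {duct}")
            ax_p.semilogx(resp["freq_hz"], resp[f"phase_{duct}"])
    ax_g.set_ylabel("gain (mdeg per deg/s)")
    ax_p.set_ylabel("phase re velocity (deg)")
    ax_p.set_xlabel("frequency (Hz)")
    ax_g.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sensitivity_map(smap: SensitivityMap, path) -> None:
    """Mercator-style longitude/latitude image of the total sensitivity."""
    fig, ax = plt.subplots(figsize=(8, 4))
    pm = ax.pcolormesh(smap.lon, smap.lat, smap.total, shading="auto", cmap="viridis")
    fig.colorbar(pm, ax=ax, label="sensitivity (mdeg per deg/s)")
    ax.set_xlabel("longitude (deg)")
    ax.set_ylabel("latitude (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_plate_field(sol, path, field: str = "deflection") -> None:
    """Colour map of the plate deflection or rotation magnitude."""
    mesh = sol.mesh
    values = sol.w if field == "deflection" else np.linalg.norm(sol.theta, axis=1)
    fig, ax = plt.subplots(figsize=(5, 5))
    tris = np.vstack([mesh.quads[:, [0, 1, 2]], mesh.quads[:, [0, 2, 3]]])
    tc = ax.tripcolor(mesh.nodes[:, 0], mesh.nodes[:, 1], tris, values, shading="gouraud")
    fig.colorbar(tc, ax=ax, label=field)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
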