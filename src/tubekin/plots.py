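"""Rendered figures for kymographs (headless matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["save_shear_kymograph", "save_activity_kymograph"]


def save_shear_kymograph(kymo_df, path) -> Path:
    """Heatmap of circumferentially averaged |mu| over (s, t)."""
    piv = kymo_df.pivot_table(index="t", columns="s_center", values="abs_mu")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(piv.columns, piv.index, piv.to_numpy(), shading="auto")
    ax.set_xlabel("material AP position s (um)")
    ax.set_ylabel("time (min)")
    fig.colorbar(im, ax=ax, label="|mu|")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def save_activity_kymograph(kymo: dict, path) -> Path:
    """Heatmap of the group-mean calcium activity over (AP, t)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    data = np.ma.masked_invalid(kymo["mean"])
    im = ax.pcolormesh(kymo["ap"], kymo["t"], data, shading="auto")
    ax.set_xlabel("AP position (um)")
    ax.set_ylabel("time from onset (min)")
    fig.colorbar(im, ax=ax, label="activity (a.u.)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
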