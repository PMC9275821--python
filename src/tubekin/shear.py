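"""Material-frame shear via the Beltrami coefficient.

Anisotropic tissue deformation is measured against a fixed *material chart*:
per-vertex 2D coordinates assigned at a reference time (the onset of the
first constriction) whose reference metric is conformal — an infinitesimal
circle of tissue drawn in the chart is a circle on the surface.  At later
times the same chart maps to the deformed surface; the induced metric
``g' = J^T J`` of that map encodes all accumulated anisotropy in the complex
Beltrami coefficient

    mu = (g11' - g22' + 2 i g12') / (g11' + g22' + 2 sqrt(det g')),

with |mu| < 1 for any positive-definite metric.  |mu| gives the axis ratio
``K = (1 + |mu|)/(1 - |mu|)`` of the image ellipse of an infinitesimal
circle; arg(mu)/2 is the stretch orientation relative to the chart axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .geometry import (
    TubeSurface,
    face_areas,
    face_chart_coords,
    harmonic_cylinder_chart,
)

__all__ = [
    "MaterialChart",
    "build_material_chart",
    "induced_metric",
    "beltrami",
    "anisotropy_ratio",
    "face_beltrami",
    "shear_kymograph",
]


@dataclass
class MaterialChart:
    """Per-vertex material coordinates fixed at the reference time.

    ``coords[:, 0]`` is the longitudinal coordinate (zeta), ``coords[:, 1]``
    the circumferential one (phi-like, period 2*pi after scaling bookkeeping
    is absorbed into zeta).  ``faces`` matches the reference surface.
    ``residual_mu`` reports the per-face area-weighted mean |mu| of the
    reference itself — how far the chart is from exactly isotropic.
    """

    coords: np.ndarray  # (n, 2)
    faces: np.ndarray
    s_material: np.ndarray  # per-vertex longitudinal coordinate for binning
    residual_mu: float
    period: float = 2.0 * np.pi  # circumferential period of coords[:, 1]


def _face_coords_2d(coords: np.ndarray, faces: np.ndarray, period: float) -> np.ndarray:
    """Per-face (3, 2) material coordinates, second column unwrapped."""
    c = coords[faces]
    ref = c[:, :1, 1]
    c = c.copy()
    c[:, :, 1] += period * np.round((ref - c[:, :, 1]) / period)
    return c


def induced_metric(
    surface_t: TubeSurface, chart: MaterialChart
) -> np.ndarray:
    """Per-face induced metric g' = (g11, g12, g22) of chart -> 3D at time t.

    Each triangle's affine map from material coordinates to its 3D embedding
    gives ``g'_ij = d_i X . d_j X``; shared vertex correspondence carries the
    chart onto the deformed surface.
    """
    F = chart.faces
    c2 = _face_coords_2d(chart.coords, F, chart.period)
    V = surface_t.vertices
    e1_2 = c2[:, 1] - c2[:, 0]
    e2_2 = c2[:, 2] - c2[:, 0]
    P = np.stack([e1_2, e2_2], axis=-1)  # (m, 2, 2)
    detP = P[:, 0, 0] * P[:, 1, 1] - P[:, 0, 1] * P[:, 1, 0]
    if np.any(np.abs(detP) < 1e-14):
        bad = np.flatnonzero(np.abs(detP) < 1e-14)
        raise ValueError(f"degenerate chart triangles at faces {bad[:10].tolist()}")
    Pinv = np.empty_like(P)
    Pinv[:, 0, 0] = P[:, 1, 1]
    Pinv[:, 1, 1] = P[:, 0, 0]
    Pinv[:, 0, 1] = -P[:, 0, 1]
    Pinv[:, 1, 0] = -P[:, 1, 0]
    Pinv /= detP[:, None, None]
    E1 = V[F[:, 1]] - V[F[:, 0]]
    E2 = V[F[:, 2]] - V[F[:, 0]]
    Q = np.stack([E1, E2], axis=-1)  # (m, 3, 2)
    QtQ = np.einsum("mik,mil->mkl", Q, Q)
    g = np.einsum("mki,mkl,mlj->mij", Pinv, QtQ, Pinv)
    return np.stack([g[:, 0, 0], g[:, 0, 1], g[:, 1, 1]], axis=-1)


def beltrami(g: np.ndarray) -> np.ndarray:
    """Beltrami coefficient mu from metric components (g11, g12, g22).

    Accepts a single triple or an (m, 3) array.  Requires positive-definite
    input; returns complex mu with |mu| < 1, and mu = 0 iff the metric is
    conformal.
    """
    g = np.atleast_2d(np.asarray(g, dtype=float))
    g11, g12, g22 = g[:, 0], g[:, 1], g[:, 2]
    det = g11 * g22 - g12 * g12
    if np.any(det <= 0) or np.any(g11 <= 0):
        raise ValueError("metric must be positive definite")
    mu = (g11 - g22 + 2j * g12) / (g11 + g22 + 2.0 * np.sqrt(det))
    return mu[0] if mu.shape == (1,) else mu


def anisotropy_ratio(mu) -> np.ndarray | float:
    """Axis ratio K = (1 + |mu|) / (1 - |mu|) of the image ellipse; K >= 1."""
    amu = np.abs(mu)
    if np.any(np.atleast_1d(amu) >= 1):
        raise ValueError("|mu| must be < 1")
    return (1.0 + amu) / (1.0 - amu)


def face_beltrami(surface_t: TubeSurface, chart: MaterialChart) -> np.ndarray:
    """Per-face Beltrami coefficient of the material map at time t."""
    return beltrami(induced_metric(surface_t, chart))


def build_material_chart(reference: TubeSurface, max_residual: float = 0.05) -> MaterialChart:
    """Isotropy-normalized material chart from the reference surface.

    Starts from the surface's own (s, phi) chart (computed harmonically if
    absent), then rescales the longitudinal coordinate by a single factor
    chosen to minimize the area-weighted mean |mu| of the reference map —
    for a tube this aligns the longitudinal and circumferential metric
    scales, making the reference conformal up to discretization.  The
    residual anisotropy is reported and must not exceed ``max_residual``.
    """
    if not reference.has_chart:
        reference = harmonic_cylinder_chart(reference)
    fc = face_chart_coords(reference)  # (m, 3, 2), phi unwrapped
    s = reference.s

    fa = face_areas(reference.vertices, reference.faces)

    def mean_abs_mu(log_scale: float) -> float:
        coords = np.stack(
            [reference.s * np.exp(log_scale), reference.phi], axis=-1
        )
        chart = MaterialChart(coords, reference.faces, s, 0.0)
        mu = face_beltrami(reference, chart)
        return float((fa * np.abs(mu)).sum() / fa.sum())

    # bracket the scale: s-range vs circumference of order 2*pi
    s_span = s.max() - s.min()
    guess = np.log(2.0 * np.pi / max(s_span, 1e-9))
    res = minimize_scalar(
        mean_abs_mu,
        bounds=(guess - 3.0, guess + 3.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    scale = float(np.exp(res.x))
    coords = np.stack([s * scale, reference.phi], axis=-1)
    residual = float(res.fun)
    if residual > max_residual:
        raise ValueError(
            f"reference chart anisotropy |mu|={residual:.3f} exceeds "
            f"{max_residual}; the reference surface is not well approximated "
            "by this conformal normalization"
        )
    return MaterialChart(coords, reference.faces, s.copy(), residual)


def shear_kymograph(
    sequence,
    chart: MaterialChart,
    n_s_bins: int = 40,
    magnitude: bool = False,
) -> pd.DataFrame:
    """Circumferentially averaged Beltrami coefficient per s-bin and time.

    For each timepoint the per-face mu is averaged (complex, area-weighted —
    orientation cancellation preserved; set ``magnitude=True`` to average
    |mu| instead) within bins of the material longitudinal coordinate.

    Columns: t, s_bin, s_center, re_mu, im_mu, abs_mu, K.
    """
    s_face = chart.s_material[chart.faces].mean(axis=1)
    edges = np.linspace(
        chart.s_material.min(), chart.s_material.max(), n_s_bins + 1
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    bins = np.clip(np.digitize(s_face, edges) - 1, 0, n_s_bins - 1)
    rows = []
    for k, surf in enumerate(sequence.surfaces):
        mu = face_beltrami(surf, chart)
        fa = face_areas(surf.vertices, surf.faces)
        for b in range(n_s_bins):
            sel = bins == b
            if not sel.any():
                raise ValueError(f"empty s-bin {b} in kymograph")
            w = fa[sel]
            if magnitude:
                m = (w * np.abs(mu[sel])).sum() / w.sum()
                m = complex(m, 0.0)
            else:
                m = complex((w * mu[sel]).sum() / w.sum())
            rows.append(
                {
                    "t": float(sequence.times[k]),
                    "s_bin": b,
                    "s_center": float(centers[b]),
                    "re_mu": m.real,
                    "im_mu": m.imag,
                    "abs_mu": abs(m),
                    "K": float(anisotropy_ratio(abs(m))),
                }
            )
    return pd.DataFrame(rows)
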