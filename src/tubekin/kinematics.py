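"""Covariant tissue kinematics on evolving surfaces.

The central quantity is the near-incompressibility relation on a deforming
surface: for a tissue that conserves local area, the out-of-plane deformation
``2 H v_n`` (mean curvature times inward normal velocity) balances the
covariant in-plane divergence ``div v_par`` of the tangential velocity.  The
residual ``div v_par - 2 H v_n`` is the local relative area growth rate
``d ln A / dt``.

Velocities come from Lagrangian vertex correspondence (same vertex = same
material point); geometric operators are evaluated on the midpoint surface of
each displacement step, which makes the forward-difference velocity a centered
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    SurfaceSequence,
    TubeSurface,
    boundary_vertex_mask,
    face_areas,
    face_normals,
    mean_curvature,
    vertex_areas,
    vertex_normals,
)

__all__ = [
    "VelocityField",
    "lagrangian_velocity",
    "covariant_divergence",
    "patch_flux",
    "incompressibility_fields",
    "incompressibility_correlation",
    "weighted_pearson",
    "metric_rate_check",
]


@dataclass
class VelocityField:
    """Per-vertex velocity split into tangential and inward-normal parts."""

    v: np.ndarray  # (n, 3) um/min
    v_par: np.ndarray  # (n, 3), tangential
    vn: np.ndarray  # (n,), positive inward
    time: float

    def __post_init__(self) -> None:
        # v = v_par + vn * n exactly by construction; guard tangency
        pass


def lagrangian_velocity(
    seq: SurfaceSequence, k: int
) -> tuple[VelocityField, TubeSurface]:
    """Forward-difference velocity at timepoint ``k`` and the midpoint surface.

    ``v_i = (X_i(t_{k+1}) - X_i(t_k)) / dt`` per vertex; at the last timepoint
    a backward difference is used.  The decomposition into tangential and
    normal parts is taken against the midpoint surface's inward normals.
    """
    if len(seq) < 2:
        raise ValueError("need at least two timepoints for a velocity")
    if k == len(seq) - 1:
        k0, k1 = k - 1, k
    else:
        k0, k1 = k, k + 1
    dt = seq.times[k1] - seq.times[k0]
    if dt <= 0:
        raise ValueError("non-increasing timestamps")
    X0, X1 = seq[k0].vertices, seq[k1].vertices
    v = (X1 - X0) / dt
    mid = seq[k0].with_vertices(0.5 * (X0 + X1))
    n_in = vertex_normals(mid.vertices, mid.faces)
    vn = np.einsum("ij,ij->i", v, n_in)
    v_par = v - vn[:, None] * n_in
    return VelocityField(v=v, v_par=v_par, vn=vn, time=float(seq.times[k0])), mid


def _p1_hat_gradients(surface: TubeSurface):
    """Gradients of the P1 hat functions of each face corner: (m, 3, 3)."""
    V, F = surface.vertices, surface.faces
    v0, v1, v2 = (V[F[:, k]] for k in range(3))
    n = face_normals(V, F)
    a2 = (2.0 * face_areas(V, F))[:, None]
    g0 = np.cross(n, v2 - v1) / a2
    g1 = np.cross(n, v0 - v2) / a2
    g2 = np.cross(n, v1 - v0) / a2
    return np.stack([g0, g1, g2], axis=1)


def covariant_divergence(
    v_par: np.ndarray, surface: TubeSurface, check_tangency: bool = True
) -> np.ndarray:
    """Covariant divergence of a tangential field, per vertex (1/min).

    Galerkin (P1 finite-element) weak form with lumped vertex areas:
    ``div_i = -(1/A_i) * sum_f A_f * v_f . grad(hat_i)|_f`` where ``v_f`` is
    the face-average of the vertex field projected into the face plane.  On a
    closed surface the divergence integrates to zero exactly; on chart
    sub-rectangles it obeys the discrete divergence theorem against
    :func:`patch_flux`.
    """
    V, F = surface.vertices, surface.faces
    if check_tangency:
        n_v = vertex_normals(V, F)
        t_err = np.abs(np.einsum("ij,ij->i", v_par, n_v))
        scale = max(np.abs(v_par).max(), 1e-12)
        if t_err.max() > 0.2 * scale:
            raise ValueError("input field has a large non-tangential component")
    fn = face_normals(V, F)
    fa = face_areas(V, F)
    vf = v_par[F].mean(axis=1)
    vf = vf - np.einsum("ij,ij->i", vf, fn)[:, None] * fn
    grads = _p1_hat_gradients(surface)
    contrib = -fa[:, None] * np.einsum("fj,fkj->fk", vf, grads)
    div = np.zeros(len(V))
    np.add.at(div, F.ravel(), contrib.ravel())
    return div / vertex_areas(V, F)


def patch_flux(
    v_par: np.ndarray, surface: TubeSurface, vertex_mask: np.ndarray
) -> float:
    """Discrete outward flux of ``v_par`` through the boundary of a vertex set.

    Defined through the same weak form as :func:`covariant_divergence`, so
    that ``sum_{i in patch} A_i div_i == patch_flux`` holds to machine
    precision (the discrete divergence theorem).
    """
    V, F = surface.vertices, surface.faces
    fn = face_normals(V, F)
    fa = face_areas(V, F)
    vf = v_par[F].mean(axis=1)
    vf = vf - np.einsum("ij,ij->i", vf, fn)[:, None] * fn
    grads = _p1_hat_gradients(surface)
    chi = vertex_mask.astype(float)[F]  # (m, 3)
    grad_chi = np.einsum("fk,fkj->fj", chi, grads)
    return float(-(fa * np.einsum("fj,fj->f", vf, grad_chi)).sum())


def incompressibility_fields(
    seq: SurfaceSequence,
    k: int,
    n_s_bins: int = 20,
    n_phi_bins: int = 16,
) -> pd.DataFrame:
    """Per-patch kinematic fields at timepoint ``k``.

    Vertices are binned on a rectangular (s, phi) chart grid; per-patch values
    are vertex-area-weighted means of H, v_n, div(v_par), the out-of-plane
    deformation ``oop = 2 H v_n``, the residual ``div - oop``, and an
    independent estimate of the relative area growth rate ``dlnA_dt`` from the
    change of vertex areas.  Boundary vertices (one-sided operators) are
    excluded.

    Columns: t, s_bin, phi_bin, area, H, vn, div, oop, residual, dlnA_dt.
    """
    surf = seq[k]
    surf.require_chart()
    field, mid = lagrangian_velocity(seq, k)
    H = mean_curvature(mid)
    div = covariant_divergence(field.v_par, mid, check_tangency=False)
    va_mid = vertex_areas(mid.vertices, mid.faces)

    k1 = k + 1 if k < len(seq) - 1 else k
    k0 = k if k < len(seq) - 1 else k - 1
    dt = seq.times[k1] - seq.times[k0]
    va0 = vertex_areas(seq[k0].vertices, seq[k0].faces)
    va1 = vertex_areas(seq[k1].vertices, seq[k1].faces)
    dlnA = (va1 - va0) / (dt * va_mid)

    interior = ~boundary_vertex_mask(surf.faces, surf.n_vertices)

    s, phi = surf.s, np.mod(surf.phi, 2 * np.pi)
    s_edges = np.linspace(s.min(), s.max(), n_s_bins + 1)
    p_edges = np.linspace(0.0, 2 * np.pi, n_phi_bins + 1)
    si = np.clip(np.digitize(s, s_edges) - 1, 0, n_s_bins - 1)
    pi_ = np.clip(np.digitize(phi, p_edges) - 1, 0, n_phi_bins - 1)

    rows = []
    for sb in range(n_s_bins):
        for pb in range(n_phi_bins):
            sel = (si == sb) & (pi_ == pb) & interior
            if not sel.any():
                raise ValueError(f"empty patch (s_bin={sb}, phi_bin={pb})")
            w = va_mid[sel]
            wsum = w.sum()
            mean = lambda x: float((x[sel] * w).sum() / wsum)  # noqa: E731
            dv = mean(div)
            # average the pointwise product: H and vn co-vary within a patch
            oop = mean(2.0 * H * field.vn)
            rows.append(
                {
                    "t": float(seq.times[k]),
                    "s_bin": sb,
                    "phi_bin": pb,
                    "area": float(wsum),
                    "H": mean(H),
                    "vn": mean(field.vn),
                    "div": dv,
                    "oop": oop,
                    "residual": dv - oop,
                    "dlnA_dt": mean(dlnA),
                }
            )
    return pd.DataFrame(rows)


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    """Weighted Pearson correlation and regression slope of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    w = w / w.sum()
    mx, my = (w * x).sum(), (w * y).sum()
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        raise ValueError("zero-variance field; correlation undefined")
    return cov / np.sqrt(vx * vy), cov / vx


def incompressibility_correlation(
    patches: pd.DataFrame, weighted: bool = True
) -> tuple[float, float]:
    """Pooled correlation between out-of-plane deformation and divergence.

    All (patch, timepoint) samples are pooled; with ``weighted=True`` each
    sample counts with its patch area.  Returns ``(pearson_r, slope)`` of
    ``oop = 2 H v_n`` against ``div v_par``.
    """
    w = patches["area"].to_numpy() if weighted else None
    r, slope = weighted_pearson(
        patches["div"].to_numpy(), patches["oop"].to_numpy(), w
    )
    return float(r), float(slope)


def metric_rate_check(
    flow,
    t: float,
    n_u: int = 512,
    dt_fd: float = 1e-3,
    margin: float = 0.05,
) -> float:
    """Max relative deviation of d(g_ij)/dt from 2*sym(grad v) - 2*vn*b_ij.

    Validates the metric-rate identity on the parametric axisymmetric flow,
    where the second fundamental form is available in closed form.  Only the
    diagonal components are nonzero by symmetry.  ``margin`` trims the ends of
    the material domain where one-sided numerical derivatives dominate.
    Returns the deviation normalized by the largest metric-rate magnitude.
    """
    spec = flow.spec
    u = np.linspace(margin * spec.L0, (1 - margin) * spec.L0, n_u)
    gp = flow.metric(t + dt_fd, u)
    gm = flow.metric(max(t - dt_fd, 0.0), u)
    denom = dt_fd + min(dt_fd, t)
    dg_uu = (gp[0] - gm[0]) / denom
    dg_pp = (gp[1] - gm[1]) / denom

    g_uu, g_pp = flow.metric(t, u)
    b_uu, b_pp = flow.second_fundamental_form(t, u)
    H, vn, _ = flow.analytic_fields(t, u)

    zu, zdot, rhodot = flow.marker_velocity(t, u)
    _, r_z, _, _ = flow.radius_derivs(zu, t)
    z_u = np.gradient(zu, u)
    # covariant velocity component v_u = v . X_u (v_phi = 0 by axisymmetry)
    v_u = z_u * (zdot + r_z * rhodot)
    gamma_uuu = np.gradient(g_uu, u) / (2.0 * g_uu)
    gamma_upp = -np.gradient(g_pp, u) / (2.0 * g_uu)
    nabla_u_v_u = np.gradient(v_u, u) - gamma_uuu * v_u
    nabla_p_v_p = -gamma_upp * v_u

    rhs_uu = 2.0 * nabla_u_v_u - 2.0 * vn * b_uu
    rhs_pp = 2.0 * nabla_p_v_p - 2.0 * vn * b_pp
    scale = max(np.abs(dg_uu).max(), np.abs(dg_pp).max(), 1e-300)
    dev = max(np.abs(dg_uu - rhs_uu).max(), np.abs(dg_pp - rhs_pp).max())
    return float(dev / scale)
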