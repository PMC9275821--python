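"""Synthetic inputs emulating light-sheet recordings of a folding gut tube.

Every input the analysis pipeline consumes can be generated here with known
ground truth: an axisymmetric tube developing localized constrictions under an
exactly area-preserving Lagrangian flow, circumferentially elongated cell
tessellations, paired nuclei tracks with slow relative drift, calcium movies
with transient localized pulses, and Bernoulli fold-outcome tables.

The constricting tube is the central fixture.  Its radius profile is a
Gaussian-necked surface of revolution

    r(z, t) = R0 - sum_j d_j(t) * exp(-(z - c_j)^2 / (2 w_j^2)),

and material markers move axially so that the local area element
``r * sqrt(1 + r_z^2) * dz/du`` is conserved per marker (solved by quadrature
and monotone inversion).  Because the flow preserves areas by construction,
the out-of-plane deformation ``2 H v_n`` equals the covariant divergence of
the in-plane velocity exactly, giving analytic oracle fields for the
incompressibility analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
import shapely.geometry as sgeom

from .geometry import SurfaceSequence, TubeSurface, face_normals

__all__ = [
    "Constriction",
    "TubeSpec",
    "CellFieldSpec",
    "PulseSpec",
    "ConstrictingTubeFlow",
    "AnalyticKinematics",
    "GeneratedCell",
    "CalciumStack",
    "make_constricting_tube",
    "make_sphere_sequence",
    "make_cell_tessellation",
    "make_nuclei_pairs",
    "make_calcium_movie",
    "make_fold_outcomes",
]


# ---------------------------------------------------------------------------
# constricting tube


@dataclass
class Constriction:
    """One Gaussian constriction: center (um), final depth (um), width (um).

    ``depth_profile`` maps time (min) to depth; the default ramps linearly
    from 0 to ``depth`` over the sequence duration (set when the flow is
    built).
    """

    center: float
    depth: float
    width: float
    depth_profile: Callable[[float], float] | None = None


@dataclass
class TubeSpec:
    R0: float = 30.0
    L0: float = 200.0
    constrictions: Sequence[Constriction] = field(default_factory=list)
    n_s: int = 64
    n_phi: int = 32
    dt: float = 1.0
    n_t: int = 30
    seed: int = 0
    area_growth_rate: float = 0.0  # relative area growth per minute

    def __post_init__(self) -> None:
        if self.n_s < 16 or self.n_phi < 16:
            raise ValueError("mesh resolution must satisfy n_s >= 16, n_phi >= 16")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for c in self.constrictions:
            if not (0 <= c.depth < self.R0):
                raise ValueError("constriction depth must satisfy 0 <= d < R0")
            if c.width <= 0:
                raise ValueError("constriction width must be positive")


@dataclass
class AnalyticKinematics:
    """Exact per-vertex kinematic fields of a parametric flow.

    ``div`` is the covariant divergence of the tangential velocity; for the
    area-preserving flow it equals ``2*H*vn`` plus any prescribed uniform
    area-growth rate.  ``residual = div - 2*H*vn``.
    """

    H: np.ndarray  # (n_t, n_vertices), 1/um
    vn: np.ndarray  # (n_t, n_vertices), um/min, positive inward
    div: np.ndarray  # (n_t, n_vertices), 1/min
    velocity: np.ndarray  # (n_t, n_vertices, 3), um/min

    @property
    def oop(self) -> np.ndarray:
        return 2.0 * self.H * self.vn

    @property
    def residual(self) -> np.ndarray:
        return self.div - self.oop


class ConstrictingTubeFlow:
    """Area-preserving Lagrangian flow on a constricting surface of revolution.

    The tube axis is x; material markers are labelled by their rest axial
    coordinate ``u`` in [0, L0].  The anterior end (u=0) is held fixed and the
    tube extends posteriorly as constrictions deepen.
    """

    def __init__(self, spec: TubeSpec, quad_points: int = 8192):
        self.spec = spec
        T = max((spec.n_t - 1) * spec.dt, spec.dt)
        self._profiles = []
        for c in spec.constrictions:
            if c.depth_profile is not None:
                self._profiles.append(c.depth_profile)
            else:
                d, ramp = c.depth, T
                self._profiles.append(lambda t, d=d, ramp=ramp: d * min(max(t, 0.0), ramp) / ramp)
        self._quad_points = quad_points
        # generous axial quadrature range: lost neck area must be made up
        extra = sum(3.0 * c.width + c.depth for c in spec.constrictions)
        self._z_max = 2.0 * spec.L0 + 4.0 * extra
        self.u = np.linspace(0.0, spec.L0, spec.n_s)

    # -- radius profile and closed-form derivatives -----------------------
    def depths(self, t: float) -> np.ndarray:
        return np.array([p(t) for p in self._profiles])

    def _gaussians(self, z: np.ndarray, t: float):
        spec = self.spec
        z = np.asarray(z, dtype=float)
        g = np.zeros_like(z)
        gz = np.zeros_like(z)
        gzz = np.zeros_like(z)
        for c, d in zip(spec.constrictions, self.depths(t)):
            x = (z - c.center) / c.width
            e = d * np.exp(-0.5 * x * x)
            g += e
            gz += -e * x / c.width
            gzz += e * (x * x - 1.0) / (c.width * c.width)
        return g, gz, gzz

    def radius(self, z, t: float):
        g, _, _ = self._gaussians(z, t)
        return self.spec.R0 - g

    def radius_derivs(self, z, t: float):
        """(r, r_z, r_zz, r_t) at fixed lab coordinate z."""
        g, gz, gzz = self._gaussians(z, t)
        eps = 1e-4 * max(self.spec.dt, 1e-6)
        gp, _, _ = self._gaussians(z, t + eps)
        gm, _, _ = self._gaussians(z, max(t - eps, 0.0))
        r_t = -(gp - gm) / (eps + min(eps, t))
        return self.spec.R0 - g, -gz, -gzz, r_t

    def growth_factor(self, t: float) -> float:
        return float(np.exp(self.spec.area_growth_rate * t))

    # -- quadrature / marker inversion ------------------------------------
    def _cumulative_area(self, t: float):
        """Fine grid z and cumulative area-per-radian Lambda(z, t)."""
        z = np.linspace(0.0, self._z_max, self._quad_points)
        r, r_z, _, _ = self.radius_derivs(z, t)
        if np.any(r <= 0):
            raise RuntimeError(
                f"neck closes (r <= 0) at time t={t:g} min; constriction too deep"
            )
        integrand = r * np.sqrt(1.0 + r_z * r_z)
        lam = np.concatenate([[0.0], np.cumsum((integrand[1:] + integrand[:-1]) * 0.5 * np.diff(z))])
        return z, lam

    def marker_positions(self, t: float, u: np.ndarray | None = None) -> np.ndarray:
        """Axial positions z(u, t) conserving the per-marker area element."""
        spec = self.spec
        if u is None:
            u = self.u
        z, lam = self._cumulative_area(t)
        target = self.growth_factor(t) * spec.R0 * np.asarray(u, dtype=float)
        if target.max() > lam[-1]:
            raise RuntimeError(
                f"quadrature range exhausted at time t={t:g} min; "
                "constriction too deep or too narrow for this domain"
            )
        return np.interp(target, lam, z)

    def marker_velocity(self, t: float, u: np.ndarray | None = None):
        """(z, zdot, rhodot): axial position/speed and radial speed per marker."""
        spec = self.spec
        if u is None:
            u = self.u
        u = np.asarray(u, dtype=float)
        zu = self.marker_positions(t, u)
        r, r_z, _, r_t = self.radius_derivs(zu, t)
        # Lambda_t by quadrature of the closed-form time derivative
        z, _ = self._cumulative_area(t)
        eps = 1e-3 * spec.dt
        rg_p, rz_p, _, _ = self.radius_derivs(z, t + eps)
        rg_m, rz_m, _, _ = self.radius_derivs(z, max(t - eps, 0.0))
        f_p = rg_p * np.sqrt(1.0 + rz_p**2)
        f_m = rg_m * np.sqrt(1.0 + rz_m**2)
        df = (f_p - f_m) / (eps + min(eps, t))
        lam_t = np.concatenate([[0.0], np.cumsum((df[1:] + df[:-1]) * 0.5 * np.diff(z))])
        lam_t_u = np.interp(zu, z, lam_t)
        gdot = self.spec.area_growth_rate * self.growth_factor(t)
        zdot = (gdot * spec.R0 * u - lam_t_u) / (r * np.sqrt(1.0 + r_z * r_z))
        rhodot = r_t + r_z * zdot
        return zu, zdot, rhodot

    # -- discrete-area-exact mesh markers ----------------------------------
    def _band_areas(self, z: np.ndarray, t: float) -> np.ndarray:
        """Discrete area of each ring band, per phi cell (two triangles)."""
        n_phi = self.spec.n_phi
        delta = 2.0 * np.pi / n_phi
        r = self.radius(z, t)
        z0, z1 = z[:-1], z[1:]
        r0, r1 = r[:-1], r[1:]
        cd, sd = np.cos(delta), np.sin(delta)
        A = np.column_stack([z0, r0, np.zeros_like(r0)])
        B = np.column_stack([z0, r0 * cd, r0 * sd])
        C = np.column_stack([z1, r1, np.zeros_like(r1)])
        D = np.column_stack([z1, r1 * cd, r1 * sd])
        t1 = 0.5 * np.linalg.norm(np.cross(B - A, C - A), axis=1)
        t2 = 0.5 * np.linalg.norm(np.cross(D - B, C - B), axis=1)
        return t1 + t2

    def mesh_marker_z(self, t: float) -> np.ndarray:
        """Marker positions refined so *discrete* band areas are conserved.

        Starts from the continuum quadrature solution and applies a few
        fixed-point sweeps matching the cumulative discrete band area to its
        (uniformly grown) initial value.
        """
        z = self.marker_positions(t)
        z0 = self.u
        target = self.growth_factor(t) * np.concatenate(
            [[0.0], np.cumsum(self._band_areas(z0, 0.0))]
        )
        ghost = np.linspace(1.0, 30.0, 8)
        for _ in range(100):
            zq = np.concatenate([z, z[-1] + ghost])  # extend past the tail
            cum = np.concatenate([[0.0], np.cumsum(self._band_areas(zq, t))])
            err = np.abs(cum[: len(z)] - target).max() / max(target[-1], 1e-300)
            if err < 1e-12:
                break
            znew = np.interp(target, cum, zq)
            znew[0] = z[0]
            z = znew
        return z

    def mesh_marker_velocity(self, t: float):
        """(z, zdot, rhodot) of the discrete-area-conserving markers."""
        eps = 1e-3 * self.spec.dt
        zp = self.mesh_marker_z(t + eps)
        zm = self.mesh_marker_z(max(t - eps, 0.0))
        zu = self.mesh_marker_z(t)
        zdot = (zp - zm) / (eps + min(eps, t))
        r, r_z, _, r_t = self.radius_derivs(zu, t)
        rhodot = r_t + r_z * zdot
        return zu, zdot, rhodot

    # -- analytic fields ---------------------------------------------------
    def analytic_fields(self, t: float, u: np.ndarray | None = None):
        """(H, vn, div) per marker; H in 1/um, rates in 1/min.

        Mean curvature of the surface of revolution with the inward normal
        convention; vn positive inward; div = 2*H*vn + growth rate because the
        flow preserves (or uniformly grows) the local area element.
        """
        if u is None:
            zu = self.mesh_marker_z(t)
        else:
            zu = self.marker_positions(t, u)
        r, r_z, r_zz, r_t = self.radius_derivs(zu, t)
        q = 1.0 + r_z * r_z
        H = 0.5 * (1.0 / (r * np.sqrt(q)) - r_zz / q**1.5)
        vn = -r_t / np.sqrt(q)
        div = 2.0 * H * vn + self.spec.area_growth_rate
        return H, vn, div

    def tangential_speed(self, t: float, u: np.ndarray | None = None):
        """Meridional tangential velocity component v_s per marker (um/min)."""
        if u is None:
            u = self.u
        zu, zdot, rhodot = self.marker_velocity(t, u)
        _, r_z, _, _ = self.radius_derivs(zu, t)
        q = np.sqrt(1.0 + r_z * r_z)
        return (zdot + r_z * rhodot) / q

    def divergence_by_flux(self, t: float, u: np.ndarray | None = None):
        """Independent covariant divergence: (1/r) d(r v_s)/d(arc length).

        Computed by numerical differentiation in the material coordinate; used
        as an oracle against the area-conservation construction.
        """
        if u is None:
            u = self.u
        u = np.asarray(u, dtype=float)
        zu = self.marker_positions(t, u)
        r, r_z, _, _ = self.radius_derivs(zu, t)
        v_s = self.tangential_speed(t, u)
        # arc length along the meridian at fixed t
        ell = np.concatenate(
            [[0.0], np.cumsum(np.hypot(np.diff(zu), np.diff(r)))]
        )
        return np.gradient(r * v_s, ell) / r

    # -- metric and curvature tensor (validation of the metric-rate identity)
    def metric(self, t: float, u: np.ndarray | None = None):
        """Induced metric components (g_uu, g_pp) in (u, phi) coordinates."""
        if u is None:
            u = self.u
        u = np.asarray(u, dtype=float)
        zu = self.marker_positions(t, u)
        r, r_z, _, _ = self.radius_derivs(zu, t)
        z_u = np.gradient(zu, u)
        g_uu = z_u * z_u * (1.0 + r_z * r_z)
        g_pp = r * r
        return g_uu, g_pp

    def second_fundamental_form(self, t: float, u: np.ndarray | None = None):
        """(b_uu, b_pp) with the inward normal, so b_pp = r / sqrt(1+r_z^2) > 0."""
        if u is None:
            u = self.u
        u = np.asarray(u, dtype=float)
        zu = self.marker_positions(t, u)
        r, r_z, r_zz, _ = self.radius_derivs(zu, t)
        z_u = np.gradient(zu, u)
        q = 1.0 + r_z * r_z
        b_uu = -z_u * z_u * r_zz / np.sqrt(q)
        b_pp = r / np.sqrt(q)
        return b_uu, b_pp

    # -- meshing ------------------------------------------------------------
    def surface(self, t: float) -> TubeSurface:
        spec = self.spec
        zu = self.mesh_marker_z(t)
        r = self.radius(zu, t)
        phi = 2.0 * np.pi * np.arange(spec.n_phi) / spec.n_phi
        Z, PHI = np.meshgrid(zu, phi, indexing="ij")
        R, _ = np.meshgrid(r, phi, indexing="ij")
        verts = np.column_stack(
            [Z.ravel(), (R * np.cos(PHI)).ravel(), (R * np.sin(PHI)).ravel()]
        )
        faces = _cylinder_grid_faces(spec.n_s, spec.n_phi)
        s_chart = np.repeat(self.u, spec.n_phi)
        phi_chart = np.tile(phi, spec.n_s)
        surf = TubeSurface(verts, faces, s=s_chart, phi=phi_chart)
        return _orient_inward_axis(surf)

    def sample_sequence(self) -> tuple[SurfaceSequence, AnalyticKinematics]:
        spec = self.spec
        times = np.arange(spec.n_t) * spec.dt
        surfaces, H, vn, div, vel = [], [], [], [], []
        for t in times:
            try:
                surfaces.append(self.surface(float(t)))
                h, v, d = self.analytic_fields(float(t))
                zu, zdot, rhodot = self.mesh_marker_velocity(float(t))
            except RuntimeError as err:
                raise RuntimeError(f"tube generation failed at timestep t={t:g} min: {err}") from err
            phi = surfaces[-1].phi
            H.append(np.repeat(h, spec.n_phi))
            vn.append(np.repeat(v, spec.n_phi))
            div.append(np.repeat(d, spec.n_phi))
            zd = np.repeat(zdot, spec.n_phi)
            rd = np.repeat(rhodot, spec.n_phi)
            vel.append(np.column_stack([zd, rd * np.cos(phi), rd * np.sin(phi)]))
        seq = SurfaceSequence(surfaces, times)
        fields = AnalyticKinematics(
            H=np.array(H), vn=np.array(vn), div=np.array(div), velocity=np.array(vel)
        )
        return seq, fields


def _cylinder_grid_faces(n_s: int, n_phi: int) -> np.ndarray:
    faces = []
    for i in range(n_s - 1):
        for j in range(n_phi):
            a = i * n_phi + j
            b = i * n_phi + (j + 1) % n_phi
            c = (i + 1) * n_phi + j
            d = (i + 1) * n_phi + (j + 1) % n_phi
            faces.append([a, b, c])
            faces.append([b, d, c])
    return np.asarray(faces, dtype=np.int64)


def _orient_inward_axis(surface: TubeSurface) -> TubeSurface:
    """Flip face winding if normals point away from the x-axis."""
    V, F = surface.vertices, surface.faces
    n = face_normals(V, F)
    cent = V[F].mean(axis=1)
    radial = cent.copy()
    radial[:, 0] = 0.0
    nr = np.linalg.norm(radial, axis=1)
    nr[nr == 0] = 1.0
    score = np.mean(np.einsum("ij,ij->i", n, radial / nr[:, None]))
    if score > 0:
        surface.faces = F[:, [0, 2, 1]]
    return surface


def make_constricting_tube(spec: TubeSpec):
    """Generate the area-preserving constricting-tube sequence.

    Returns ``(sequence, analytic_fields, flow)``: the Lagrangian mesh time
    series, the exact per-vertex kinematic fields, and the parametric flow
    object (usable to evaluate the geometry at arbitrary times).
    """
    flow = ConstrictingTubeFlow(spec)
    seq, fields = flow.sample_sequence()
    return seq, fields, flow


# ---------------------------------------------------------------------------
# sphere sequence (analytic oracle for normal-motion kinematics)


def make_sphere_sequence(
    radius_of_t: Callable[[float], float],
    n_t: int,
    dt: float = 1.0,
    subdivisions: int = 3,
) -> tuple[SurfaceSequence, AnalyticKinematics]:
    """Sphere R(t) moving purely normally; div of tangential velocity is 0.

    The residual ``div - 2*H*vn`` therefore equals the relative area growth
    rate ``d ln A / dt = 2 Rdot / R``.
    """
    import trimesh

    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    unit = np.asarray(base.vertices)
    faces = np.asarray(base.faces)[:, [0, 2, 1]]  # flip: normals inward
    times = np.arange(n_t) * dt
    surfaces, H, vn, div, vel = [], [], [], [], []
    eps = 1e-5 * max(dt, 1e-9)
    for t in times:
        R = float(radius_of_t(float(t)))
        if R <= 0:
            raise ValueError(f"radius must stay positive; R({t})={R}")
        Rdot = (radius_of_t(float(t) + eps) - radius_of_t(max(float(t) - eps, 0.0))) / (
            eps + min(eps, float(t))
        )
        surfaces.append(TubeSurface(unit * R, faces))
        n = len(unit)
        H.append(np.full(n, 1.0 / R))
        vn.append(np.full(n, -Rdot))  # inward positive
        div.append(np.zeros(n))
        vel.append(unit * Rdot)
    seq = SurfaceSequence(surfaces, times)
    fields = AnalyticKinematics(
        H=np.array(H), vn=np.array(vn), div=np.array(div), velocity=np.array(vel)
    )
    return seq, fields


# ---------------------------------------------------------------------------
# cell tessellations


@dataclass
class CellFieldSpec:
    n_cells: int = 600
    mean_area: float | None = None  # um^2; derived from surface area if None
    aspect_profile: Callable[[float], float] | float = 2.5
    orientation: float = 0.0  # radians from the circumferential axis
    jitter: float = 0.1
    seed: int = 0

    def profile(self, s: float | np.ndarray) -> np.ndarray:
        if callable(self.aspect_profile):
            return np.asarray(self.aspect_profile(s), dtype=float)
        return np.full_like(np.asarray(s, dtype=float), float(self.aspect_profile))


@dataclass
class GeneratedCell:
    """A generated cell polygon in chart coordinates with its ground truth."""

    cell_id: int
    polygon_chart: np.ndarray  # (k, 2) columns (s, phi)
    target_aspect: float
    target_orientation: float


def _hex_voronoi_polygons(
    xi_lo: float,
    xi_hi: float,
    period: float,
    h: float,
    jitter: float,
    rng: np.random.Generator,
):
    """Jittered hexagonal-lattice Voronoi cells on a periodic strip.

    The strip is [xi_lo, xi_hi] x [0, period), periodic in the second axis.
    Returns closed polygons (isotropic, area ~ h^2 sqrt(3)/2) for the seeds
    of the central periodic copy, closed at the xi boundaries by mirroring.
    """
    dxi = h * np.sqrt(3.0) / 2.0
    seeds = []
    xi = xi_lo + 0.5 * dxi
    col = 0
    while xi < xi_hi:
        n_eta = max(int(round(period / h)), 1)
        d_eta = period / n_eta
        off = 0.5 * d_eta if col % 2 else 0.0
        etas = np.mod((np.arange(n_eta) + 0.5) * d_eta + off, period)
        pts = np.column_stack([np.full(n_eta, xi), etas])
        pts += rng.normal(0.0, jitter * h, pts.shape)
        pts[:, 1] = np.mod(pts[:, 1], period)
        seeds.append(pts)
        xi += dxi
        col += 1
    pts = np.vstack(seeds)
    keep = (pts[:, 0] > xi_lo) & (pts[:, 0] < xi_hi)
    pts = pts[keep]
    n_central = len(pts)
    tiled = np.vstack([pts + np.array([0.0, k * period]) for k in (0, -1, 1)])
    mirror_lo = tiled.copy()
    mirror_lo[:, 0] = 2 * xi_lo - mirror_lo[:, 0]
    mirror_hi = tiled.copy()
    mirror_hi[:, 0] = 2 * xi_hi - mirror_hi[:, 0]
    vor = Voronoi(np.vstack([tiled, mirror_lo, mirror_hi]))
    polys = []
    for cid in range(n_central):
        region = vor.regions[vor.point_region[cid]]
        if -1 in region or len(region) < 3:
            continue
        polys.append((cid, vor.vertices[region]))
    return polys


def make_cell_tessellation(
    spec: CellFieldSpec, surface: TubeSurface
) -> list[GeneratedCell]:
    """Anisotropic Voronoi tessellation of the chart, periodic in phi.

    An isotropic jittered hexagonal Voronoi tessellation is built in an
    auxiliary space and mapped into the physical chart by an area-controlled
    anisotropic stretch, so each cell elongates by the local target aspect
    ratio along the circumferential axis (Voronoi cells themselves do not
    survive anisotropic scaling of their seeds, so the polygons are mapped,
    not the seeds).  With ``orientation != 0`` the stretch axes are rotated
    and seam periodicity becomes approximate (cells are clipped at the
    chart boundary).  Polygons are returned in chart coordinates (s, phi).
    """
    surface.require_chart()
    rng = np.random.default_rng(spec.seed)
    s_lo, s_hi = float(surface.s.min()), float(surface.s.max())
    L = s_hi - s_lo
    # effective radius from the (near-cylindrical) surface area
    from .geometry import surface_area as _area

    R_eff = _area(surface) / (2.0 * np.pi * L)
    W = 2.0 * np.pi * R_eff
    total = L * W
    mean_area = spec.mean_area if spec.mean_area is not None else total / spec.n_cells
    if spec.n_cells * mean_area > 1.1 * total:
        raise ValueError(
            f"n_cells={spec.n_cells} with mean_area={mean_area:.1f} um^2 "
            f"exceeds the chart area {total:.1f} um^2"
        )
    h = float(np.sqrt(2.0 * mean_area / np.sqrt(3.0)))
    grid = np.linspace(s_lo, s_hi, 512)
    prof = np.clip(spec.profile(grid), 1.0, None)
    A_bar = float(prof.mean())

    cells: list[GeneratedCell] = []
    if spec.orientation == 0.0:
        # periodic-exact branch: warp the longitudinal axis so that the local
        # (circumferential / longitudinal) extent ratio equals the profile
        xi_grid = np.concatenate(
            [[0.0], np.cumsum((prof[1:] + prof[:-1]) / 2.0 * np.diff(grid))]
        ) / np.sqrt(A_bar)
        period = W / np.sqrt(A_bar)
        polys = _hex_voronoi_polygons(
            0.0, float(xi_grid[-1]), period, h, spec.jitter, rng
        )
        box = sgeom.box(s_lo, -0.6 * W, s_hi, 1.6 * W)
        for cid, poly_xi in polys:
            x = np.interp(poly_xi[:, 0], xi_grid, grid)  # inverse warp
            y = poly_xi[:, 1] * np.sqrt(A_bar)
            cells.append(_finish_cell(cid, x, y, box, R_eff, spec))
    else:
        # rotated linear stretch; periodicity across the seam is approximate
        e = np.array([np.sin(spec.orientation), np.cos(spec.orientation)])
        ep = np.array([-e[1], e[0]])
        M = (
            np.sqrt(A_bar) * np.outer(e, e)
            + (1.0 / np.sqrt(A_bar)) * np.outer(ep, ep)
        )
        Minv = np.linalg.inv(M)
        corners = np.array(
            [[s_lo, -0.1 * W], [s_hi, -0.1 * W], [s_lo, 1.1 * W], [s_hi, 1.1 * W]]
        ) @ Minv.T
        xi_lo, xi_hi = corners[:, 0].min(), corners[:, 0].max()
        span = corners[:, 1].max() - corners[:, 1].min()
        polys = _hex_voronoi_polygons(
            float(xi_lo), float(xi_hi), float(span), h, spec.jitter, rng
        )
        shift = corners[:, 1].min()
        box = sgeom.box(s_lo, -0.1 * W, s_hi, 1.1 * W)
        for cid, poly_xi in polys:
            p = (poly_xi + np.array([0.0, shift])) @ M.T
            cells.append(_finish_cell(cid, p[:, 0], p[:, 1], box, R_eff, spec))
    return [c for c in cells if c is not None]


def _finish_cell(cid, x, y, box, R_eff, spec: CellFieldSpec):
    poly = sgeom.Polygon(np.column_stack([x, y]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    poly = poly.intersection(box)
    if poly.is_empty or poly.geom_type != "Polygon" or poly.area < 1e-9:
        return None
    xy = np.asarray(poly.exterior.coords)[:-1]
    s_c = float(xy[:, 0].mean())
    return GeneratedCell(
        cell_id=cid,
        polygon_chart=np.column_stack([xy[:, 0], xy[:, 1] / R_eff]),
        target_aspect=float(np.atleast_1d(spec.profile(s_c))[0]),
        target_orientation=spec.orientation,
    )


# ---------------------------------------------------------------------------
# nuclei pair tracks


def make_nuclei_pairs(
    n_pairs: int,
    drift_rate: float,
    duration: float,
    seed: int,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    flow: ConstrictingTubeFlow | None = None,
) -> pd.DataFrame:
    """Paired muscle/endoderm nuclei tracks with slow relative drift.

    Each pair rides the (shared) tissue motion of a constricting tube; the
    partner separates from its mate at ``drift_rate`` um/h along a fixed
    random direction, starting below the 5 um pairing threshold.  Tracking
    noise is isotropic Gaussian per timepoint.

    Returns a tidy table (pair_id, layer, t, x, y, z).
    """
    if drift_rate < 0:
        raise ValueError("drift_rate must be >= 0")
    rng = np.random.default_rng(seed)
    if flow is None:
        spec = TubeSpec(
            R0=30.0,
            L0=200.0,
            constrictions=[Constriction(center=100.0, depth=18.0, width=15.0)],
            n_s=64,
            n_phi=32,
            dt=dt,
            n_t=max(int(round(duration / dt)) + 1, 2),
        )
        flow = ConstrictingTubeFlow(spec)
    spec = flow.spec
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    u = rng.uniform(0.05 * spec.L0, 0.95 * spec.L0, n_pairs)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_pairs)
    sep0 = rng.uniform(1.0, 4.0, n_pairs)
    direction = rng.normal(size=(n_pairs, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)

    rows = []
    for t in times:
        z = flow.marker_positions(float(t), u)
        r = flow.radius(z, float(t))
        base = np.column_stack([z, r * np.cos(phi), r * np.sin(phi)])
        sep = sep0 + drift_rate * t / 60.0
        endo = base + rng.normal(0.0, noise_sd, base.shape)
        musc = base + direction * sep[:, None] + rng.normal(0.0, noise_sd, base.shape)
        for pid in range(n_pairs):
            rows.append((pid, "endoderm", t, *endo[pid]))
            rows.append((pid, "muscle", t, *musc[pid]))
    return pd.DataFrame(rows, columns=["pair_id", "layer", "t", "x", "y", "z"])


# ---------------------------------------------------------------------------
# calcium movies


@dataclass
class PulseSpec:
    frame_shape: tuple[int, int] = (64, 128)  # (circumferential, AP) pixels
    n_frames: int = 60  # total frames (3 per composite period)
    triplet_interval: float = 9.0  # seconds between frames of a triplet
    composite_period: float = 90.0  # seconds between triplets
    pulse_centers: Sequence[float] = (64.0,)  # AP positions, um
    pulse_rate: float = 2.0  # pulses per minute
    amplitude: float = 100.0
    duration: int = 1  # frames a pulse persists
    background_level: float = 20.0
    noise_sd: float = 2.0
    pixel_size: float = 1.0  # um per pixel
    blob_sigma: float = 3.0  # px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.duration < 1:
            raise ValueError("duration must be >= 1 frame")
        if not (9.0 <= self.triplet_interval <= 10.0):
            raise ValueError("triplet_interval must lie in [9, 10] s")
        if self.n_frames % 3:
            raise ValueError("n_frames must be a multiple of 3 (triplets)")


@dataclass
class CalciumStack:
    """Ordered max-projection frames grouped in triplets.

    ``ap_axis`` names the image axis (0=rows, 1=columns) running along the
    anterior-posterior direction; the other axis is circumferential.
    ``t0`` is the constriction-onset alignment time in minutes.
    """

    frames: np.ndarray  # (n_frames, ny, nx)
    triplet_interval: float
    composite_period: float
    pixel_size: float
    ap_axis: int = 1
    t0: float = 0.0

    @property
    def n_triplets(self) -> int:
        return self.frames.shape[0] // 3

    def triplet(self, k: int) -> np.ndarray:
        return self.frames[3 * k : 3 * k + 3]

    def triplet_times(self) -> np.ndarray:
        """Time of each triplet in minutes, relative to recording start."""
        return np.arange(self.n_triplets) * self.composite_period / 60.0


def make_calcium_movie(spec: PulseSpec) -> tuple[CalciumStack, pd.DataFrame]:
    """Noisy background movie with transient localized pulses.

    Pulse events are Poisson in time at the configured rate, placed at the
    given AP centers (jittered by the blob width) and random circumferential
    positions, each lasting ``duration`` frames.  Returns the stack and the
    ground-truth pulse table (frame, ap_px, circ_px, amplitude).
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.frame_shape
    frames = spec.background_level + rng.normal(
        0.0, spec.noise_sd, (spec.n_frames, ny, nx)
    )
    total_min = spec.n_frames / 3.0 * spec.composite_period / 60.0
    n_pulses = rng.poisson(spec.pulse_rate * total_min)
    yy, xx = np.mgrid[0:ny, 0:nx]
    truth = []
    for _ in range(n_pulses):
        f0 = rng.integers(0, spec.n_frames)
        center = rng.choice(np.asarray(spec.pulse_centers)) / spec.pixel_size
        cx = center + rng.normal(0.0, spec.blob_sigma)
        cy = rng.uniform(0, ny)
        blob = np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * spec.blob_sigma**2)
        )
        for f in range(f0, min(f0 + spec.duration, spec.n_frames)):
            frames[f] += spec.amplitude * blob
        truth.append((int(f0), float(cx), float(cy), spec.amplitude))
    table = pd.DataFrame(truth, columns=["frame", "ap_px", "circ_px", "amplitude"])
    stack = CalciumStack(
        frames=frames,
        triplet_interval=spec.triplet_interval,
        composite_period=spec.composite_period,
        pixel_size=spec.pixel_size,
        ap_axis=1,
    )
    return stack, table


# ---------------------------------------------------------------------------
# fold outcomes


def make_fold_outcomes(
    p_true: float, N: int, seed: int, condition: str = "wt"
) -> pd.DataFrame:
    """Bernoulli fold-outcome table: each embryo forms all 3 folds w.p. p_true.

    Unsuccessful embryos form 0-2 folds (uniformly).  Columns: embryo,
    condition, folds, success.
    """
    if not (0.0 <= p_true <= 1.0):
        raise ValueError("p_true must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    success = rng.random(N) < p_true
    folds = np.where(success, 3, rng.integers(0, 3, N))
    return pd.DataFrame(
        {
            "embryo": np.arange(N),
            "condition": condition,
            "folds": folds,
            "success": success,
        }
    )
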