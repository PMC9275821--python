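"""Cell-scale measurements: shape tensors, rearrangements, layer coupling.

Segmented cell polygons live in the chart plane of a tube surface.  Each
polygon is embedded into 3D through the surface's chart, projected onto the
local tangent plane spanned by the (s_hat, phi_hat) frame at its centroid,
and summarized by the second-moment-of-area (shape) tensor.  Its eigenvalues
``I1 >= I2`` give the cell aspect ratio ``a/b = sqrt(I1/I2)`` and the
orientation ``theta`` of the long axis relative to the longitudinal
direction.

Population statistics are area-weighted:

    <a/b>   = sum_i A_i (a_i/b_i) / sum_i A_i
    <theta> = atan2(sum_i A_i sin(theta_i), sum_i A_i cos(theta_i))

with standard errors from a subsample-size-extrapolated bootstrap.  The
module also detects T1 neighbor exchanges from adjacency time series,
tracks cell areas, quantifies relative motion of muscle-endoderm nuclei
pairs, and compares cell-scale anisotropy with tissue-scale shear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
from scipy.spatial import cKDTree
from scipy.stats import binomtest

from . import stats as tkstats
from .geometry import TubeSurface, face_chart_coords, tangent_directions

__all__ = [
    "CellShapeRecord",
    "ChartLocator",
    "embed_and_measure",
    "measure_cells",
    "polygon_shape_tensor",
    "weighted_mean_aspect",
    "weighted_mean_orientation",
    "bootstrap_se",
    "plain_bootstrap_se",
    "track_cell_areas",
    "NeighborGraph",
    "T1Event",
    "detect_t1_events",
    "t1_orientation_bias",
    "cellshape_vs_tissue_shear",
    "nuclei_pair_motion",
    "group_anisotropy_comparison",
]


@dataclass
class CellShapeRecord:
    cell_id: int
    time: float
    polygon_2d: np.ndarray  # chart coordinates (s, phi)
    polygon_3d: np.ndarray  # embedded vertices (k, 3)
    centroid_3d: np.ndarray
    area: float  # um^2, measured in the tangent plane
    I1: float
    I2: float
    aspect: float  # a/b = sqrt(I1/I2) >= 1
    theta: float  # radians in (-pi/2, pi/2], long axis vs s_hat
    s: float  # centroid longitudinal coordinate


# ---------------------------------------------------------------------------
# polygon moments


def polygon_shape_tensor(xy: np.ndarray):
    """Area, centroid and second-moment-of-area tensor of a simple polygon.

    The tensor is ``S = (1/A) integral (r - c)(r - c)^T dA`` over the polygon
    (the normalized second moment about the centroid); computed with the
    shoelace-based closed forms, orientation-independent.
    """
    x, y = xy[:, 0], xy[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = 0.5 * cross.sum()
    if A == 0:
        raise ValueError("degenerate polygon with zero area")
    cx = ((x + x1) * cross).sum() / (6.0 * A)
    cy = ((y + y1) * cross).sum() / (6.0 * A)
    sxx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    syy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    sxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    sign = np.sign(A)
    A = abs(A)
    sxx, syy, sxy = sign * sxx, sign * syy, sign * sxy
    S = np.array(
        [
            [sxx / A - cx * cx, sxy / A - cx * cy],
            [sxy / A - cx * cy, syy / A - cy * cy],
        ]
    )
    return A, np.array([cx, cy]), S


def _shape_from_tensor(S: np.ndarray):
    """(I1, I2, aspect, theta) from a 2x2 shape tensor; theta of I1 axis."""
    evals, evecs = np.linalg.eigh(S)
    I2, I1 = float(evals[0]), float(evals[1])
    v = evecs[:, 1]
    theta = float(np.arctan2(v[1], v[0]))
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    aspect = float(np.sqrt(I1 / I2)) if I2 > 0 else np.inf
    return I1, I2, aspect, theta


# ---------------------------------------------------------------------------
# chart point location and embedding


class ChartLocator:
    """Locate chart points in a surface's (s, phi) triangulation.

    Candidate faces come from a KD-tree over face chart centroids; the face
    maximizing the smallest barycentric coordinate wins.  Queries are tried
    at phi, phi-2*pi and phi+2*pi to handle the periodic seam.
    """

    def __init__(self, surface: TubeSurface):
        surface.require_chart()
        self.surface = surface
        self.fc = face_chart_coords(surface)  # (m, 3, 2)
        self._tree = cKDTree(self.fc.mean(axis=1))
        self._shat, self._phihat = tangent_directions(surface)

    def locate(self, pts: np.ndarray, k: int = 16):
        """(face_index, barycentric) for each (s, phi) query point."""
        pts = np.atleast_2d(pts)
        out_f = np.empty(len(pts), dtype=np.int64)
        out_b = np.empty((len(pts), 3))
        shifts = np.array([0.0, -2 * np.pi, 2 * np.pi])
        for i, p in enumerate(pts):
            best_score, best = -np.inf, None
            for sh in shifts:
                q = np.array([p[0], p[1] + sh])
                _, idx = self._tree.query(q, k=min(k, len(self.fc)))
                idx = np.atleast_1d(idx)
                tri = self.fc[idx]  # (k, 3, 2)
                b = _barycentric(tri, q)
                scores = b.min(axis=1)
                j = int(np.argmax(scores))
                if scores[j] > best_score:
                    best_score = float(scores[j])
                    best = (int(idx[j]), b[j])
            out_f[i] = best[0]
            out_b[i] = best[1]
        return out_f, out_b

    def embed(self, pts: np.ndarray) -> np.ndarray:
        """Map chart points to 3D positions on the surface."""
        f, b = self.locate(pts)
        tri = self.surface.vertices[self.surface.faces[f]]  # (k, 3, 3)
        return np.einsum("kj,kji->ki", b, tri)

    def frame_at(self, pt: np.ndarray):
        """Orthonormal tangent frame (s_hat, phi_hat) at a chart point."""
        f, _ = self.locate(np.atleast_2d(pt))
        return self._shat[f[0]], self._phihat[f[0]]


def _barycentric(tri: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of point p in each 2D triangle of ``tri``."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0, v1, v2 = b - a, c - a, p[None, :] - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    den = d00 * d11 - d01 * d01
    den = np.where(np.abs(den) < 1e-300, np.nan, den)
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    u = 1.0 - v - w
    out = np.stack([u, v, w], axis=-1)
    return np.where(np.isfinite(out), out, -np.inf)


def _unwrap_polygon_phi(poly: np.ndarray) -> np.ndarray:
    out = poly.copy()
    out[:, 1] = np.unwrap(out[:, 1])
    return out


def embed_and_measure(
    polygon_2d: np.ndarray,
    surface: TubeSurface,
    locator: ChartLocator | None = None,
    cell_id: int = -1,
    time: float = 0.0,
) -> CellShapeRecord:
    """Embed one chart polygon on the surface and measure its shape tensor.

    The polygon is embedded vertex-by-vertex, projected on the tangent plane
    of the face under its chart centroid (x along s_hat, y along phi_hat),
    and measured there.  ``theta`` is the angle of the long axis from s_hat.
    """
    poly = _unwrap_polygon_phi(np.asarray(polygon_2d, dtype=float))
    sp = sgeom.Polygon(poly)
    if not sp.is_valid or not sp.is_simple:
        raise ValueError(f"self-intersecting polygon for cell_id={cell_id}")
    if locator is None:
        locator = ChartLocator(surface)
    p3 = locator.embed(poly)
    centroid_chart = poly.mean(axis=0)
    shat, phihat = locator.frame_at(centroid_chart)
    c0 = p3.mean(axis=0)
    xy = np.column_stack([(p3 - c0) @ shat, (p3 - c0) @ phihat])
    A, c2, S = polygon_shape_tensor(xy)
    I1, I2, aspect, theta = _shape_from_tensor(S)
    centroid_3d = c0 + c2[0] * shat + c2[1] * phihat
    return CellShapeRecord(
        cell_id=cell_id,
        time=time,
        polygon_2d=np.asarray(polygon_2d, dtype=float),
        polygon_3d=p3,
        centroid_3d=centroid_3d,
        area=A,
        I1=I1,
        I2=I2,
        aspect=aspect,
        theta=theta,
        s=float(centroid_chart[0]),
    )


def measure_cells(
    polygons, surface: TubeSurface, time: float = 0.0
) -> list[CellShapeRecord]:
    """Measure a batch of chart polygons on one surface.

    ``polygons`` is an iterable of ``(cell_id, polygon_2d)`` pairs or of
    generated cells with ``cell_id``/``polygon_chart`` attributes.
    """
    locator = ChartLocator(surface)
    records = []
    for item in polygons:
        if hasattr(item, "polygon_chart"):
            cid, poly = item.cell_id, item.polygon_chart
        else:
            cid, poly = item
        records.append(
            embed_and_measure(poly, surface, locator, cell_id=cid, time=time)
        )
    return records


# ---------------------------------------------------------------------------
# population statistics


def _areas_values(records, attr: str):
    A = np.array([r.area for r in records], dtype=float)
    x = np.array([getattr(r, attr) for r in records], dtype=float)
    if len(A) == 0:
        raise ValueError("no records")
    if np.all(A == 0):
        raise ValueError("all-zero cell areas")
    return A, x


def weighted_mean_aspect(records) -> float:
    """Area-weighted mean aspect ratio <a/b> = sum(A_i a_i/b_i) / sum(A_i)."""
    A, x = _areas_values(records, "aspect")
    return float((A * x).sum() / A.sum())


def weighted_mean_orientation(records, axial: bool = False) -> float:
    """Area-weighted mean orientation via the weighted vector sum.

    ``<theta> = atan2(sum A_i sin(theta_i), sum A_i cos(theta_i))``.  With
    ``axial=True`` the angles are doubled before averaging and halved after
    (axial statistics; orientations theta and theta+pi identified), which is
    the appropriate treatment for undirected cell axes.
    """
    A, th = _areas_values(records, "theta")
    if axial:
        m = np.arctan2((A * np.sin(2 * th)).sum(), (A * np.cos(2 * th)).sum())
        return float(m / 2.0)
    return float(np.arctan2((A * np.sin(th)).sum(), (A * np.cos(th)).sum()))


def bootstrap_se(
    values,
    weights=None,
    n_boot: int = 1000,
    n_sizes: int = 50,
    seed: int = 0,
) -> float:
    """Standard error of the weighted mean by subsample-size extrapolation.

    Subsamples of size n (with replacement) are drawn for 50 sizes in
    (N/4, N); the variance of the subsample means is fit as
    ``var(n) = a/n + c`` by least squares in 1/n, and the SE is the square
    root of the fit evaluated at n = N.  The intercept absorbs variance that
    does not shrink with subsample size.
    """
    x = np.asarray(values, dtype=float)
    N = len(x)
    if N < 8:
        raise ValueError("need at least 8 samples to extrapolate a bootstrap SE")
    w = np.ones(N) if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    sizes = np.unique(
        np.round(np.linspace(N // 4 + 1, N, n_sizes)).astype(int)
    )
    inv_n, var = [], []
    for n in sizes:
        idx = rng.integers(0, N, size=(n_boot, n))
        means = (w[idx] * x[idx]).sum(axis=1) / w[idx].sum(axis=1)
        inv_n.append(1.0 / n)
        var.append(means.var())
    coeffs = np.polyfit(inv_n, var, 1)  # var = a * (1/n) + c
    se2 = float(np.polyval(coeffs, 1.0 / N))
    return float(np.sqrt(max(se2, 0.0)))


def plain_bootstrap_se(values, weights=None, n_boot: int = 1000, seed: int = 0) -> float:
    """SD of N-out-of-N bootstrap weighted means (the classical estimate)."""
    x = np.asarray(values, dtype=float)
    N = len(x)
    w = np.ones(N) if weights is None else np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, N, size=(n_boot, N))
    means = (w[idx] * x[idx]).sum(axis=1) / w[idx].sum(axis=1)
    return float(means.std())


# ---------------------------------------------------------------------------
# area tracking


def track_cell_areas(records) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-track area time series and the population mean/SD per timepoint.

    Records must be tracked (same ``cell_id`` = same cell over time).  Gaps
    in a track are tolerated and flagged in the per-track table; duplicate
    (cell, time) entries are an error.
    """
    df = pd.DataFrame(
        [(r.cell_id, r.time, r.area) for r in records],
        columns=["cell_id", "t", "area"],
    )
    if df.duplicated(["cell_id", "t"]).any():
        dup = df[df.duplicated(["cell_id", "t"])].iloc[0]
        raise ValueError(
            f"duplicate record for cell {int(dup.cell_id)} at t={dup.t}"
        )
    times = np.sort(df["t"].unique())
    counts = df.groupby("cell_id")["t"].count()
    df = df.sort_values(["cell_id", "t"]).reset_index(drop=True)
    df["has_gaps"] = df["cell_id"].map(counts < len(times))
    pop = (
        df.groupby("t")["area"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return df, pop


# ---------------------------------------------------------------------------
# T1 transitions


@dataclass
class NeighborGraph:
    """Cell adjacency over time plus centroids for event geometry.

    ``adjacency[t]`` is a set of frozenset cell-id pairs sharing an edge at
    time ``t``; ``centroids[(cell_id, t)]`` is the 2D centroid in a locally
    conformal patch whose first axis is AP.
    """

    times: np.ndarray
    adjacency: dict
    centroids: dict

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for t in self.times:
            for pair in self.adjacency.get(float(t), set()):
                for c in pair:
                    if (c, float(t)) not in self.centroids:
                        raise ValueError(
                            f"adjacency references cell {c} without centroid at t={t}"
                        )

    @classmethod
    def from_polygons(cls, polys_by_time: dict, min_shared: float = 1e-6):
        """Build adjacency from chart polygons: cells sharing a boundary arc.

        ``polys_by_time[t]`` maps cell_id -> (k, 2) polygon.  Two cells are
        neighbors when their boundaries overlap along a segment longer than
        ``min_shared``.
        """
        times = np.array(sorted(polys_by_time))
        adjacency, centroids = {}, {}
        for t in times:
            polys = {
                c: sgeom.Polygon(p) for c, p in polys_by_time[t].items()
            }
            for c, p in polys.items():
                centroids[(c, float(t))] = np.asarray(
                    p.centroid.coords[0], dtype=float
                )
            pairs = set()
            ids = sorted(polys)
            for i, a in enumerate(ids):
                pa = polys[a].buffer(min_shared)
                for b_ in ids[i + 1 :]:
                    inter = pa.intersection(polys[b_].buffer(min_shared))
                    if inter.area > 4.0 * min_shared * min_shared * 10:
                        pairs.add(frozenset((a, b_)))
            adjacency[float(t)] = pairs
        return cls(times=times, adjacency=adjacency, centroids=centroids)


@dataclass
class T1Event:
    kind: str  # "gained" | "lost"
    time: float
    pair: frozenset
    axis_angle: float  # radians vs AP in (-pi/2, pi/2]


def _debounced_runs(states: np.ndarray, window: int) -> np.ndarray:
    """Remove state runs of length <= window that revert (flicker)."""
    s = states.copy()
    changed = True
    while changed:
        changed = False
        # run-length encode
        idx = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate([[0], idx])
        ends = np.concatenate([idx, [len(s)]])
        for a, b in zip(starts[1:-1], ends[1:-1]):  # interior runs only
            if (b - a) <= window:
                s[a:b] = s[a - 1]
                changed = True
                break
    return s


def detect_t1_events(graph: NeighborGraph, debounce: int = 1) -> list[T1Event]:
    """T1 events: cell pairs whose shared junction appears or vanishes.

    Pairs that are neighbors at every timepoint are filtered out; adjacency
    changes that revert within ``debounce`` timepoints are discarded as
    segmentation flicker.  Each surviving change yields one event, stamped
    with the first timepoint of the new state, and an axis along the
    centroid-centroid segment of the pair at that time.
    """
    times = graph.times
    if len(times) < 2:
        raise ValueError("need at least two timepoints")
    all_pairs = set()
    for t in times:
        all_pairs |= graph.adjacency.get(float(t), set())
    events: list[T1Event] = []
    for pair in sorted(all_pairs, key=lambda p: tuple(sorted(p))):
        a, b = tuple(sorted(pair))
        present_mask = np.array(
            [
                (a, float(t)) in graph.centroids and (b, float(t)) in graph.centroids
                for t in times
            ]
        )
        tsub = times[present_mask]
        if len(tsub) < 2:
            continue
        adj = np.array(
            [pair in graph.adjacency.get(float(t), set()) for t in tsub]
        )
        if adj.all():
            continue  # shared edge never participates in a rearrangement
        adj = _debounced_runs(adj.astype(int), debounce)
        for i in np.flatnonzero(np.diff(adj)):
            t_ev = float(tsub[i + 1])
            kind = "gained" if adj[i + 1] == 1 else "lost"
            ca = graph.centroids[(a, t_ev)]
            cb = graph.centroids[(b, t_ev)]
            d = cb - ca
            ang = float(np.arctan2(d[1], d[0]))
            if ang <= -np.pi / 2:
                ang += np.pi
            elif ang > np.pi / 2:
                ang -= np.pi
            events.append(T1Event(kind=kind, time=t_ev, pair=pair, axis_angle=ang))
    return events


def t1_orientation_bias(events) -> dict:
    """AP-vs-DV classification of T1 axes and an exact binomial test.

    An event whose axis lies within 45 degrees of the AP direction counts as
    AP-oriented; the two-sided binomial test asks whether the AP/DV split
    deviates from 1/2.
    """
    if len(events) == 0:
        raise ValueError("no events to classify")
    ap = sum(1 for e in events if abs(e.axis_angle) < np.pi / 4)
    n = len(events)
    res = binomtest(ap, n, 0.5, alternative="two-sided")
    return {"n_ap": ap, "n_dv": n - ap, "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# cell shape vs tissue shear


def cellshape_vs_tissue_shear(
    records_by_time: dict, kymograph: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Compare per-s-bin cell anisotropy change with tissue anisotropy K.

    ``records_by_time[t]`` is the list of measured cell records at time t.
    For each kymograph s-bin and timepoint, the area-weighted mean cell
    aspect is normalized by its value at the first timepoint and correlated
    against the tissue anisotropy ratio K of the same bin.  Returns the
    merged table and the Pearson correlation.
    """
    centers = np.sort(kymograph["s_center"].unique())
    if len(centers) < 2:
        raise ValueError("kymograph needs >= 2 s-bins")
    half = 0.5 * (centers[1] - centers[0])
    edges = np.concatenate([centers - half, [centers[-1] + half]])
    times = sorted(records_by_time)
    kt = sorted(kymograph["t"].unique())
    shared = [t for t in times if t in kt]
    if not shared:
        raise ValueError("records and kymograph share no timepoints")
    rows = []
    base: dict[int, float] = {}
    for t in shared:
        recs = records_by_time[t]
        sbin = np.clip(
            np.digitize([r.s for r in recs], edges) - 1, 0, len(centers) - 1
        )
        for b in range(len(centers)):
            sel = [r for r, sb in zip(recs, sbin) if sb == b]
            if not sel:
                continue
            m = weighted_mean_aspect(sel)
            if b not in base:
                base[b] = m
            krow = kymograph[
                (kymograph["t"] == t)
                & (np.isclose(kymograph["s_center"], centers[b]))
            ]
            if krow.empty:
                continue
            rows.append(
                {
                    "t": t,
                    "s_center": centers[b],
                    "cell_aspect_change": m / base[b],
                    "tissue_K": float(krow["K"].iloc[0]),
                }
            )
    table = pd.DataFrame(rows)
    r = float(
        np.corrcoef(table["cell_aspect_change"], table["tissue_K"])[0, 1]
    )
    return table, r


# ---------------------------------------------------------------------------
# nuclei pair motion


def nuclei_pair_motion(tracks: pd.DataFrame) -> dict:
    """Pair separation versus time and its fitted growth rate.

    ``tracks`` is tidy with columns (pair_id, layer, t, x, y, z); each pair
    must have both layers at every timepoint it appears.  Returns the
    per-time mean +- SD separation, the fitted mean separation rate in um/h,
    and the mean integrated path length of the nuclei for comparison.
    """
    required = {"pair_id", "layer", "t", "x", "y", "z"}
    if not required.issubset(tracks.columns):
        raise ValueError(f"tracks must have columns {sorted(required)}")
    piv = tracks.pivot_table(
        index=["pair_id", "t"], columns="layer", values=["x", "y", "z"]
    )
    if piv.isna().any().any():
        raise ValueError("unpaired track: a pair lacks one layer at some timepoint")
    layers = tracks["layer"].unique()
    la, lb = sorted(layers)[0], sorted(layers)[1]
    pa = piv.xs(la, level=1, axis=1)[["x", "y", "z"]].to_numpy()
    pb = piv.xs(lb, level=1, axis=1)[["x", "y", "z"]].to_numpy()
    sep = np.linalg.norm(pa - pb, axis=1)
    df = piv.reset_index()[["pair_id", "t"]].copy()
    df.columns = ["pair_id", "t"]
    df["separation"] = sep
    per_time = (
        df.groupby("t")["separation"].agg(mean="mean", sd="std").reset_index()
    )
    slope = np.polyfit(per_time["t"], per_time["mean"], 1)[0]  # um/min

    # integrated path length per nucleus, averaged
    path = []
    for (pid, layer), grp in tracks.sort_values("t").groupby(["pair_id", "layer"]):
        xyz = grp[["x", "y", "z"]].to_numpy()
        path.append(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())
    return {
        "per_time": per_time,
        "rate_um_per_h": float(slope * 60.0),
        "mean_path_length": float(np.mean(path)),
        "mean_delta_separation": float(
            per_time["mean"].iloc[-1] - per_time["mean"].iloc[0]
        ),
    }


# ---------------------------------------------------------------------------
# condition comparison


def group_anisotropy_comparison(
    records_a_by_time: dict, records_b_by_time: dict
) -> dict:
    """Per-timepoint z-scores of condition B against A and a sustained p.

    At each shared timepoint the cell aspect distributions are summarized and
    compared with the two-sample z-score; the per-timepoint scores are
    combined with Stouffer's rule into a single one-sided p for a sustained
    reduction of anisotropy change in condition B.
    """
    shared = sorted(set(records_a_by_time) & set(records_b_by_time))
    if not shared:
        raise ValueError("conditions share no timepoints")
    rows = []
    for t in shared:
        ga = tkstats.GroupSummary.from_values(
            [r.aspect for r in records_a_by_time[t]]
        )
        gb = tkstats.GroupSummary.from_values(
            [r.aspect for r in records_b_by_time[t]]
        )
        z = tkstats.z_score(gb, ga)
        rows.append({"t": t, "mean_a": ga.mean, "mean_b": gb.mean, "z": z})
    table = pd.DataFrame(rows)
    if len(shared) == 1:
        return {"per_time": table, "combined_z": float(table["z"].iloc[0]),
                "p": tkstats.one_sided_p(float(table["z"].iloc[0])),
                "warning": "single shared timepoint; no combination"}
    zc, p = tkstats.stouffer_combined_p(table["z"].to_numpy())
    return {"per_time": table, "combined_z": zc, "p": p}
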