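"""Calcium-transient quantification from frame triplets.

Fluorescent reporter movies are acquired as triplets of max-projection frames
a few seconds apart (one triplet per composite period).  Transient activity
is isolated with the symmetric triplet difference

    dI = |I1 - I2| + |I2 - I3| + |I1 - I3|,

which cancels static fluorescence and is invariant under permutations of the
three frames.  Coherent features are extracted with a Gaussian blur followed
by a white top-hat filter, summed along the circumferential image axis into
an anterior-posterior activity profile, normalized across embryos against a
background window far from the constriction site, and assembled into
onset-aligned kymographs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from .synthetic import CalciumStack

__all__ = [
    "transient_activity",
    "extract_features",
    "ap_activity_profile",
    "stack_profiles",
    "integrate_activity",
    "normalize_embryo",
    "activity_kymograph",
]


def transient_activity(triplet: np.ndarray) -> np.ndarray:
    """Pixelwise triplet difference dI = |I1-I2| + |I2-I3| + |I1-I3|.

    Zero for identical frames; for a pulse of amplitude A present only in the
    middle frame, dI = 2A at the pulse pixels.
    """
    triplet = np.asarray(triplet, dtype=float)
    if triplet.shape[0] != 3 or triplet.ndim != 3:
        raise ValueError("triplet must be 3 frames of equal shape")
    i1, i2, i3 = triplet
    return np.abs(i1 - i2) + np.abs(i2 - i3) + np.abs(i1 - i3)


def extract_features(
    dI: np.ndarray, blur_sigma: float = 2.0, tophat_radius: float = 15.0
) -> np.ndarray:
    """Gaussian blur followed by a white top-hat filter.

    The blur suppresses pixel noise; the top-hat (opening subtracted from the
    image, with a disk footprint) removes background plateaus broader than
    the footprint while preserving isolated pulse blobs.  Blobs closer than
    the top-hat radius merge into one feature.
    """
    if blur_sigma <= 0 or tophat_radius <= 0:
        raise ValueError("filter parameters must be positive")
    if tophat_radius < 2.0 * blur_sigma:
        warnings.warn(
            "top-hat radius below blur support; features may be erased",
            stacklevel=2,
        )
    blurred = ndimage.gaussian_filter(np.asarray(dI, dtype=float), blur_sigma)
    footprint = morphology.disk(int(round(tophat_radius)))
    return morphology.white_tophat(blurred, footprint)


def ap_activity_profile(
    cleaned: np.ndarray, ap_axis: int = 1, pixel_size: float = 1.0
):
    """Sum the cleaned signal along the circumferential axis.

    Returns ``(positions_um, profile)``: one value per AP pixel column.
    """
    if ap_axis not in (0, 1):
        raise ValueError("ap_axis must be 0 or 1")
    circ_axis = 1 - ap_axis
    profile = np.asarray(cleaned, dtype=float).sum(axis=circ_axis)
    positions = np.arange(profile.shape[0]) * pixel_size
    return positions, profile


def stack_profiles(
    stack: CalciumStack, blur_sigma: float = 2.0, tophat_radius: float = 15.0
) -> pd.DataFrame:
    """AP activity profile for every triplet of a stack.

    Columns: triplet, t (minutes from recording start), ap_um, activity.
    """
    rows = []
    times = stack.triplet_times()
    for k in range(stack.n_triplets):
        dI = transient_activity(stack.triplet(k))
        cleaned = extract_features(dI, blur_sigma, tophat_radius)
        pos, prof = ap_activity_profile(cleaned, stack.ap_axis, stack.pixel_size)
        for x, v in zip(pos, prof):
            rows.append(
                {"triplet": k, "t": float(times[k]), "ap_um": float(x), "activity": float(v)}
            )
    return pd.DataFrame(rows)


def integrate_activity(
    profiles: pd.DataFrame, t_min: float, t_max: float
) -> pd.DataFrame:
    """Time-integrated AP profile over a window (minutes).

    Sums the per-triplet profiles whose timestamps fall in [t_min, t_max].
    """
    lo, hi = profiles["t"].min(), profiles["t"].max()
    if t_min > hi or t_max < lo:
        raise ValueError(
            f"window [{t_min}, {t_max}] outside recorded range [{lo}, {hi}]"
        )
    sel = profiles[(profiles["t"] >= t_min) & (profiles["t"] <= t_max)]
    return (
        sel.groupby("ap_um")["activity"].sum().rename("integrated").reset_index()
    )


def normalize_embryo(
    positions: np.ndarray,
    profile: np.ndarray,
    site: float,
    background_window: tuple[float, float] = (45.0, 50.0),
):
    """Normalize a profile to its background and maximum.

    The background is the mean of the profile at distances within
    ``background_window`` (um) from the putative constriction ``site``; the
    normalized profile maps background to 0 and the maximum to 1, removing
    embryo-to-embryo differences in optical density (invariant under affine
    intensity rescaling of the raw movie).
    """
    positions = np.asarray(positions, dtype=float)
    profile = np.asarray(profile, dtype=float)
    dist = np.abs(positions - site)
    sel = (dist >= background_window[0]) & (dist <= background_window[1])
    if not sel.any():
        raise ValueError("background window contains no profile samples")
    bg = profile[sel].mean()
    peak = profile.max()
    if peak <= bg:
        raise ValueError(
            "profile maximum does not exceed background; record uninformative"
        )
    return (profile - bg) / (peak - bg)


def activity_kymograph(
    records: list[dict],
    n_ap: int = 64,
    n_t: int = 32,
) -> dict:
    """Group-mean kymograph over embryos on a common (AP, t) grid.

    Each record is a dict with keys ``profiles`` (the tidy per-triplet table
    from :func:`stack_profiles`) and ``t0`` (constriction onset, minutes);
    times are re-aligned so t=0 is the onset.  Returns dict with ``ap``,
    ``t``, ``mean`` (n_t, n_ap) and ``sem`` layers.
    """
    if not records:
        raise ValueError("no records")
    ap_lo = max(r["profiles"]["ap_um"].min() for r in records)
    ap_hi = min(r["profiles"]["ap_um"].max() for r in records)
    if ap_hi <= ap_lo:
        raise ValueError("records have disjoint AP ranges")
    t_lo = min((r["profiles"]["t"].min() - r["t0"]) for r in records)
    t_hi = max((r["profiles"]["t"].max() - r["t0"]) for r in records)
    ap = np.linspace(ap_lo, ap_hi, n_ap)
    tt = np.linspace(t_lo, t_hi, n_t)
    layers = []
    for r in records:
        prof = r["profiles"]
        times = np.sort(prof["t"].unique())
        grid = np.full((len(times), n_ap), np.nan)
        for i, t in enumerate(times):
            sub = prof[prof["t"] == t]
            grid[i] = np.interp(ap, sub["ap_um"], sub["activity"])
        shifted = times - r["t0"]
        out = np.full((n_t, n_ap), np.nan)
        inside = (tt >= shifted.min()) & (tt <= shifted.max())
        for j in range(n_ap):
            out[inside, j] = np.interp(tt[inside], shifted, grid[:, j])
        layers.append(out)
    cube = np.stack(layers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(cube, axis=0)
        n_eff = np.sum(np.isfinite(cube), axis=0)
        sem = np.nanstd(cube, axis=0) / np.sqrt(np.maximum(n_eff, 1))
    return {"ap": ap, "t": tt, "mean": mean, "sem": sem, "n": n_eff}
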