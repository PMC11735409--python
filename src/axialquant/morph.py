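"""Midline morphometrics of elongated organoid masks.

An organoid's 2D binary mask (from an upstream segmentation network) is
reduced to a midline — the longest geodesic path on its morphological
skeleton, extended to the mask boundary along the end tangents — whose
arclength defines the maximum organoid length. Reporter signal is resampled
along the standardized midline coordinate s ∈ [0, 1] (per-bin maximum over
the pixels nearest each midline position), yielding per-sample profiles from
which the longest uninterrupted positive stretch, conservative bright-area
fractions, volume-fraction ratios and cohort correlations are computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from scipy.stats import pearsonr
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import skeletonize

__all__ = [
    "MidlineProfile",
    "extract_midline",
    "standardized_profile",
    "auto_positivity_threshold",
    "longest_positive_stretch",
    "signal_area_fraction",
    "correlate",
    "volume_fraction_ratio",
]


@dataclass
class MidlineProfile:
    """Midline geometry and (optionally) a standardized signal profile."""

    polyline_um: np.ndarray  # (N, 2) (x, y) µm
    arclength_um: float
    pixel_size: float
    bin_values: Optional[np.ndarray] = None  # per-bin maximum signal
    bin_centers: Optional[np.ndarray] = None  # s positions (i+0.5)/n
    interpolated_bins: Optional[np.ndarray] = None  # bool flags
    flipped: bool = False


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = cc_label(mask, connectivity=2)
    if lab.max() == 0:
        raise ValueError("organoid mask is empty")
    if lab.max() > 1:
        warnings.warn("mask has multiple components; keeping the largest")
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
    return mask.astype(bool)


def _principal_axis_chord(mask: np.ndarray) -> np.ndarray:
    """Chord through the centroid along the principal axis, clipped to the
    mask; fallback midline for masks too thin to skeletonize."""
    props = regionprops(mask.astype(np.uint8))[0]
    cy, cx = props.centroid
    theta = props.orientation  # angle of major axis vs row axis
    # unit vector of the major axis in (row, col)
    dr, dc = -math.cos(theta), math.sin(theta)
    pts = []
    for sign in (-1.0, 1.0):
        r, c = cy, cx
        step = 0.5
        while True:
            rn, cn = r + sign * dr * step, c + sign * dc * step
            ri, ci = int(round(rn)), int(round(cn))
            if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]) or not mask[ri, ci]:
                break
            r, c = rn, cn
        pts.append((r, c))
    chord = np.array([pts[0], (cy, cx), pts[1]])
    return chord


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path on the skeleton via a double Dijkstra sweep.

    Exact on tree-shaped skeletons (the typical case after thinning); on the
    rare skeleton with loops the sweep returns a near-longest path.
    Returns the path as an (N, 2) array of (row, col).
    """
    coords = np.column_stack(np.nonzero(skel))
    n = len(coords)
    if n == 1:
        return coords.astype(float)
    index = -np.ones(skel.shape, dtype=np.int64)
    index[coords[:, 0], coords[:, 1]] = np.arange(n)
    rows_i, cols_j, weights = [], [], []
    for dr, dc in _NEIGHBORS:
        rr, cc = coords[:, 0] + dr, coords[:, 1] + dc
        ok = (rr >= 0) & (cc >= 0) & (rr < skel.shape[0]) & (cc < skel.shape[1])
        ok[ok] &= skel[rr[ok], cc[ok]]
        src = np.nonzero(ok)[0]
        dst = index[rr[src], cc[src]]
        rows_i.append(src)
        cols_j.append(dst)
        weights.append(np.full(len(src), math.hypot(dr, dc)))
    adj = sparse.csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows_i), np.concatenate(cols_j))),
        shape=(n, n),
    )

    def farthest(start: int):
        dist, pred = dijkstra(adj, indices=start, return_predecessors=True)
        dist[np.isinf(dist)] = -1.0
        end = int(np.argmax(dist))
        return end, pred

    end1, _ = farthest(0)
    end2, pred = farthest(end1)
    path = [end2]
    while path[-1] != end1:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    return coords[np.array(path[::-1])].astype(float)


def _smooth_polyline(path: np.ndarray, window: int = 5) -> np.ndarray:
    if len(path) <= window:
        return path
    kernel = np.ones(window) / window
    sm = path.copy()
    for ax in range(2):
        sm[:, ax] = np.convolve(np.pad(path[:, ax], window // 2, mode="edge"), kernel, mode="valid")[: len(path)]
    sm[0], sm[-1] = path[0], path[-1]
    return sm


def _resample_polyline(path: np.ndarray, step: float) -> np.ndarray:
    """Resample by arclength at ~``step`` px spacing; long straight segments
    suppress residual pixel-scale wobble that skews far-pixel projections."""
    seg = np.diff(path, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    total = cum[-1]
    if total == 0 or len(path) < 3:
        return path
    n = max(int(round(total / step)), 2)
    s_new = np.linspace(0.0, total, n + 1)
    return np.column_stack([np.interp(s_new, cum, path[:, ax]) for ax in range(2)])


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray, tail_len: int = 5) -> np.ndarray:
    """Extend both path ends to the mask boundary along the end tangents."""
    out = [path]
    tail_len = min(max(tail_len, 2), max(len(path) // 2, 2))
    for which in (0, -1):
        tail = path[:tail_len] if which == 0 else path[-tail_len:]
        if len(tail) >= 2:
            d = tail[-1] - tail[0] if which == -1 else tail[0] - tail[-1]
        else:
            d = np.array([0.0, 0.0])
        norm = np.hypot(*d)
        if norm == 0:
            continue
        d = d / norm
        r, c = path[which]
        last = None
        while True:
            r, c = r + 0.5 * d[0], c + 0.5 * d[1]
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]) or not mask[ri, ci]:
                break
            last = (r, c)
        if last is not None:
            if which == 0:
                out.insert(0, np.array([last]))
            else:
                out.append(np.array([last]))
    return np.vstack(out)


def extract_midline(mask: np.ndarray, pixel_size: float = 1.0) -> MidlineProfile:
    """Midline polyline and arclength of an organoid mask.

    The midline is the longest geodesic path on the morphological skeleton
    (short side branches are ignored by construction), smoothed and extended
    to the mask boundary along the end tangents. Masks thinner than ~3 px
    everywhere fall back to the principal-axis chord with a warning.
    """
    mask = _largest_component(np.asarray(mask, dtype=bool))
    half_width = float(ndi.distance_transform_edt(mask).max())
    if half_width < 1.5:
        warnings.warn("mask is thinner than 3 px everywhere; using principal-axis chord")
        path = _principal_axis_chord(mask)
    else:
        skel = skeletonize(mask)
        if not skel.any():
            path = _principal_axis_chord(mask)
        else:
            path = _longest_skeleton_path(skel)
            if len(path) < max(3, 0.05 * math.sqrt(mask.sum())):
                # near-round mask: skeleton collapses to a point; use the chord
                path = _principal_axis_chord(mask)
            else:
                # near the tips the skeleton forks toward the rounded-cap
                # corners; drop that fork region (about one half-width) so the
                # tip extension follows the axial direction, then smooth over
                # the half-width scale where skeleton wobble tilts directions
                trim = int(half_width)
                if len(path) > 6 * trim and trim > 0:
                    path = path[trim:-trim]
                window = max(5, int(half_width) | 1)
                path = _smooth_polyline(path, window)
                path = _resample_polyline(path, max(2.0, half_width / 2.0))
            path = _extend_to_boundary(path, mask, tail_len=3)
    seg = np.diff(path, axis=0)
    arclen_px = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if arclen_px == 0.0:
        arclen_px = 1.0  # single-pixel mask: one-pixel midline
    poly_um = np.column_stack((path[:, 1] * pixel_size, path[:, 0] * pixel_size))
    return MidlineProfile(polyline_um=poly_um, arclength_um=arclen_px * pixel_size, pixel_size=pixel_size)


def standardized_profile(
    mask: np.ndarray,
    signal: np.ndarray,
    n_bins: int = 100,
    pixel_size: float = 1.0,
    midline: Optional[MidlineProfile] = None,
    orient_bright_low: bool = True,
) -> MidlineProfile:
    """Maximum signal along the standardized midline coordinate.

    Every in-mask pixel is assigned to its nearest midline vertex; each of
    the ``n_bins`` bins at s = (i+0.5)/n takes the maximum signal among its
    assigned pixels. Empty bins are linearly interpolated and flagged. With
    ``orient_bright_low`` the profile is flipped, if needed, so the brighter
    half sits at lower s, making profiles comparable across samples.
    """
    if midline is None:
        midline = extract_midline(mask, pixel_size)
    mask = _largest_component(np.asarray(mask, dtype=bool))
    if signal.shape != mask.shape:
        raise ValueError("signal must be aligned to the mask")
    poly_px = np.column_stack((midline.polyline_um[:, 1], midline.polyline_um[:, 0])) / midline.pixel_size
    seg = np.diff(poly_px, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s_vertex = cum / cum[-1] if cum[-1] > 0 else np.zeros(len(poly_px))
    # densify so nearest-vertex assignment approximates nearest-point
    dense_s, dense_pts = [s_vertex[0]], [poly_px[0]]
    for i in range(len(seg)):
        steps = max(int(seglen[i] / 0.7), 1)
        for t in np.linspace(0, 1, steps + 1)[1:]:
            dense_pts.append(poly_px[i] + t * seg[i])
            dense_s.append(s_vertex[i] + t * (s_vertex[i + 1] - s_vertex[i]))
    tree = cKDTree(np.asarray(dense_pts))
    rr, cc = np.nonzero(mask)
    _, idx = tree.query(np.column_stack((rr, cc)).astype(float), k=1)
    s_pix = np.asarray(dense_s)[idx]
    bins = np.minimum((s_pix * n_bins).astype(int), n_bins - 1)
    acc = np.full(n_bins, -np.inf)
    np.maximum.at(acc, bins, signal[rr, cc].astype(float))
    values = np.where(np.isinf(acc), np.nan, acc)
    empty = np.isnan(values)
    if empty.any() and not empty.all():
        centers = (np.arange(n_bins) + 0.5) / n_bins
        values[empty] = np.interp(centers[empty], centers[~empty], values[~empty])
    flipped = False
    if orient_bright_low and n_bins > 1:
        half = n_bins // 2
        if np.nansum(values[n_bins - half:]) > np.nansum(values[:half]):
            values = values[::-1].copy()
            empty = empty[::-1].copy()
            flipped = True
    return MidlineProfile(
        polyline_um=midline.polyline_um,
        arclength_um=midline.arclength_um,
        pixel_size=midline.pixel_size,
        bin_values=values,
        bin_centers=(np.arange(n_bins) + 0.5) / n_bins,
        interpolated_bins=empty,
        flipped=flipped,
    )


def auto_positivity_threshold(bin_values: np.ndarray, random_state: int = 0) -> float:
    """Midpoint between background and signal modes of a 2-component
    Gaussian mixture over per-bin maxima."""
    from sklearn.mixture import GaussianMixture

    v = np.asarray(bin_values, dtype=float).reshape(-1, 1)
    v = v[np.isfinite(v[:, 0])].reshape(-1, 1)
    if len(v) < 2 or np.all(v == v[0]):
        return float(v.mean()) if len(v) else 0.0
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3).fit(v)
    lo, hi = np.sort(gm.means_.ravel())
    return float(0.5 * (lo + hi))


def longest_positive_stretch(
    profile: MidlineProfile, threshold: Optional[float] = None
) -> float:
    """Longest run of consecutive positive bins as a fraction of the length.

    ``threshold`` defaults to the automatic background/signal midpoint.
    """
    if profile.bin_values is None:
        raise ValueError("profile carries no signal; run standardized_profile first")
    v = profile.bin_values
    if threshold is None:
        threshold = auto_positivity_threshold(v)
    pos = v >= threshold
    best = run = 0
    for p in pos:
        run = run + 1 if p else 0
        best = max(best, run)
    return best / len(v)


def signal_area_fraction(
    mask: np.ndarray,
    signal: np.ndarray,
    threshold: Optional[float] = None,
    percentile: float = 99.0,
) -> Tuple[float, float]:
    """Fraction of mask area with signal at or above a conservative threshold.

    Default threshold: the ``percentile``-th percentile (99th) of the in-mask
    signal, a deliberately conservative cut for "brightest signal" area.
    Returns (fraction, threshold used).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    inside = signal[mask]
    if threshold is None:
        threshold = float(np.percentile(inside, percentile))
    return float((inside >= threshold).mean()), float(threshold)


def correlate(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson product-moment correlation with a two-sided p-value.

    Zero variance in either vector leaves the correlation undefined: returns
    (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("zero variance: correlation undefined")
        return float("nan"), float("nan")
    r, p = pearsonr(x, y)
    return float(r), float(p)


def volume_fraction_ratio(
    tbxt_fraction: Sequence[float], foxc2_fraction: Sequence[float]
) -> np.ndarray:
    """Per-sample ratio of two volume fractions (e.g. notochord TBXT over
    somitic FOXC2); NaN where the denominator is 0 (flagged undefined,
    excluded from cohort summaries)."""
    a = np.asarray(tbxt_fraction, dtype=float)
    b = np.asarray(foxc2_fraction, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("fractions must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b > 0, a / b, np.nan)
    return ratio
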