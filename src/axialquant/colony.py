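"""Micropattern colony quantification.

Radial intensity profiles (mean signal per normalized-radius bin, averaged
across colonies with s.d. bands), counting of peripheral marker-high
aggregates by angular connectivity, and time-course relative-expression
normalization (per gene, log10(value + pseudo-count) scaled to its maximum).
Profiles can be computed from raw image pixels or from per-cell records;
both views are exposed because nucleus-pipeline analyses are cell-based
while stain quantifications are pixel-based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "RadialProfile",
    "AggregateCount",
    "bin_radial_image",
    "bin_radial_cells",
    "radial_profile",
    "count_edge_aggregates",
    "relative_expression",
    "fit_circle",
]


@dataclass
class RadialProfile:
    bin_centers: np.ndarray  # normalized radius r/R
    per_colony: np.ndarray  # (n_colonies, n_bins), NaN where a bin is empty
    mean: np.ndarray
    sd: np.ndarray
    n_colonies: int


@dataclass
class AggregateCount:
    colony_id: Union[int, str]
    diameter_um: float
    n_aggregates: int
    arc_extents_deg: List[Tuple[float, float]]


def _bin_means(r_norm: np.ndarray, values: np.ndarray, n_bins: int) -> Tuple[np.ndarray, np.ndarray]:
    keep = r_norm <= 1.0
    r_norm, values = r_norm[keep], values[keep]
    idx = np.minimum((r_norm * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan  # empty bins are missing, not zero
    return means, counts


def bin_radial_image(
    image: np.ndarray,
    center: Tuple[float, float],
    radius: float,
    n_bins: int = 50,
    return_counts: bool = False,
):
    """Per-bin mean pixel intensity for one colony image plane.

    ``center`` is (x, y) and ``radius`` the colony radius, both in pixel
    units of the image. Pixels beyond r/R = 1 are excluded. With
    ``return_counts`` also returns the per-bin pixel counts (these sum to
    the number of pixels inside the disc).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ny, nx = image.shape
    cx, cy = center
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError("center must lie inside the image")
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    r = np.hypot(cols + 0.5 - cx, rows + 0.5 - cy) / radius
    means, counts = _bin_means(r.ravel(), image.astype(float).ravel(), n_bins)
    return (means, counts) if return_counts else means


def bin_radial_cells(
    records: pd.DataFrame,
    value_col: str,
    center_um: Tuple[float, float],
    radius_um: float,
    n_bins: int = 50,
) -> np.ndarray:
    """Per-bin mean of a per-cell value, binning cells by centroid radius."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    r = np.hypot(
        records["x_um"].to_numpy(float) - center_um[0],
        records["y_um"].to_numpy(float) - center_um[1],
    ) / radius_um
    return _bin_means(r, records[value_col].to_numpy(float), n_bins)[0]


def radial_profile(per_colony_bins: Sequence[np.ndarray], n_bins: Optional[int] = None) -> RadialProfile:
    """Across-colony aggregation of per-colony radial bin means.

    The across-colony mean and s.d. ignore colonies whose bin is empty; the
    s.d. is identically 0 for a single colony.
    """
    mat = np.vstack([np.asarray(b, dtype=float) for b in per_colony_bins])
    if n_bins is not None and mat.shape[1] != n_bins:
        raise ValueError("per-colony bin vectors disagree with n_bins")
    nb = mat.shape[1]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-empty bins stay NaN
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0) if mat.shape[0] > 1 else np.zeros(nb)
    centers = (np.arange(nb) + 0.5) / nb
    return RadialProfile(bin_centers=centers, per_colony=mat, mean=mean, sd=sd, n_colonies=mat.shape[0])


def _angular_groups(angles_deg: np.ndarray, gap_deg: float) -> List[np.ndarray]:
    """Group angles on the circle, splitting at gaps larger than gap_deg."""
    order = np.argsort(angles_deg)
    a = angles_deg[order]
    n = len(a)
    if n == 0:
        return []
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    breaks = np.nonzero(gaps > gap_deg)[0]
    if len(breaks) == 0:
        return [order]  # a single aggregate spanning the whole ring
    groups = []
    start = (breaks[-1] + 1) % n
    idx = start
    current = []
    for _ in range(n):
        current.append(order[idx])
        if idx in breaks:
            groups.append(np.array(current))
            current = []
        idx = (idx + 1) % n
    if current:
        groups.append(np.array(current))
    return groups


def count_edge_aggregates(
    records: Optional[pd.DataFrame] = None,
    mask: Optional[np.ndarray] = None,
    center: Tuple[float, float] = (0.0, 0.0),
    radius: float = 1.0,
    edge_band: float = 0.8,
    gap_deg: float = 15.0,
    min_cells: int = 3,
    marker: str = "TBXT",
    colony_id: Union[int, str] = 0,
) -> AggregateCount:
    """Count marker-high aggregates in the colony's peripheral band.

    Takes either per-cell ``records`` (cells with ``level_<marker> == 'high'``)
    or a boolean pixel ``mask`` of marker-positive signal. Positive items with
    normalized radius ≥ ``edge_band`` are grouped by angular connectivity:
    consecutive angles closer than ``gap_deg`` belong to one aggregate; groups
    with at least ``min_cells`` members are counted.
    """
    cx, cy = center
    if records is not None:
        sel = records[records[f"level_{marker}"] == "high"]
        x = sel["x_um"].to_numpy(float) - cx
        y = sel["y_um"].to_numpy(float) - cy
    elif mask is not None:
        rr, cc = np.nonzero(mask)
        x = cc + 0.5 - cx
        y = rr + 0.5 - cy
    else:
        raise ValueError("provide records or mask")
    r = np.hypot(x, y) / radius
    band = (r >= edge_band) & (r <= 1.0 + 1e-9)
    angles = np.degrees(np.arctan2(y[band], x[band])) % 360.0
    groups = [g for g in _angular_groups(angles, gap_deg) if len(g) >= min_cells]
    extents = []
    for g in groups:
        a = np.sort(angles[g])
        # report the arc in a rotation-stable way (may wrap through 0)
        gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
        cut = int(np.argmax(gaps))
        start = a[(cut + 1) % len(a)]
        end = a[cut]
        extents.append((float(start), float(end)))
    return AggregateCount(
        colony_id=colony_id,
        diameter_um=2.0 * radius,
        n_aggregates=len(groups),
        arc_extents_deg=extents,
    )


def relative_expression(timecourse: pd.DataFrame, pseudo_count: float = 1.0) -> pd.DataFrame:
    """Normalize a gene × time expression table to each gene's maximum.

    Each value becomes log10(value + pseudo_count) divided by the gene's
    maximum log10(value + pseudo_count), so the peak time point is exactly 1.
    Genes whose maximum is 0 (all-zero expression with pseudo_count 1) are
    returned as NaN rather than dividing by zero.
    """
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive")
    vals = timecourse.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative")
    logv = np.log10(vals + pseudo_count)
    maxes = logv.max(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(maxes > 0, logv / maxes, np.nan)
    return pd.DataFrame(norm, index=timecourse.index, columns=timecourse.columns)


def fit_circle(points: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares (Kåsa) circle fit; returns (cx, cy, radius).

    Used to estimate a colony's center and radius from its boundary pixels
    when the nominal micropattern diameter is not supplied.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 boundary points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    radius = math.sqrt(sol[2] + cx**2 + cy**2)
    return float(cx), float(cy), float(radius)
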