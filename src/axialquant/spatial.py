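"""Spatial mapping of quantified cells.

Cells are clustered on their (log-transformed, z-scored) marker signal
profiles, cluster identities are mapped back to the 3D centroid cloud, and
nearest-neighbour distance analyses compare how close one cell class lies to
two others (e.g. notochord-like cells to floor plate versus dorsal neural
cells), with a paired Wilcoxon signed-rank test on the per-cell distance
pairs. All distances are Euclidean in physical µm, so anisotropic z spacing
is honoured as long as centroids are expressed in µm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import wilcoxon

from .markers import boxplot_stats

__all__ = ["ClusterResult", "DistanceReport", "cluster_cells", "spatial_scatter", "nearest_distance_analysis"]

_COORDS = ["x_um", "y_um", "z_um"]


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-cell cluster id, contiguous from 0
    k: int
    method: str
    rng_seed: int
    degenerate: bool
    marker_stats: Dict[int, Dict[str, Dict[str, float]]] = field(default_factory=dict)


@dataclass
class DistanceReport:
    source_class: str
    target_1: str
    target_2: str
    distances_1: np.ndarray  # µm, one per source cell
    distances_2: np.ndarray
    mean_1: float
    mean_2: float
    median_1: float
    median_2: float
    statistic: float
    p_value: float
    n_source: int


def cluster_cells(
    records: pd.DataFrame,
    markers: Sequence[str],
    k: int = 4,
    rng_seed: int = 0,
) -> ClusterResult:
    """K-means clustering of cells on z-scored log(signal + 1).

    Deterministic given ``rng_seed``. Degenerate input (all cells identical)
    is flagged with a warning and yields a single effective cluster. Per
    cluster and marker, box-plot statistics of the raw signal are attached.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError(f"cannot form k={k} clusters from {len(records)} cells")
    cols = [f"mean_{m}" for m in markers]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise ValueError(f"records lack signal columns: {missing}")
    X = np.log1p(records[cols].to_numpy(dtype=float))
    sd = X.std(axis=0)
    degenerate = bool(np.all(sd == 0.0))
    if degenerate:
        warnings.warn("all cells have identical signals; clustering is degenerate")
        labels = np.zeros(len(records), dtype=int)
    else:
        from sklearn.cluster import KMeans

        Xz = (X - X.mean(axis=0)) / np.where(sd == 0.0, 1.0, sd)
        km = KMeans(n_clusters=k, random_state=rng_seed, n_init=10)
        labels = km.fit_predict(Xz)
        # relabel contiguously in order of first appearance, for determinism
        remap: Dict[int, int] = {}
        for lab in labels:
            if lab not in remap:
                remap[lab] = len(remap)
        labels = np.array([remap[lab] for lab in labels])
    stats: Dict[int, Dict[str, Dict[str, float]]] = {}
    for cid in np.unique(labels):
        sel = records.loc[labels == cid, cols]
        stats[int(cid)] = {
            m: boxplot_stats(sel[f"mean_{m}"].to_numpy()) for m in markers
        }
    return ClusterResult(
        labels=labels, k=k, method="kmeans", rng_seed=rng_seed, degenerate=degenerate, marker_stats=stats
    )


def spatial_scatter(records: pd.DataFrame, assignment: Sequence) -> pd.DataFrame:
    """Plot-ready table of 3D centroids with their cluster/class assignment."""
    if len(records) == 0:
        return pd.DataFrame(columns=["cell_id"] + _COORDS + ["assignment"])
    missing = [c for c in _COORDS if c not in records.columns]
    if missing:
        raise ValueError(f"records lack centroid columns: {missing}")
    out = records[["cell_id"] + _COORDS].copy() if "cell_id" in records.columns else records[_COORDS].copy()
    out["assignment"] = list(assignment)
    return out.reset_index(drop=True)


def _nearest(source_xyz: np.ndarray, target_xyz: np.ndarray) -> np.ndarray:
    tree = cKDTree(target_xyz)
    d, _ = tree.query(source_xyz, k=1)
    return np.asarray(d, dtype=float)


def nearest_distance_analysis(
    records: pd.DataFrame,
    source_class: str,
    target_1: str,
    target_2: str,
    class_col: str = "cell_class",
) -> DistanceReport:
    """Nearest-neighbour distances from a source class to two target classes.

    For every source cell, the Euclidean 3D distance to the closest cell of
    each target class; the two per-cell distance vectors are compared with a
    two-sided Wilcoxon signed-rank test.
    """
    for name in (source_class, target_1, target_2):
        if not (records[class_col] == name).any():
            raise ValueError(f"class {name!r} has no cells")
    src = records.loc[records[class_col] == source_class, _COORDS].to_numpy(dtype=float)
    t1 = records.loc[records[class_col] == target_1, _COORDS].to_numpy(dtype=float)
    t2 = records.loc[records[class_col] == target_2, _COORDS].to_numpy(dtype=float)
    d1 = _nearest(src, t1)
    d2 = _nearest(src, t2)
    diff = d1 - d2
    if np.allclose(diff, 0.0):
        stat, p = np.nan, 1.0
    else:
        stat, p = wilcoxon(d1, d2, zero_method="wilcox", alternative="two-sided")
    return DistanceReport(
        source_class=source_class,
        target_1=target_1,
        target_2=target_2,
        distances_1=d1,
        distances_2=d2,
        mean_1=float(d1.mean()),
        mean_2=float(d2.mean()),
        median_1=float(np.median(d1)),
        median_2=float(np.median(d2)),
        statistic=float(stat),
        p_value=float(p),
        n_source=len(src),
    )
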