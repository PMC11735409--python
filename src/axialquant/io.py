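"""Readers and writers: TIFF stacks, per-plane label images, cell tables.

Cell tables are comma-separated with a ``#``-prefixed metadata header
(provenance: parameters hash, seed, package version) so every output file
carries its own provenance and remains greppable. Pixel indices are 0-based;
physical coordinates are µm with the origin at the image corner.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .consolidate import NucleusModel, PlaneMask

__all__ = [
    "read_stack",
    "write_stack",
    "read_plane_masks",
    "write_plane_masks",
    "label_volume",
    "cells_table",
    "write_table",
    "read_table",
    "params_hash",
]

_FLOAT_FMT = "%.9g"


def params_hash(params: Dict) -> str:
    """Stable short hash of a parameter mapping, for provenance headers."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_stack(path: Union[str, Path], layout: str = "CZYX") -> Tuple[np.ndarray, Dict]:
    """Read a multi-channel TIFF stack and normalize its axes to CZYX.

    ``layout`` declares the axis order of the file (e.g. ``"CZYX"`` or
    ``"ZCYX"``); a mismatch between the declared and found dimensionality is
    an error naming both shapes.
    """
    arr = tifffile.imread(str(path))
    layout = layout.upper()
    if sorted(layout) != sorted("CZYX"):
        raise ValueError(f"layout must be a permutation of CZYX, got {layout!r}")
    if arr.ndim != len(layout):
        raise ValueError(
            f"axis declaration {layout!r} expects {len(layout)} dimensions, "
            f"but {path} has shape {arr.shape}"
        )
    order = [layout.index(ax) for ax in "CZYX"]
    arr = np.transpose(arr, order)
    return arr, {"path": str(path), "layout": layout, "shape_czyx": arr.shape}


def write_stack(path: Union[str, Path], stack: np.ndarray) -> None:
    """Write a CZYX stack; float stacks are stored as float32."""
    arr = stack.astype(np.float32) if np.issubdtype(stack.dtype, np.floating) else stack
    tifffile.imwrite(str(path), arr)


def label_volume(nuclei: Sequence[NucleusModel], shape: Tuple[int, int, int]) -> np.ndarray:
    """Render consolidated nuclei as a 3D uint16 label volume."""
    vol = np.zeros(shape, dtype=np.uint16)
    for nuc in nuclei:
        v = nuc.voxel_mask
        vol[v[:, 0], v[:, 1], v[:, 2]] = nuc.nucleus_id
    return vol


def write_plane_masks(
    out_dir: Union[str, Path],
    masks: Sequence[PlaneMask],
    shape_yx: Tuple[int, int],
    n_planes: int,
) -> None:
    """Write per-plane 16-bit label TIFFs (background 0) from plane masks."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    planes = {z: np.zeros(shape_yx, dtype=np.uint16) for z in range(n_planes)}
    for m in masks:
        planes[m.plane_index][m.pixels[:, 0], m.pixels[:, 1]] = m.label
    for z, img in planes.items():
        tifffile.imwrite(str(out_dir / f"plane_{z:04d}.tif"), img)


def read_plane_masks(
    source: Union[str, Path],
    pixel_size_xy: float,
    z_spacing: float,
) -> List[PlaneMask]:
    """Load per-plane instance masks from a directory of 2D label TIFFs
    (sorted by name, one per z-plane) or a single 3D label TIFF."""
    source = Path(source)
    if source.is_dir():
        files = sorted(source.glob("*.tif")) + sorted(source.glob("*.tiff"))
        planes = [tifffile.imread(str(f)) for f in files]
    else:
        vol = tifffile.imread(str(source))
        if vol.ndim != 3:
            raise ValueError(f"expected a 3D label TIFF, got shape {vol.shape}")
        planes = list(vol)
    masks: List[PlaneMask] = []
    for z, img in enumerate(planes):
        for lab in np.unique(img):
            if lab == 0:
                continue
            rr, cc = np.nonzero(img == lab)
            masks.append(
                PlaneMask(z, int(lab), np.column_stack((rr, cc)), pixel_size_xy, z_spacing)
            )
    return masks


def cells_table(nuclei: Sequence[NucleusModel]) -> pd.DataFrame:
    """One row per consolidated nucleus: id, centroid (µm), volume, planes,
    per-channel mean intensities."""
    rows = []
    for nuc in nuclei:
        row = {
            "cell_id": nuc.nucleus_id,
            "x_um": nuc.centroid[0],
            "y_um": nuc.centroid[1],
            "z_um": nuc.centroid[2],
            "volume_um3": nuc.volume,
            "n_planes": nuc.n_planes,
        }
        for name, mean in nuc.channel_means.items():
            row[f"mean_{name}"] = mean
        rows.append(row)
    cols = ["cell_id", "x_um", "y_um", "z_um", "volume_um3", "n_planes"]
    if rows:
        extra = [c for c in rows[0] if c not in cols]
        return pd.DataFrame(rows, columns=cols + extra)
    return pd.DataFrame(columns=cols)


def write_table(path: Union[str, Path], df: pd.DataFrame, metadata: Optional[Dict] = None) -> None:
    """Write a CSV with a '#'-prefixed metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_table(path: Union[str, Path]) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Read a CSV written by :func:`write_table`; returns (table, metadata)."""
    meta: Dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta
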