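"""Ground-truthed synthetic microscopy scenes.

Emulates the two imaging preparations this package quantifies, with full
knowledge of the truth so every downstream stage is testable without raw
image data:

* **disc** scenes — micropatterned stem-cell colonies: ellipsoidal nuclei
  packed in a disc, with radially organised marker classes (e.g. a TBXT-high
  edge ring, a SOX2-high centre, a double-positive intermediate ring);
* **capsule** scenes — elongated trunk organoids: nuclei packed in a stadium
  (capsule) footprint with axial/transverse zones, including a midline
  reporter stripe of configurable axial coverage.

A second stage (:func:`emit_detections`) degrades the true nuclei into
imperfect per-plane 2D masks the way a 2D detector would: per-plane misses,
splits, merges of abutting masks and boundary jitter, all with recorded
provenance.

The module also provides 2D organoid fixtures (curved capsule masks with
known centerline, striped reporter signals) used by the midline
morphometrics, and small tabular generators for marker-level and clustering
benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage as ndi

from .consolidate import PlaneMask, NodeKey

__all__ = [
    "Zone",
    "SceneSpec",
    "NoiseSpec",
    "TrueNucleus",
    "GroundTruth",
    "PackingError",
    "generate_scene",
    "emit_detections",
    "true_mask_labels",
    "curve_capsule_mask",
    "stripe_signal",
    "paint_area_fraction",
    "notoroid_cohort",
    "lognormal_mixture",
    "colony_cell_table",
    "clustered_hcr_table",
]


class PackingError(RuntimeError):
    """Raised when the requested number of nuclei cannot be placed."""


@dataclass
class Zone:
    """A named spatial class with its marker intensity means.

    For disc geometry, membership is by normalized radius ``r/R`` in
    ``r_range``. For capsule geometry, by normalized axial position
    ``s`` in ``s_range`` and signed transverse position ``t`` (=
    y-offset / half-width, in [-1, 1]) in ``t_range``. Zones are tested in
    layout order; the first match wins. ``paint`` additionally paints the
    zone's footprint into the intensity stack (used for reporter stripes).
    """

    name: str
    markers: Dict[str, float]
    r_range: Tuple[float, float] = (0.0, 1.0)
    s_range: Tuple[float, float] = (0.0, 1.0)
    t_range: Tuple[float, float] = (-1.0, 1.0)
    paint: bool = False


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Dimensions in µm. ``nucleus_radius_mean``/``sd`` set the xy semi-axes of
    the ellipsoidal nuclei (~4 µm for a typical epiblast-like nucleus); the
    z semi-axis gets a mild random anisotropy factor. Defaults emulate a
    confocal stack at 1 µm lateral pixels and 1 µm z-steps.
    """

    geometry: str  # "disc" | "capsule"
    n_nuclei: int
    diameter: float = 200.0  # disc
    length: float = 400.0  # capsule
    width: float = 120.0  # capsule
    nucleus_radius_mean: float = 4.0
    nucleus_radius_sd: float = 0.5
    z_planes: int = 16
    pixel_size_xy: float = 1.0
    z_spacing: float = 1.0
    class_layout: List[Zone] = field(default_factory=list)
    background_markers: Dict[str, float] = field(default_factory=dict)
    background_level: float = 2.0
    intensity_sd: float = 3.0
    nucleus_cv: float = 0.1  # cell-to-cell lognormal variability of means
    rng_seed: int = 0
    max_attempts_per_nucleus: int = 400

    def __post_init__(self) -> None:
        if self.geometry not in ("disc", "capsule"):
            raise ValueError("geometry must be 'disc' or 'capsule'")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")

    # -- canonical layouts -------------------------------------------------

    @classmethod
    def micropattern(cls, diameter: float = 200.0, n_nuclei: int = 150, **kw) -> "SceneSpec":
        """Disc colony with a TBXT-high edge ring, SOX2-high centre and a
        double-positive intermediate ring."""
        layout = [
            Zone("TBXT_edge", {"TBXT": 120.0, "SOX2": 8.0}, r_range=(0.8, 1.01)),
            Zone("double_positive", {"TBXT": 60.0, "SOX2": 60.0}, r_range=(0.5, 0.8)),
            Zone("SOX2_centre", {"TBXT": 8.0, "SOX2": 120.0}, r_range=(0.0, 0.5)),
        ]
        kw.setdefault("class_layout", layout)
        kw.setdefault("background_markers", {"TBXT": 8.0, "SOX2": 8.0})
        return cls(geometry="disc", diameter=diameter, n_nuclei=n_nuclei, **kw)

    @classmethod
    def notoroid(
        cls,
        length: float = 400.0,
        width: float = 120.0,
        n_nuclei: int = 250,
        stripe_coverage: float = 0.4,
        **kw,
    ) -> "SceneSpec":
        """Capsule organoid with a midline reporter stripe plus ventral
        floor-plate and distal dorsal zones (for distance analyses)."""
        s0 = 0.5 - stripe_coverage / 2.0
        s1 = 0.5 + stripe_coverage / 2.0
        layout = [
            Zone(
                "notochord",
                {"reporter": 150.0, "TBXT": 120.0, "PAX6": 5.0},
                s_range=(s0, s1),
                t_range=(-0.18, 0.18),
                paint=True,
            ),
            Zone("floor_plate", {"reporter": 10.0, "TBXT": 10.0, "PAX6": 8.0}, t_range=(0.18, 0.5)),
            Zone("dorsal", {"reporter": 5.0, "TBXT": 5.0, "PAX6": 120.0}, t_range=(0.75, 1.01)),
        ]
        kw.setdefault("class_layout", layout)
        kw.setdefault("background_markers", {"reporter": 5.0, "TBXT": 5.0, "PAX6": 5.0})
        return cls(geometry="capsule", length=length, width=width, n_nuclei=n_nuclei, **kw)

    # -- geometry helpers --------------------------------------------------

    @property
    def shape(self) -> Tuple[int, int, int]:
        px = self.pixel_size_xy
        if self.geometry == "disc":
            n = int(math.ceil(self.diameter / px)) + 4
            return (self.z_planes, n, n)
        ny = int(math.ceil(self.width / px)) + 4
        nx = int(math.ceil(self.length / px)) + 4
        return (self.z_planes, ny, nx)

    @property
    def center_um(self) -> Tuple[float, float]:
        _, ny, nx = self.shape
        return (nx * self.pixel_size_xy / 2.0, ny * self.pixel_size_xy / 2.0)

    @property
    def channel_names(self) -> List[str]:
        names: List[str] = []
        for z in self.class_layout:
            for m in z.markers:
                if m not in names:
                    names.append(m)
        for m in self.background_markers:
            if m not in names:
                names.append(m)
        return names

    def _inside(self, x: float, y: float, margin: float) -> bool:
        cx, cy = self.center_um
        if self.geometry == "disc":
            return math.hypot(x - cx, y - cy) <= self.diameter / 2.0 - margin
        # distance to the central segment of the stadium
        half = max(self.length / 2.0 - self.width / 2.0, 0.0)
        dx = max(abs(x - cx) - half, 0.0)
        return math.hypot(dx, y - cy) <= self.width / 2.0 - margin

    def normalized_coords(self, x: float, y: float) -> Tuple[float, float, float]:
        """(r/R, s, t) of a point; unused coordinates are 0."""
        cx, cy = self.center_um
        if self.geometry == "disc":
            return (math.hypot(x - cx, y - cy) / (self.diameter / 2.0), 0.0, 0.0)
        s = (x - (cx - self.length / 2.0)) / self.length
        t = (y - cy) / (self.width / 2.0)
        return (0.0, s, t)

    def classify(self, x: float, y: float) -> Tuple[str, Dict[str, float]]:
        r, s, t = self.normalized_coords(x, y)
        for zone in self.class_layout:
            if self.geometry == "disc":
                if zone.r_range[0] <= r < zone.r_range[1]:
                    return zone.name, zone.markers
            else:
                if (
                    zone.s_range[0] <= s < zone.s_range[1]
                    and zone.t_range[0] <= t < zone.t_range[1]
                ):
                    return zone.name, zone.markers
        return "other", self.background_markers


@dataclass
class NoiseSpec:
    """Detector imperfection model for :func:`emit_detections`."""

    miss_prob: float = 0.0
    split_prob: float = 0.0
    merge_prob: float = 0.0
    jitter_px: int = 0
    intensity_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.miss_prob, self.split_prob, self.merge_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class TrueNucleus:
    nucleus_id: int
    center: Tuple[float, float, float]  # (x, y, z) µm
    semi_axes: Tuple[float, float]  # (xy, z) µm
    zone: str
    channel_means: Dict[str, float]
    voxels: np.ndarray  # (M, 3) (z, row, col)


@dataclass
class GroundTruth:
    spec: SceneSpec
    nuclei: List[TrueNucleus]
    shape: Tuple[int, int, int]
    channel_names: List[str]
    mask_to_nucleus: Dict[NodeKey, int] = field(default_factory=dict)
    merged_masks: Set[NodeKey] = field(default_factory=set)
    split_masks: Set[NodeKey] = field(default_factory=set)
    events: Dict[str, int] = field(default_factory=dict)

    def label_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=np.uint16)
        for nuc in self.nuclei:
            v = nuc.voxels
            vol[v[:, 0], v[:, 1], v[:, 2]] = nuc.nucleus_id
        return vol


# ---------------------------------------------------------------------------
# scene generation


def _voxelize_ellipsoid(
    center: Tuple[float, float, float],
    a_xy: float,
    c_z: float,
    spec: SceneSpec,
) -> np.ndarray:
    px, zs = spec.pixel_size_xy, spec.z_spacing
    xc, yc, zc = center
    nz, ny, nx = spec.shape
    z0 = max(int((zc - c_z) / zs - 0.5), 0)
    z1 = min(int((zc + c_z) / zs + 0.5) + 1, nz)
    r0 = max(int((yc - a_xy) / px - 0.5), 0)
    r1 = min(int((yc + a_xy) / px + 0.5) + 1, ny)
    c0 = max(int((xc - a_xy) / px - 0.5), 0)
    c1 = min(int((xc + a_xy) / px + 0.5) + 1, nx)
    zi, ri, ci = np.mgrid[z0:z1, r0:r1, c0:c1]
    xs = (ci + 0.5) * px
    ys = (ri + 0.5) * px
    zv = (zi + 0.5) * zs
    inside = ((xs - xc) / a_xy) ** 2 + ((ys - yc) / a_xy) ** 2 + ((zv - zc) / c_z) ** 2 <= 1.0
    vox = np.column_stack((zi[inside], ri[inside], ci[inside]))
    if len(vox) == 0:  # guarantee one voxel for pathologically small nuclei
        vox = np.array(
            [[min(max(int(zc / zs), 0), nz - 1), min(max(int(yc / px), 0), ny - 1), min(max(int(xc / px), 0), nx - 1)]],
            dtype=np.int64,
        )
    return vox.astype(np.int64)


def _zone_footprint(zone: Zone, spec: SceneSpec) -> np.ndarray:
    """Boolean (Y, X) footprint of a capsule zone, for painted stripes."""
    nz, ny, nx = spec.shape
    px = spec.pixel_size_xy
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    xs = (cols + 0.5) * px
    ys = (rows + 0.5) * px
    cx, cy = spec.center_um
    s = (xs - (cx - spec.length / 2.0)) / spec.length
    t = (ys - cy) / (spec.width / 2.0)
    return (
        (s >= zone.s_range[0])
        & (s < zone.s_range[1])
        & (t >= zone.t_range[0])
        & (t < zone.t_range[1])
    )


def generate_scene(
    spec: SceneSpec, render: bool = True
) -> Tuple[Optional[np.ndarray], GroundTruth]:
    """Place, classify and (optionally) render a synthetic scene.

    Returns ``(stack, truth)`` where ``stack`` is a ``(C, Z, Y, X)`` float32
    intensity array (or None with ``render=False``; placement draws are
    unaffected). Deterministic given ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    px, zs = spec.pixel_size_xy, spec.z_spacing
    nz, ny, nx = spec.shape
    z_extent = nz * zs

    centers: List[Tuple[float, float, float]] = []
    radii: List[float] = []
    nuclei: List[TrueNucleus] = []
    placed = np.empty((0, 3))
    reach = np.empty((0,))
    for i in range(spec.n_nuclei):
        ok = False
        for _ in range(spec.max_attempts_per_nucleus):
            r_xy = max(float(rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_sd)), 1.0)
            aniso = float(np.clip(rng.normal(1.0, 0.1), 0.7, 1.3))
            c_z = r_xy * aniso
            if spec.geometry == "disc":
                rr = (spec.diameter / 2.0 - r_xy) * math.sqrt(rng.random())
                th = rng.random() * 2 * math.pi
                cx0, cy0 = spec.center_um
                x, y = cx0 + rr * math.cos(th), cy0 + rr * math.sin(th)
            else:
                cx0, cy0 = spec.center_um
                x = cx0 + (rng.random() - 0.5) * spec.length
                y = cy0 + (rng.random() - 0.5) * spec.width
                if not spec._inside(x, y, r_xy):
                    continue
            zlo, zhi = c_z, max(z_extent - c_z, c_z)
            z = zlo + rng.random() * (zhi - zlo)
            cand = np.array([x, y, z])
            # cylindrical (xy) exclusion: like nuclei in an epithelial sheet,
            # no nucleus sits directly above another — which also guarantees
            # that noise-free detections are exactly consolidatable
            if len(placed) and np.any(
                np.hypot(placed[:, 0] - x, placed[:, 1] - y) < reach + r_xy + 0.5
            ):
                continue
            placed = np.vstack([placed, cand])
            reach = np.append(reach, r_xy)
            centers.append((x, y, z))
            radii.append(r_xy)
            zone, means = spec.classify(x, y)
            jitter = {
                m: v * float(np.exp(rng.normal(0.0, spec.nucleus_cv))) for m, v in means.items()
            }
            vox = _voxelize_ellipsoid((x, y, z), r_xy, c_z, spec)
            nuclei.append(
                TrueNucleus(
                    nucleus_id=i + 1,
                    center=(x, y, z),
                    semi_axes=(r_xy, c_z),
                    zone=zone,
                    channel_means=jitter,
                    voxels=vox,
                )
            )
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could only place {len(nuclei)} of {spec.n_nuclei} nuclei "
                f"in the requested geometry"
            )

    channel_names = spec.channel_names
    truth = GroundTruth(spec=spec, nuclei=nuclei, shape=spec.shape, channel_names=channel_names)
    if not render:
        return None, truth

    stack = rng.normal(spec.background_level, spec.intensity_sd, size=(len(channel_names), nz, ny, nx)).astype(np.float32)
    # painted zones (reporter stripes) under the nuclei
    for zone in spec.class_layout:
        if zone.paint and spec.geometry == "capsule":
            fp = _zone_footprint(zone, spec)
            for ci, name in enumerate(channel_names):
                lvl = zone.markers.get(name)
                if lvl is not None and lvl > spec.background_level:
                    stack[ci, :, fp] += lvl * 0.5
    for nuc in nuclei:
        v = nuc.voxels
        for ci, name in enumerate(channel_names):
            mean = nuc.channel_means.get(name, spec.background_markers.get(name, spec.background_level))
            stack[ci, v[:, 0], v[:, 1], v[:, 2]] = mean + rng.normal(
                0.0, spec.intensity_sd, size=len(v)
            )
    np.clip(stack, 0.0, None, out=stack)
    return stack, truth


# ---------------------------------------------------------------------------
# detection emission


def _split_pixels(pix: np.ndarray) -> Optional[Tuple[np.ndarray, np.ndarray]]:
    r_span = pix[:, 0].max() - pix[:, 0].min()
    c_span = pix[:, 1].max() - pix[:, 1].min()
    axis = 0 if r_span >= c_span else 1
    cut = np.median(pix[:, axis])
    lo = pix[pix[:, axis] <= cut]
    hi = pix[pix[:, axis] > cut]
    if len(lo) == 0 or len(hi) == 0:
        return None
    return lo, hi


def _jitter_pixels(pix: np.ndarray, amount: int, grow: bool, shape: Tuple[int, int]) -> np.ndarray:
    r0, c0 = pix[:, 0].min() - amount - 1, pix[:, 1].min() - amount - 1
    r1, c1 = pix[:, 0].max() + amount + 2, pix[:, 1].max() + amount + 2
    crop = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    crop[pix[:, 0] - r0, pix[:, 1] - c0] = True
    struct = ndi.generate_binary_structure(2, 2)
    if grow:
        crop = ndi.binary_dilation(crop, struct, iterations=amount)
    else:
        eroded = ndi.binary_erosion(crop, struct, iterations=amount)
        if not eroded.any():
            return pix
        crop = eroded
    rr, cc = np.nonzero(crop)
    rr, cc = rr + r0, cc + c0
    keep = (rr >= 0) & (cc >= 0) & (rr < shape[0]) & (cc < shape[1])
    out = np.column_stack((rr[keep], cc[keep]))
    return out if len(out) else pix


def _codes(pix: np.ndarray, width: int) -> np.ndarray:
    return pix[:, 0].astype(np.int64) * width + pix[:, 1]


def _dilated_codes(pix: np.ndarray, width: int) -> np.ndarray:
    base = _codes(pix, width)
    out = [base + dr * width + dc for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    return np.unique(np.concatenate(out))


def emit_detections(
    truth: GroundTruth,
    noise: NoiseSpec,
    rng: Optional[np.random.Generator] = None,
) -> List[PlaneMask]:
    """Slice true nuclei into per-plane masks and degrade them.

    Applies, per (nucleus, plane): miss, split and boundary jitter; then, per
    plane, merges of abutting mask pairs from different nuclei. Provenance is
    recorded on ``truth`` (``mask_to_nucleus`` maps every emitted mask to its
    dominant true nucleus; merge/split products are flagged) together with
    event counts under ``truth.events``.
    """
    if rng is None:
        rng = np.random.default_rng(truth.spec.rng_seed + 1)
    spec = truth.spec
    nz, ny, nx = truth.shape
    events = {"eligible": 0, "miss": 0, "split": 0, "merge": 0, "merge_candidates": 0}
    # stage 1: per-nucleus per-plane pieces
    pieces: Dict[int, List[Tuple[int, np.ndarray, bool]]] = {z: [] for z in range(nz)}
    for nuc in truth.nuclei:
        v = nuc.voxels
        for z in np.unique(v[:, 0]):
            pix = v[v[:, 0] == z][:, 1:]
            events["eligible"] += 1
            if rng.random() < noise.miss_prob:
                events["miss"] += 1
                continue
            parts: List[Tuple[np.ndarray, bool]] = [(pix, False)]
            if rng.random() < noise.split_prob:
                halves = _split_pixels(pix)
                if halves is not None:
                    events["split"] += 1
                    parts = [(halves[0], True), (halves[1], True)]
            for ppix, was_split in parts:
                if noise.jitter_px > 0:
                    ppix = _jitter_pixels(ppix, noise.jitter_px, bool(rng.random() < 0.5), (ny, nx))
                pieces[int(z)].append((nuc.nucleus_id, ppix, was_split))

    # stage 2: merges within planes, then labelling
    masks: List[PlaneMask] = []
    truth.mask_to_nucleus.clear()
    truth.merged_masks.clear()
    truth.split_masks.clear()
    for z in range(nz):
        plane_pieces = pieces[z]
        merged_into: Dict[int, int] = {}
        if noise.merge_prob > 0 and len(plane_pieces) > 1:
            dil = [_dilated_codes(p[1], nx) for p in plane_pieces]
            raw = [_codes(p[1], nx) for p in plane_pieces]
            for i in range(len(plane_pieces)):
                if i in merged_into:
                    continue
                for j in range(i + 1, len(plane_pieces)):
                    if j in merged_into or plane_pieces[i][0] == plane_pieces[j][0]:
                        continue
                    if len(np.intersect1d(dil[i], raw[j], assume_unique=True)) == 0:
                        continue
                    events["merge_candidates"] += 1
                    if rng.random() < noise.merge_prob:
                        merged_into[j] = i
                        events["merge"] += 1
                        break
        label = 0
        groups: Dict[int, List[int]] = {}
        for idx in range(len(plane_pieces)):
            root = merged_into.get(idx, idx)
            groups.setdefault(root, []).append(idx)
        for root in sorted(groups):
            members = groups[root]
            label += 1
            pix = np.vstack([plane_pieces[i][1] for i in members])
            mask = PlaneMask(z, label, pix, spec.pixel_size_xy, spec.z_spacing)
            masks.append(mask)
            # dominant true nucleus by contributed pixel count
            sizes = {plane_pieces[i][0]: len(plane_pieces[i][1]) for i in members}
            dominant = max(sorted(sizes), key=lambda k: sizes[k])
            truth.mask_to_nucleus[mask.key] = dominant
            if len(members) > 1:
                truth.merged_masks.add(mask.key)
            if any(plane_pieces[i][2] for i in members):
                truth.split_masks.add(mask.key)
    truth.events = events
    return masks


def true_mask_labels(truth: GroundTruth, masks: Sequence[PlaneMask]) -> np.ndarray:
    """Ground-truth nucleus label per emitted mask, aligned with ``masks``."""
    return np.array([truth.mask_to_nucleus[m.key] for m in masks])


# ---------------------------------------------------------------------------
# 2D organoid fixtures (midline morphometrics)


def curve_capsule_mask(
    curve_xy_um: np.ndarray,
    width_um: float,
    pixel_size: float,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Rasterize a tube of ``width_um`` around a polyline.

    Returns ``(mask, s_image, full_length)``: a boolean mask; a float image
    giving every pixel's standardized position along the organoid's long
    axis (NaN outside the mask); and the tip-to-tip length in µm. The
    standardized coordinate is normalized over the full tip-to-tip length —
    centerline arclength plus one cap radius at each end — matching how a
    measured midline spans the mask extremities; cap pixels collapse onto
    the cap entry positions.
    """
    curve = np.asarray(curve_xy_um, dtype=float)
    seg = np.diff(curve, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = float(seg_len.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # dense resample of the curve, ~1/4 pixel spacing
    n_dense = max(int(arclen / (0.25 * pixel_size)), 2)
    s_dense = np.linspace(0.0, arclen, n_dense)
    xs = np.interp(s_dense, cum, curve[:, 0])
    ys = np.interp(s_dense, cum, curve[:, 1])
    pad = width_um / 2.0 + 3 * pixel_size
    x0, y0 = xs.min() - pad, ys.min() - pad
    nx = int(math.ceil((xs.max() + pad - x0) / pixel_size))
    ny = int(math.ceil((ys.max() + pad - y0) / pixel_size))
    # continuous nearest-point assignment: pixel centres against the dense
    # curve samples (raster-quantized centerlines skew the foot point of
    # far-off-axis pixels by several pixels)
    from scipy.spatial import cKDTree

    full_length = arclen + width_um
    tree = cKDTree(np.column_stack((xs, ys)))
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    px_xy = np.column_stack(
        (((cols.ravel() + 0.5) * pixel_size + x0), ((rows.ravel() + 0.5) * pixel_size + y0))
    )
    dist, idx = tree.query(px_xy, k=1)
    mask = (dist <= width_um / 2.0).reshape(ny, nx)
    s_vals = ((s_dense + width_um / 2.0) / full_length)[idx].reshape(ny, nx)
    s_image = np.where(mask, s_vals, np.nan)
    return mask, s_image, full_length


def stripe_signal(
    mask: np.ndarray,
    s_image: np.ndarray,
    s_interval: Tuple[float, float],
    stripe_level: float = 200.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Reporter image: ``stripe_level`` where the normalized arclength lies in
    ``s_interval``, ``background`` elsewhere inside the mask."""
    if rng is None:
        rng = np.random.default_rng(0)
    sig = rng.normal(background, noise_sd, size=mask.shape).astype(np.float32)
    inside = mask & (s_image >= s_interval[0]) & (s_image <= s_interval[1])
    sig[inside] += stripe_level - background
    sig[~mask] = 0.0
    return np.clip(sig, 0.0, None)


def paint_area_fraction(
    mask: np.ndarray,
    s_image: np.ndarray,
    fraction: float,
    level: float = 200.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, float]:
    """Signal image whose bright area is exactly ``fraction`` of the mask.

    The ``k = round(fraction * area)`` pixels closest to the midpoint of the
    centerline (by |s - 0.5|) are painted at ``level``. Returns the image and
    the achieved fraction.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rr, cc = np.nonzero(mask)
    k = int(round(fraction * len(rr)))
    order = np.argsort(np.abs(s_image[rr, cc] - 0.5), kind="stable")
    sel = order[:k]
    sig = rng.normal(background, noise_sd, size=mask.shape).astype(np.float32)
    sig[rr[sel], cc[sel]] = level + rng.normal(0.0, noise_sd, size=k)
    sig[~mask] = 0.0
    achieved = k / len(rr) if len(rr) else 0.0
    return np.clip(sig, 0.0, None), achieved


def _arc_curve(length: float, curvature: float, n: int = 60) -> np.ndarray:
    """Polyline of given arclength: straight if curvature 0, circular arc
    otherwise (curvature in 1/µm)."""
    if abs(curvature) < 1e-9:
        x = np.linspace(0.0, length, n)
        return np.column_stack((x, np.zeros(n)))
    radius = 1.0 / curvature
    theta = np.linspace(0.0, length / radius, n)
    return np.column_stack((radius * np.sin(theta), radius * (1.0 - np.cos(theta))))


def notoroid_cohort(
    n_samples: int,
    seed: int,
    coverage_mean: float = 0.371,
    coverage_sd: float = 0.199,
    pixel_size: float = 4.0,
    length_mean: float = 1260.0,
    length_sd: float = 250.0,
    width_mean: float = 220.0,
    width_sd: float = 30.0,
    couple_area: bool = False,
) -> List[Dict]:
    """Cohort of 2D organoid fixtures with striped reporter signal.

    Stripe axial coverage is drawn from N(coverage_mean, coverage_sd²)
    truncated to [0, 1] and the stripe is centred on the midline, as reporter
    expression concentrates in the middle of the long axis. With
    ``couple_area=True`` a bright-area channel is added whose area fraction
    decreases with total mask area (larger organoids dilute the bright
    domain), for correlation-sign benchmarks.
    """
    rng = np.random.default_rng(seed)
    out: List[Dict] = []
    for _ in range(n_samples):
        length = float(np.clip(rng.normal(length_mean, length_sd), 500.0, 2500.0))
        width = float(np.clip(rng.normal(width_mean, width_sd), 100.0, 400.0))
        coverage = float(np.clip(rng.normal(coverage_mean, coverage_sd), 0.0, 1.0))
        curvature = float(rng.uniform(0.0, 0.5)) / length  # gentle bend
        curve = _arc_curve(length, curvature)
        mask, s_image, full_length = curve_capsule_mask(curve, width, pixel_size)
        sig = stripe_signal(
            mask,
            s_image,
            (0.5 - coverage / 2.0, 0.5 + coverage / 2.0),
            rng=rng,
        )
        rec = {
            "mask": mask,
            "signal": sig,
            "s_image": s_image,
            "pixel_size": pixel_size,
            "true_length": full_length,
            "true_coverage": coverage,
        }
        if couple_area:
            area = float(mask.sum()) * pixel_size**2
            # larger organoid -> smaller bright fraction, plus noise
            frac = float(np.clip(0.07 - 0.04 * (area - 2.0e5) / 2.0e5 + rng.normal(0.0, 0.01), 0.003, 0.15))
            bright, achieved = paint_area_fraction(mask, s_image, frac, rng=rng)
            rec.update({"bright": bright, "true_area_fraction": achieved, "area_um2": area})
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# tabular generators (marker levels, clustering)


def lognormal_mixture(
    n: int,
    seed: int,
    log_means: Sequence[float] = (1.0, 3.2, 5.4),
    log_sds: Sequence[float] = (0.35, 0.35, 0.35),
    weights: Sequence[float] = (0.4, 0.35, 0.25),
) -> Tuple[np.ndarray, np.ndarray]:
    """Well-separated 3-component log-normal intensity mixture.

    Returns (values, component labels 0/1/2 ordered by mean).
    """
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(weights), size=n, p=np.asarray(weights) / np.sum(weights))
    mu = np.asarray(log_means)[labels]
    sd = np.asarray(log_sds)[labels]
    values = np.exp(rng.normal(mu, sd))
    return values, labels


_CLASS_LEVELS = {
    # (SOX2, TBXT) target levels per gated class; absent/low/high
    "SOX2_only": ("high", "absent"),
    "TBXT_only": ("absent", "high"),
    "double_positive": ("low", "low"),
    "other": ("absent", "absent"),
}
_LEVEL_LOGMEAN = {"absent": math.log(2.0), "low": math.log(30.0), "high": math.log(300.0)}


def colony_cell_table(
    n: int,
    proportions: Dict[str, float],
    seed: int,
    n_colonies: int = 1,
    level_sd: float = 0.3,
):
    """Cell table with SOX2/TBXT intensities drawn per gated class.

    Intensities are log-normal around class-typical levels such that manual
    thresholds (10, 100) recover the generating level. Returns a pandas
    DataFrame with columns colony_id, true_class, mean_SOX2, mean_TBXT.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    names = list(proportions)
    p = np.array([proportions[c] for c in names], dtype=float)
    classes = rng.choice(len(names), size=n, p=p / p.sum())
    sox, tbxt = [], []
    for c in classes:
        lv_s, lv_t = _CLASS_LEVELS[names[c]]
        sox.append(np.exp(rng.normal(_LEVEL_LOGMEAN[lv_s], level_sd)))
        tbxt.append(np.exp(rng.normal(_LEVEL_LOGMEAN[lv_t], level_sd)))
    return_df = {
        "cell_id": np.arange(1, n + 1),
        "colony_id": rng.integers(0, n_colonies, size=n) + 1,
        "true_class": [names[c] for c in classes],
        "mean_SOX2": np.asarray(sox),
        "mean_TBXT": np.asarray(tbxt),
    }
    return pd.DataFrame(return_df)


def clustered_hcr_table(
    n_per_cluster: int,
    seed: int,
    markers: Sequence[str] = ("CHRD", "LEFTY1", "SPRY2"),
    k: int = 3,
    snr: float = 4.0,
    sigma: float = 0.25,
):
    """Synthetic per-cell HCR table with k log-space populations.

    Cluster log-mean vectors sit at the vertices of a regular simplex
    (randomly rotated), with centre-to-centre separation ``snr`` times the
    r.m.s. noise magnitude sigma·√d (d = number of markers, isotropic
    per-marker noise sigma).
    """
    import pandas as pd

    d = len(markers)
    if k > d + 1:
        raise ValueError("need k <= n_markers + 1 for a regular simplex of centers")
    rng = np.random.default_rng(seed)
    sep = snr * sigma * math.sqrt(d)
    simplex = np.eye(k, d)
    simplex -= simplex.mean(axis=0)
    simplex *= sep / np.linalg.norm(simplex[0] - simplex[1])
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    centers = simplex @ q.T
    rows = []
    for c in range(k):
        logv = rng.normal(centers[c] + 3.0, sigma, size=(n_per_cluster, len(markers)))
        rows.append(logv)
    logv = np.vstack(rows)
    labels = np.repeat(np.arange(k), n_per_cluster)
    df = pd.DataFrame(np.exp(logv), columns=[f"mean_{m}" for m in markers])
    df.insert(0, "cell_id", np.arange(1, len(df) + 1))
    df["true_cluster"] = labels
    return df
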