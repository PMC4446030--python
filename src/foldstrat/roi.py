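"""Fold midline construction and placement of paired circular ROIs.

Measurements are taken in pairs of congruent circular ROIs at regular
stations along a midline that runs from just below the epithelium to the
deep end of the fold.  The midline follows the medial axis of the fold
mask (per depth row, the ridge of the distance transform); the two ROIs of
a station flank the midline symmetrically, offset perpendicular to it by
one ROI radius, so a pair samples the tissue on both sides of the midline
at one depth.  Measurement ROIs are 35 um in diameter; scoring ROIs 70 um.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as _cc_label

from .segmentation import CircularROI, GeometryError, roi_pixel_indices


@dataclass
class Midline:
    """Polyline (um coordinates) from the subepithelial start point to the
    deep end of the fold, monotone in depth."""

    points: np.ndarray            # (N, 2) columns (x_um, y_um)
    fold_mask: np.ndarray
    epithelium_mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("midline points must be an (N, 2) array")
        seg = np.diff(self.points, axis=0)
        self._cumlen = np.concatenate(
            [[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    @property
    def total_length_um(self) -> float:
        return float(self._cumlen[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Interpolated (x, y) um at arc length ``s`` from the start."""
        s = float(np.clip(s, 0.0, self.total_length_um))
        x = np.interp(s, self._cumlen, self.points[:, 0])
        y = np.interp(s, self._cumlen, self.points[:, 1])
        return np.array([x, y])

    def normal_at(self, s: float, window_um: float = 10.0) -> np.ndarray:
        """Unit normal to the midline at arc length ``s``."""
        a = self.point_at(max(s - window_um, 0.0))
        b = self.point_at(min(s + window_um, self.total_length_um))
        t = b - a
        norm = np.hypot(*t)
        if norm == 0:
            return np.array([1.0, 0.0])
        t /= norm
        return np.array([-t[1], t[0]])


def build_midline(fold_mask: np.ndarray, epithelium_mask: np.ndarray,
                  pixel_size_um: float) -> Midline:
    """Medial-axis midline of the fold mask, starting below the epithelium.

    For every depth row of the fold mask the midline passes through the
    ridge of the Euclidean distance transform (the mean of the columns at
    the row's maximum distance-to-boundary), which traces the medial axis
    for the elongated fold geometries sampled here and spans the full
    depth of the mask.
    """
    fold_mask = np.asarray(fold_mask, dtype=bool)
    if not fold_mask.any():
        raise ValueError("fold mask is empty")
    if _cc_label(fold_mask, connectivity=2).max() != 1:
        raise ValueError("fold mask must be a single connected component")
    interior = fold_mask & ~np.asarray(epithelium_mask, dtype=bool)
    # pad so the image border counts as fold boundary
    dt = ndimage.distance_transform_edt(np.pad(fold_mask, 1))[1:-1, 1:-1]
    px = pixel_size_um
    pts = []
    rows = np.flatnonzero(interior.any(axis=1))
    for r in rows:
        row = np.where(interior[r], dt[r], -np.inf)
        ridge_cols = np.flatnonzero(row == row.max())
        c = ridge_cols.mean()
        pts.append(((c + 0.5) * px, (r + 0.5) * px))
    if len(pts) < 2:
        raise ValueError("fold mask too shallow to carry a midline")
    # extend the half-pixel stubs at both ends so the midline spans the
    # exact depth extent, from the epithelium boundary to the deep edge
    pts.insert(0, (pts[0][0], rows[0] * px))
    pts.append((pts[-1][0], (rows[-1] + 1) * px))
    return Midline(points=np.array(pts), fold_mask=fold_mask,
                   epithelium_mask=np.asarray(epithelium_mask, dtype=bool),
                   pixel_size_um=px)


@dataclass(frozen=True)
class ROIPair:
    """Two congruent circular ROIs flanking the midline at one depth
    station; ``depth_um`` is the arc length from the midline start."""

    station_index: int
    depth_um: float
    roi_a: CircularROI
    roi_b: CircularROI
    diameter_um: float


def _roi_inside(roi: CircularROI, fold_mask: np.ndarray,
                epithelium_mask: np.ndarray, px: float) -> bool:
    try:
        rr, cc = roi_pixel_indices(roi, fold_mask.shape, px)
    except GeometryError:
        return False
    if rr.size == 0:
        return False
    return bool(fold_mask[rr, cc].all() and not epithelium_mask[rr, cc].any())


def place_roi_pairs(midline: Midline, diameter_um: float,
                    spacing_um: float | None = None, *,
                    offset_factor: float = 1.0) -> list[ROIPair]:
    """Place ROI pairs at regular depth stations along the midline.

    Stations start one radius below the midline start (so the first circle
    abuts the epithelium boundary) and advance by ``spacing_um`` (default:
    one diameter, giving contiguous non-overlapping coverage).  At each
    station the two ROIs are offset perpendicular to the midline by
    ``offset_factor`` radii to either side.  Pairs whose circles would
    leave the fold mask or touch the epithelium are dropped; the
    corresponding stations simply yield no measurement (downstream they
    surface as missing subunits).
    """
    if spacing_um is None:
        spacing_um = diameter_um
    if spacing_um < diameter_um:
        raise ValueError("spacing_um must be >= diameter_um (non-overlap)")
    radius = diameter_um / 2.0
    length = midline.total_length_um
    if length < diameter_um:
        warnings.warn("midline shorter than one ROI diameter; no pairs "
                      "placed", stacklevel=2)
        return []
    pairs = []
    station = 0
    s = radius
    while s + radius <= length + 1e-9:
        p = midline.point_at(s)
        n = midline.normal_at(s)
        shift = offset_factor * radius * n
        roi_a = CircularROI(*(p - shift), diameter_um)
        roi_b = CircularROI(*(p + shift), diameter_um)
        if (_roi_inside(roi_a, midline.fold_mask, midline.epithelium_mask,
                        midline.pixel_size_um)
                and _roi_inside(roi_b, midline.fold_mask,
                                midline.epithelium_mask,
                                midline.pixel_size_um)):
            pairs.append(ROIPair(station_index=station, depth_um=s,
                                 roi_a=roi_a, roi_b=roi_b,
                                 diameter_um=diameter_um))
        station += 1
        s += spacing_um
    return pairs


def write_roi_csv(pairs: list[ROIPair], path) -> None:
    """Serialise ROI pairs so real annotated images can substitute for
    synthetic ones."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["station", "depth_um", "ax_um", "ay_um",
                         "bx_um", "by_um", "diameter_um"])
        for p in pairs:
            writer.writerow([p.station_index, p.depth_um,
                             p.roi_a.cx_um, p.roi_a.cy_um,
                             p.roi_b.cx_um, p.roi_b.cy_um, p.diameter_um])


def read_roi_csv(path) -> list[ROIPair]:
    pairs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            d = float(row["diameter_um"])
            pairs.append(ROIPair(
                station_index=int(row["station"]),
                depth_um=float(row["depth_um"]),
                roi_a=CircularROI(float(row["ax_um"]), float(row["ay_um"]), d),
                roi_b=CircularROI(float(row["bx_um"]), float(row["by_um"]), d),
                diameter_um=d))
    return pairs
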