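"""Semi-quantitative scoring of collagen structure diameters.

Collagen objects (fibres and fibre bundles) inside 70 um ROIs are counted
in three diameter categories — small fibres/bundles of 2-4 um,
intermediate bundles of >4-10 um, large bundles of >10 um — and each
count maps to a score of 0-3 through category-specific thresholds:

    small:        0 -> 0, 1-4 -> 1, 5-10 -> 2, >10 -> 3
    intermediate: 0 -> 0, 1-3 -> 1, 4-8  -> 2, >8  -> 3
    large:        0 -> 0, 1-2 -> 1, 3-4  -> 2, >4  -> 3

Object diameters are measured automatically as twice the median
medial-axis distance-transform value along the object's skeleton — a
reproducible proxy for the visual diameter judgement of a trained
observer.  Structures thinner than 2 um are not scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .segmentation import CircularROI, FibreMask, roi_pixel_indices

#: Ordered diameter categories with (lo, hi] bounds in um; diameters below
#: 2 um are uncategorised.
SIZE_CATEGORIES: tuple[tuple[str, float, float], ...] = (
    ("small", 2.0, 4.0),
    ("intermediate", 4.0, 10.0),
    ("large", 10.0, float("inf")),
)
CATEGORY_NAMES = tuple(name for name, _, _ in SIZE_CATEGORIES)

_SCORE_BINS = {
    # upper count bound (inclusive) -> score
    "small": ((0, 0), (4, 1), (10, 2)),
    "intermediate": ((0, 0), (3, 1), (8, 2)),
    "large": ((0, 0), (2, 1), (4, 2)),
}


def categorise(diameter_um: float) -> str | None:
    """Diameter category name, or None for sub-2-um structures.

    Boundary diameters fall into the lower category (2-4, >4-10, >10).
    """
    if diameter_um < SIZE_CATEGORIES[0][1]:
        return None
    for name, lo, hi in SIZE_CATEGORIES:
        if lo <= diameter_um <= hi:
            return name
    return None


def score_count(category: str, count: int) -> int:
    """Map an object count to the 0-3 score of its diameter category."""
    if category not in _SCORE_BINS:
        raise ValueError(f"unknown size category {category!r}")
    if count < 0:
        raise ValueError("count must be non-negative")
    for upper, score in _SCORE_BINS[category]:
        if count <= upper:
            return score
    return 3


def object_diameters(fibre_mask: FibreMask, roi: CircularROI,
                     pixel_size_um: float) -> list[float]:
    """Diameters (um) of mask objects attributed to a circular ROI.

    Each 8-connected component whose skeleton lies at least half inside
    the ROI is measured; its diameter is twice the median Euclidean
    distance-transform value along the skeleton, converted to um.  The
    half-inside rule is the deterministic tie-break for objects straddling
    the ROI border.
    """
    px = pixel_size_um
    rr, cc = roi_pixel_indices(roi, fibre_mask.shape, px)
    labels, _ = ndimage.label(fibre_mask.mask,
                              structure=np.ones((3, 3), dtype=int))
    touched = np.unique(labels[rr, cc])
    touched = touched[touched > 0]
    if touched.size == 0:
        return []

    inside = np.zeros(fibre_mask.shape, dtype=bool)
    inside[rr, cc] = True
    diameters = []
    objects = ndimage.find_objects(labels)
    for lab in touched:
        sl = objects[lab - 1]
        # pad the crop by one pixel so the distance transform sees the
        # object's true boundary
        r0 = max(sl[0].start - 1, 0)
        r1 = min(sl[0].stop + 1, fibre_mask.shape[0])
        c0 = max(sl[1].start - 1, 0)
        c1 = min(sl[1].stop + 1, fibre_mask.shape[1])
        comp = labels[r0:r1, c0:c1] == lab
        skel = skeletonize(comp)
        if not skel.any():
            skel = comp  # single-pixel objects
        n_in = int((skel & inside[r0:r1, c0:c1]).sum())
        if n_in * 2 < int(skel.sum()):
            continue
        dt = ndimage.distance_transform_edt(comp)
        diameters.append(float(2.0 * np.median(dt[skel]) * px))
    return diameters


@dataclass(frozen=True)
class ScoreRecord:
    """Counts and scores of one ROI station, per diameter category."""

    station_index: int
    counts: dict[str, int]
    scores: dict[str, int]


def score_roi(fibre_mask: FibreMask, roi: CircularROI,
              pixel_size_um: float, station_index: int = 0) -> ScoreRecord:
    """Count categorised objects in one ROI and score the counts."""
    counts = dict.fromkeys(CATEGORY_NAMES, 0)
    for d in object_diameters(fibre_mask, roi, pixel_size_um):
        cat = categorise(d)
        if cat is not None:
            counts[cat] += 1
    scores = {cat: score_count(cat, n) for cat, n in counts.items()}
    return ScoreRecord(station_index=station_index, counts=counts,
                       scores=scores)


def score_table(records: list[tuple[int, ScoreRecord]],
                animal_id: str, fold_type: str) -> pd.DataFrame:
    """Tidy (animal, fold, subunit, category, count, score) table from
    per-station records; ``records`` pairs each record with its subunit."""
    rows = []
    for subunit, rec in records:
        for cat in CATEGORY_NAMES:
            rows.append({"animal": animal_id, "fold": fold_type,
                         "subunit": subunit, "category": cat,
                         "count": rec.counts[cat],
                         "score": rec.scores[cat]})
    return pd.DataFrame(rows)


def median_score_profile(tables: list[pd.DataFrame],
                         n_subunits: int) -> pd.DataFrame:
    """Per-subunit median score over animals, per diameter category.

    Subunits no animal sampled stay missing (NaN), as they do for small
    folds that admit too few ROI pairs.
    """
    if not tables:
        raise ValueError("no score tables given")
    tidy = pd.concat(tables, ignore_index=True)
    med = (tidy.groupby(["subunit", "category"])["score"]
           .median().unstack("category"))
    full = pd.DataFrame(index=pd.RangeIndex(1, n_subunits + 1,
                                            name="subunit"),
                        columns=list(CATEGORY_NAMES), dtype=float)
    full.update(med)
    return full[list(CATEGORY_NAMES)]
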