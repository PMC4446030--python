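"""Virtual two-stain vocal-fold sections with known ground truth.

A section is a coronal rectangle of tissue: an epithelial band on top and
the lamina propria (the connective-tissue body of the fold) below it.  The
lamina propria is split depth-wise into 10 (caudal fold, CauF) or 20
(cranial fold, CraF) proportional subunit bands; each band carries its own
fibre composition.  Collagen structures are rendered into a trichrome-like
image, elastic fibres into a resorcin-fuchsin-like image, and the boolean
fibre masks used for the rendering are kept as ground truth, together with
a per-subunit table of true area fractions and object counts per diameter
category.

Fibres are curvilinear strokes (random walks with bounded curvature) of a
specified width, stamped as overlapping discs; aged elastic material may
additionally be rendered as 5-10 um clumps (filled discs), and aged
cranial-fold superficial collagen may be rendered reddish instead of green,
reproducing the staining anomaly that defeats a green-colour object
definition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk

from . import palette
from .stratigraphy import zone_map_for, n_subunits_for

FOLD_TYPES = ("CraF", "CauF")
AGE_GROUPS = ("young", "old")

#: Diameter categories of collagen structures (um): fibres/small bundles,
#: intermediate bundles, large bundles.
SIZE_CATEGORY_NAMES = ("small", "intermediate", "large")
_CATEGORY_DIAMETER_RANGES = {
    "small": (2.0, 4.0),
    "intermediate": (4.5, 10.0),
    "large": (10.5, 16.0),
}

ELASTIC_FIBRE_DIAMETER_UM = (2.0, 3.5)
ELASTIC_CLUMP_DIAMETER_UM = (5.0, 10.0)
FIBRE_LENGTH_UM = (10.0, 25.0)


class CompositionError(ValueError):
    """A zone composition violates a structural constraint."""


@dataclass(frozen=True)
class SectionSpec:
    """Geometry of one virtual fold section.

    ``lamina_depth_um`` is the depth of the lamina propria below the
    epithelium; a CraF paired with a CauF should be given twice the CauF
    depth, mirroring the fold anatomy (the cranial fold lacks a vocal
    muscle and is about twice as deep in connective tissue).
    """

    fold_type: str
    age_group: str
    lamina_depth_um: float
    epithelium_thickness_um: float = 50.0
    pixel_size_um: float = 0.5
    width_um: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_type not in FOLD_TYPES:
            raise ValueError(f"unknown fold_type {self.fold_type!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age_group {self.age_group!r}")
        for name in ("lamina_depth_um", "epithelium_thickness_um",
                     "pixel_size_um", "width_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pixel_size_um > 1.0:
            raise ValueError(
                "pixel_size_um must be <= 1.0 so that 2 um fibres span "
                ">= 2 pixels")

    @property
    def n_subunits(self) -> int:
        return n_subunits_for(self.fold_type)


@dataclass(frozen=True)
class ZoneComposition:
    """Fibre composition of one proportional depth band (subunit).

    ``collagen_diameter_mix`` weights the three collagen diameter
    categories (small 2-4 um, intermediate >4-10 um, large >10 um);
    ``elastic_clump_fraction`` is the fraction of elastic material rendered
    as 5-10 um clumps rather than fibres (an ageing feature);
    ``collagen_render`` selects the trichrome reaction (``green`` normal,
    ``reddish`` the anomalous aged cranial-fold reaction).
    """

    zone_id: int
    collagen_area_fraction: float
    elastic_area_fraction: float
    collagen_diameter_mix: tuple[float, float, float] = (0.7, 0.3, 0.0)
    elastic_clump_fraction: float = 0.0
    collagen_render: str = "green"

    def __post_init__(self) -> None:
        for name in ("collagen_area_fraction", "elastic_area_fraction",
                     "elastic_clump_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CompositionError(
                    f"zone {self.zone_id}: {name}={v} outside [0, 1]")
        if self.collagen_area_fraction + self.elastic_area_fraction > 1.0:
            raise CompositionError(
                f"zone {self.zone_id}: collagen + elastic fractions exceed 1")
        if self.collagen_render not in ("green", "reddish"):
            raise CompositionError(
                f"zone {self.zone_id}: unknown collagen_render "
                f"{self.collagen_render!r}")
        mix = self.collagen_diameter_mix
        if len(mix) != 3 or any(w < 0 for w in mix) or sum(mix) <= 0:
            raise CompositionError(
                f"zone {self.zone_id}: collagen_diameter_mix must be three "
                "non-negative weights with positive sum")


@dataclass
class StainedSection:
    """A rendered virtual section with its ground truth.

    ``collagen_mask`` / ``elastic_mask`` are the pre-rendering fibre masks;
    ``ground_truth`` is a per-subunit table of true area fractions and true
    collagen object counts per diameter category.
    """

    spec: SectionSpec
    trichrome_image: np.ndarray
    resorcin_image: np.ndarray
    epithelium_mask: np.ndarray
    fold_mask: np.ndarray
    collagen_mask: np.ndarray
    elastic_mask: np.ndarray
    ground_truth: pd.DataFrame
    zones: list[ZoneComposition] = field(default_factory=list)


def validate_zones(spec: SectionSpec,
                   zones: Sequence[ZoneComposition]) -> None:
    """Check per-band compositions against the section's fold and age.

    Elastic clumps are an ageing feature; the reddish trichrome reaction is
    restricted to the superficial zones (Z1-Z3) of the aged cranial fold.
    """
    if len(zones) != spec.n_subunits:
        raise CompositionError(
            f"expected {spec.n_subunits} band compositions for "
            f"{spec.fold_type}, got {len(zones)}")
    zmap = zone_map_for(spec.fold_type)
    reddish_ok = set()
    if spec.fold_type == "CraF" and spec.age_group == "old":
        for z in (1, 2, 3):
            reddish_ok.update(zmap.members[z])
    for idx, zone in enumerate(zones, start=1):
        if zone.zone_id != idx:
            raise CompositionError(
                f"band {idx}: zone_id {zone.zone_id} out of order")
        if zone.elastic_clump_fraction > 0 and spec.age_group != "old":
            raise CompositionError(
                f"zone {idx}: elastic clumps only occur in 'old' tissue")
        if zone.collagen_render == "reddish" and idx not in reddish_ok:
            raise CompositionError(
                f"zone {idx}: reddish collagen rendering only occurs in "
                "zones 1-3 of the old cranial fold")


def _stamp_disc(mask: np.ndarray, r: float, c: float, radius: float,
                row_lo: int, row_hi: int) -> int:
    """Stamp a disc clipped to a row band; return newly set pixel count."""
    rr, cc = _draw_disk((r, c), radius, shape=mask.shape)
    keep = (rr >= row_lo) & (rr < row_hi)
    rr, cc = rr[keep], cc[keep]
    fresh = ~mask[rr, cc]
    mask[rr[fresh], cc[fresh]] = True
    return int(fresh.sum())


def _draw_stroke(mask: np.ndarray, rng: np.random.Generator,
                 row_lo: int, row_hi: int, width_px: float,
                 length_px: float, budget: float) -> tuple[int, float]:
    """Stamp one curvilinear stroke clipped to a band.

    Stamping stops once ``budget`` new pixels have been laid down, so a
    band fill overshoots its target fraction by at most one disc stamp.
    Returns (new pixels, mid row of the path).
    """
    _, w = mask.shape
    # pad starts beyond the band and the image edges so that clipping does
    # not deplete fibre density near any border
    pad = length_px / 2.0
    r = rng.uniform(row_lo - pad, row_hi + pad)
    c = rng.uniform(-pad, w + pad)
    heading = rng.uniform(0.0, 2.0 * np.pi)
    radius = max(width_px / 2.0, 1.0)
    step = max(radius * 0.7, 1.0)
    n_steps = max(int(round(length_px / step)), 1)
    mid = r
    added = 0
    for i in range(n_steps):
        added += _stamp_disc(mask, r, c, radius, row_lo, row_hi)
        if added >= budget:
            break
        heading += rng.uniform(-0.25, 0.25)  # bounded curvature
        r += step * np.sin(heading)
        c += step * np.cos(heading)
        if i == n_steps // 2:
            mid = r
    return added, mid


def _fill_band(mask: np.ndarray, rng: np.random.Generator, row_lo: int,
               row_hi: int, target_fraction: float, *,
               widths_um: Sequence[tuple[str | None, float, float]],
               weights: Sequence[float], pixel_size_um: float,
               clump: Sequence[bool] | None = None) -> list[tuple[str, float]]:
    """Add strokes/clumps to ``mask`` until the band fraction reaches target.

    ``widths_um`` lists (category, lo, hi) diameter ranges sampled with
    ``weights``; entries flagged in ``clump`` render as filled discs instead
    of strokes.  Returns (category, mid_row) per object actually drawn.
    """
    band_px = (row_hi - row_lo) * mask.shape[1]
    if band_px <= 0 or target_fraction <= 0:
        return []
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    clump = [False] * len(widths_um) if clump is None else list(clump)
    drawn: list[tuple[str, float]] = []
    count = int(mask[row_lo:row_hi].sum())
    target_px = target_fraction * band_px
    n_objects = 0
    # hard cap against pathological non-convergence at saturation
    max_objects = int(band_px / 2) + 64
    while count < target_px and n_objects < max_objects:
        k = rng.choice(len(widths_um), p=weights)
        cat, lo, hi = widths_um[k]
        diam_px = rng.uniform(lo, hi) / pixel_size_um
        if clump[k]:
            r = rng.uniform(row_lo - diam_px / 2, row_hi + diam_px / 2)
            c = rng.uniform(-diam_px / 2, mask.shape[1] + diam_px / 2)
            added = _stamp_disc(mask, r, c, diam_px / 2.0, row_lo, row_hi)
            mid = r
        else:
            length_px = rng.uniform(*FIBRE_LENGTH_UM) / pixel_size_um
            added, mid = _draw_stroke(mask, rng, row_lo, row_hi, diam_px,
                                      length_px, target_px - count)
        n_objects += 1
        if added > 0 and cat is not None and row_lo <= mid < row_hi:
            drawn.append((cat, mid))
        count += added
    return drawn


def _band_rows(spec: SectionSpec, epi_rows: int, total_rows: int,
               band_index: int) -> tuple[int, int]:
    """Pixel-row interval [lo, hi) of 1-based subunit band ``band_index``."""
    n = spec.n_subunits
    lamina_rows = total_rows - epi_rows
    lo = epi_rows + int(round(lamina_rows * (band_index - 1) / n))
    hi = epi_rows + int(round(lamina_rows * band_index / n))
    return lo, hi


def _render(fibre_mask: np.ndarray, colour_index: np.ndarray,
            colours: Sequence[tuple[int, int, int]],
            epi_mask: np.ndarray, rng: np.random.Generator,
            nuclei_density: float) -> np.ndarray:
    h, w = fibre_mask.shape
    img = np.empty((h, w, 3), dtype=float)
    img[:] = palette.BACKGROUND
    img[epi_mask] = palette.EPITHELIUM
    # sparse fibroblast-nuclei texture (neutral, matches no colour rule)
    n_nuclei = int(nuclei_density * h * w)
    for _ in range(n_nuclei):
        r = rng.uniform(0, h)
        c = rng.uniform(0, w)
        rad = rng.uniform(2.0, 4.0)
        rr, cc = _draw_disk((r, c), rad, shape=(h, w))
        img[rr, cc] = palette.NUCLEI
    for i, colour in enumerate(colours):
        sel = fibre_mask & (colour_index == i)
        img[sel] = colour
    jitter = rng.uniform(1.0 - palette.CHANNEL_JITTER,
                         1.0 + palette.CHANNEL_JITTER, img.shape)
    return np.clip(img * jitter, 0, 255).astype(np.uint8)


def generate_section(spec: SectionSpec,
                     zones: Sequence[ZoneComposition]) -> StainedSection:
    """Render a two-stain virtual section from per-band compositions.

    Deterministic given ``(spec, zones)`` (the seed lives on the spec).
    The rendered per-band fibre fractions match the requested ones to
    within about one stroke's area (well under 2 percentage points at the
    default resolution).
    """
    validate_zones(spec, zones)
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    epi_rows = int(round(spec.epithelium_thickness_um / px))
    total_rows = epi_rows + int(round(spec.lamina_depth_um / px))
    w = int(round(spec.width_um / px))

    epi_mask = np.zeros((total_rows, w), dtype=bool)
    epi_mask[:epi_rows] = True
    fold_mask = np.zeros_like(epi_mask)
    fold_mask[epi_rows:] = True

    collagen = np.zeros_like(epi_mask)
    elastic = np.zeros_like(epi_mask)
    colour_index = np.zeros(epi_mask.shape, dtype=np.uint8)  # 0 green, 1 red

    counts: dict[int, dict[str, int]] = {}
    for zone in zones:
        lo, hi = _band_rows(spec, epi_rows, total_rows, zone.zone_id)
        cat_ranges = [(name,) + _CATEGORY_DIAMETER_RANGES[name]
                      for name in SIZE_CATEGORY_NAMES]
        drawn = _fill_band(
            collagen, rng, lo, hi, zone.collagen_area_fraction,
            widths_um=cat_ranges, weights=zone.collagen_diameter_mix,
            pixel_size_um=px)
        band_counts = dict.fromkeys(SIZE_CATEGORY_NAMES, 0)
        for cat, _ in drawn:
            band_counts[cat] += 1
        counts[zone.zone_id] = band_counts
        if zone.collagen_render == "reddish":
            colour_index[lo:hi] = 1
        # elastic: clumps take their share of the target area first
        cf = zone.elastic_clump_fraction
        if cf > 0:
            _fill_band(elastic, rng, lo, hi,
                       zone.elastic_area_fraction * cf,
                       widths_um=[(None,) + ELASTIC_CLUMP_DIAMETER_UM],
                       weights=[1.0], pixel_size_um=px, clump=[True])
        _fill_band(elastic, rng, lo, hi, zone.elastic_area_fraction,
                   widths_um=[(None,) + ELASTIC_FIBRE_DIAMETER_UM],
                   weights=[1.0], pixel_size_um=px)

    nuclei = 2.0e-4 if spec.age_group == "young" else 0.7e-4
    trichrome = _render(
        collagen, colour_index,
        [palette.COLLAGEN_GREEN, palette.COLLAGEN_REDDISH],
        epi_mask, rng, nuclei)
    resorcin = _render(
        elastic, np.zeros_like(colour_index), [palette.ELASTIC_VIOLET],
        epi_mask, rng, nuclei)

    records = []
    for zone in zones:
        lo, hi = _band_rows(spec, epi_rows, total_rows, zone.zone_id)
        band_px = (hi - lo) * w
        rec = {
            "subunit": zone.zone_id,
            "collagen_fraction": collagen[lo:hi].sum() / band_px,
            "elastic_fraction": elastic[lo:hi].sum() / band_px,
        }
        for cat in SIZE_CATEGORY_NAMES:
            rec[f"n_{cat}"] = counts[zone.zone_id][cat]
        records.append(rec)
    gt = pd.DataFrame.from_records(records).set_index("subunit")

    return StainedSection(
        spec=spec, trichrome_image=trichrome, resorcin_image=resorcin,
        epithelium_mask=epi_mask, fold_mask=fold_mask,
        collagen_mask=collagen, elastic_mask=elastic,
        ground_truth=gt, zones=list(zones))


def _expand_to_subunits(targets: Sequence[float],
                        fold_type: str) -> np.ndarray:
    """Accept per-zone or per-subunit targets; return per-subunit array."""
    n_sub = n_subunits_for(fold_type)
    zmap = zone_map_for(fold_type)
    targets = np.asarray(targets, dtype=float)
    if targets.shape == (n_sub,):
        return targets
    if targets.shape == (len(zmap.members),):
        out = np.empty(n_sub)
        for zid, members in zmap.members.items():
            for s in members:
                out[s - 1] = targets[zid - 1]
        return out
    raise CompositionError(
        f"targets must have length {len(zmap.members)} (zones) or "
        f"{n_sub} (subunits) for {fold_type}, got {len(targets)}")


def calibrate_composition(target_collagen: Sequence[float],
                          target_elastic: Sequence[float],
                          fold_type: str, age_group: str,
                          *, elastic_clump_fraction: float = 0.2,
                          ) -> list[ZoneComposition]:
    """Build per-band compositions whose true fractions hit the targets.

    Targets are area fractions in [0, 1], given per zone or per subunit.
    The generator's stopping rule renders each band to its requested
    fraction, so calibration is the identity on fractions; this routine
    additionally applies the fold/age rendering rules (elastic clumping in
    'old' tissue, reddish collagen in old-CraF zones 1-3, diameter mixes).
    """
    coll = _expand_to_subunits(target_collagen, fold_type)
    elast = _expand_to_subunits(target_elastic, fold_type)
    bad = np.flatnonzero((coll < 0) | (coll > 1) | (elast < 0) | (elast > 1))
    if bad.size:
        raise CompositionError(
            f"band {bad[0] + 1}: target fraction outside [0, 1]")
    bad = np.flatnonzero(coll + elast > 1.0)
    if bad.size:
        raise CompositionError(
            f"band {bad[0] + 1}: combined target fractions exceed 1")

    zmap = zone_map_for(fold_type)
    reddish = set()
    if fold_type == "CraF" and age_group == "old":
        for z in (1, 2, 3):
            reddish.update(zmap.members[z])
    old = age_group == "old"
    zones = []
    for i in range(len(coll)):
        subunit = i + 1
        if old and fold_type == "CraF" and subunit > len(coll) // 2:
            mix = (0.3, 0.4, 0.3)   # aged deep CraF grows large bundles
        elif old:
            mix = (0.5, 0.5, 0.0)   # ageing shifts mass to intermediates
        else:
            mix = (0.7, 0.3, 0.0)
        zones.append(ZoneComposition(
            zone_id=subunit,
            collagen_area_fraction=float(coll[i]),
            elastic_area_fraction=float(elast[i]),
            collagen_diameter_mix=mix,
            elastic_clump_fraction=elastic_clump_fraction if old else 0.0,
            collagen_render="reddish" if subunit in reddish else "green"))
    return zones


# Per-subunit default area-fraction profiles (units: fraction of area).
# Zone-1 elastic values are the observed group means: CauF 0.0972 (young) /
# 0.2562 (old); CraF 0.0555 (young) / 0.3151 (old).  The remaining shapes
# follow the qualitative stratigraphy: a dense subepithelial band, a loose
# superficial layer, a caudal-fold deep collagen re-increase peaking in
# subunit 10, an elastic-rich intermediate layer in the young cranial fold,
# and a graded (demarcation-free) aged caudal-fold collagen profile.
_DEFAULT_PROFILES: dict[tuple[str, str], dict[str, list[float]]] = {
    ("CauF", "young"): {
        "collagen": [0.30, 0.08, 0.08, 0.08, 0.10, 0.12, 0.15,
                     0.18, 0.22, 0.30],
        "elastic": [0.0972, 0.03, 0.03, 0.03, 0.025, 0.025, 0.025,
                    0.03, 0.03, 0.035],
    },
    ("CauF", "old"): {
        "collagen": [0.40, 0.38, 0.36, 0.35, 0.36, 0.37, 0.38,
                     0.39, 0.41, 0.44],
        "elastic": [0.2562, 0.10, 0.10, 0.10, 0.08, 0.08, 0.08,
                    0.09, 0.09, 0.10],
    },
    ("CraF", "young"): {
        "collagen": [0.08, 0.05, 0.05, 0.05, 0.06, 0.06, 0.07,
                     0.09, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20,
                     0.22, 0.24, 0.25, 0.26, 0.27, 0.28],
        "elastic": [0.0555, 0.02, 0.02, 0.02, 0.08, 0.08, 0.08,
                    0.08, 0.08, 0.08, 0.025, 0.025, 0.025, 0.025,
                    0.025, 0.025, 0.025, 0.025, 0.025, 0.025],
    },
    ("CraF", "old"): {
        "collagen": [0.12, 0.12, 0.12, 0.12, 0.13, 0.14, 0.15,
                     0.18, 0.20, 0.24, 0.28, 0.32, 0.36, 0.40,
                     0.44, 0.46, 0.48, 0.50, 0.52, 0.54],
        "elastic": [0.3151, 0.20, 0.18, 0.16, 0.12, 0.11, 0.10,
                    0.09, 0.08, 0.07, 0.06, 0.055, 0.05, 0.05,
                    0.045, 0.045, 0.04, 0.04, 0.04, 0.04],
    },
}


def default_profiles(fold_type: str, age_group: str
                     ) -> dict[str, np.ndarray]:
    """Per-subunit default area-fraction targets for a fold/age condition.

    Returns ``{"collagen": ..., "elastic": ...}`` arrays of length 10
    (CauF) or 20 (CraF), as fractions in [0, 1].
    """
    try:
        prof = _DEFAULT_PROFILES[(fold_type, age_group)]
    except KeyError:
        raise ValueError(
            f"no default profile for ({fold_type!r}, {age_group!r})")
    return {k: np.asarray(v, dtype=float) for k, v in prof.items()}


def default_section(fold_type: str, age_group: str, seed: int,
                    **spec_overrides) -> StainedSection:
    """Generate a section under the default study conditions.

    CauF lamina propria defaults to 700 um depth, CraF to 1400 um (the
    cranial midline is twice as long as the caudal one).
    """
    depth = 1400.0 if fold_type == "CraF" else 700.0
    spec_kwargs = dict(fold_type=fold_type, age_group=age_group,
                      lamina_depth_um=depth, seed=seed)
    spec_kwargs.update(spec_overrides)
    spec = SectionSpec(**spec_kwargs)
    prof = default_profiles(fold_type, age_group)
    zones = calibrate_composition(prof["collagen"], prof["elastic"],
                                  fold_type, age_group)
    return generate_section(spec, zones)


def simulate_profiles(targets_percent: Sequence[float], n_animals: int,
                      rng: np.random.Generator, *,
                      animal_sd: float = 0.15,
                      noise_sd: float = 2.0) -> pd.DataFrame:
    """Simulate per-animal subunit profiles around a mean depth profile.

    A cheap profile-level counterpart of the image pipeline for statistical
    property studies: each animal scales the whole profile by a lognormal
    factor (between-animal variation, sigma ``animal_sd``) and adds
    independent per-subunit noise (``noise_sd`` percentage points),
    truncated at zero.  Returns an animals x subunits DataFrame in percent.
    """
    targets = np.asarray(targets_percent, dtype=float)
    scale = rng.lognormal(0.0, animal_sd, size=(n_animals, 1))
    noise = rng.normal(0.0, noise_sd, size=(n_animals, targets.size))
    values = np.clip(targets[None, :] * scale + noise, 0.0, 100.0)
    return pd.DataFrame(values,
                        index=[f"animal_{i+1}" for i in range(n_animals)],
                        columns=np.arange(1, targets.size + 1))


def write_section(section: StainedSection, outdir) -> dict[str, str]:
    """Write the image pair (TIFF), masks (PNG), ground truth (CSV) and a
    generation manifest (YAML); returns the written paths."""
    import pathlib

    import imageio.v3 as iio
    import tifffile
    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, img in (("trichrome", section.trichrome_image),
                      ("resorcin", section.resorcin_image)):
        p = outdir / f"{name}.tiff"
        tifffile.imwrite(p, img)
        paths[name] = str(p)
    for name, mask in (("epithelium_mask", section.epithelium_mask),
                       ("fold_mask", section.fold_mask),
                       ("collagen_mask", section.collagen_mask),
                       ("elastic_mask", section.elastic_mask)):
        p = outdir / f"{name}.png"
        iio.imwrite(p, (mask.astype(np.uint8) * 255))
        paths[name] = str(p)
    p = outdir / "ground_truth.csv"
    section.ground_truth.to_csv(p)
    paths["ground_truth"] = str(p)
    manifest = {
        "spec": dataclasses.asdict(section.spec),
        "zones": [dataclasses.asdict(z) for z in section.zones],
    }
    p = outdir / "manifest.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    paths["manifest"] = str(p)
    return paths
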