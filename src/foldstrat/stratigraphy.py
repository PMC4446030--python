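"""Proportional-depth standardisation: subunits and hypothetical zones.

Fold thickness varies strongly between animals, so depth is standardised
by splitting each fold's lamina propria into proportional subunits of
equal relative depth: 10 in the caudal fold (CauF) and, because it is
about twice as deep, 20 in the cranial fold (CraF).  Subunits are grouped
into hypothetical zones for statistical comparison: in the CauF, Z1 is the
narrow subepithelial band (subunit 1) and Z2-Z4 divide the rest into
equidistant thirds; in the CraF, Z1 is subunit 1, Z2-Z7 are consecutive
triples and Z8 the remaining subunit 20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def n_subunits_for(fold_type: str) -> int:
    if fold_type == "CauF":
        return 10
    if fold_type == "CraF":
        return 20
    raise ValueError(f"unknown fold_type {fold_type!r}")


@dataclass(frozen=True)
class ZoneMap:
    """Grouping of 1-based subunit indices into 1-based zones."""

    fold_type: str
    members: dict[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        covered = [s for m in self.members.values() for s in m]
        n = n_subunits_for(self.fold_type)
        if sorted(covered) != list(range(1, n + 1)):
            raise ValueError(
                f"zones must partition subunits 1..{n} of {self.fold_type}")

    @property
    def n_zones(self) -> int:
        return len(self.members)

    def zone_of(self, subunit: int) -> int:
        for zid, m in self.members.items():
            if subunit in m:
                return zid
        raise KeyError(subunit)


_CAUF_ZONES = ZoneMap("CauF", {1: (1,), 2: (2, 3, 4), 3: (5, 6, 7),
                               4: (8, 9, 10)})
_CRAF_ZONES = ZoneMap("CraF", {
    1: (1,), 2: (2, 3, 4), 3: (5, 6, 7), 4: (8, 9, 10), 5: (11, 12, 13),
    6: (14, 15, 16), 7: (17, 18, 19), 8: (20,)})


def zone_map_for(fold_type: str) -> ZoneMap:
    """The standard zone grouping for a fold type (4 or 8 zones)."""
    if fold_type == "CauF":
        return _CAUF_ZONES
    if fold_type == "CraF":
        return _CRAF_ZONES
    raise ValueError(f"unknown fold_type {fold_type!r}")


def assign_subunit(depth_um: float, total_depth_um: float,
                   n_subunits: int) -> int:
    """1-based proportional subunit of a depth, with half-open bins.

    Bin k covers relative depths [(k-1)/n, k/n); depths at or beyond the
    total depth are rejected.
    """
    if not 0 <= depth_um < total_depth_um:
        raise ValueError(
            f"depth {depth_um} outside [0, {total_depth_um})")
    return int(np.floor(n_subunits * depth_um / total_depth_um)) + 1


@dataclass
class SubunitProfile:
    """Per-animal, per-fold apa values indexed by proportional subunit.

    ``values`` holds percentages in [0, 100]; missing subunits are NaN.
    """

    animal_id: str
    fold_type: str
    values: np.ndarray
    measure: str = "apa"

    def __post_init__(self) -> None:
        n = n_subunits_for(self.fold_type)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n,):
            raise ValueError(
                f"expected {n} subunit values for {self.fold_type}")
        ok = np.isnan(self.values) | ((self.values >= 0)
                                      & (self.values <= 100))
        if not ok.all():
            raise ValueError("apa values must lie in [0, 100] or be NaN")

    @property
    def n_subunits(self) -> int:
        return self.values.size

    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal": self.animal_id,
            "fold": self.fold_type,
            "subunit": np.arange(1, self.n_subunits + 1),
            self.measure: self.values,
            "missing": self.missing(),
        })


def aggregate_profile(pair_values: list[tuple[float, float]],
                      fold_type: str, total_depth_um: float,
                      animal_id: str = "animal",
                      measure: str = "apa") -> SubunitProfile:
    """Average per-station pair values into a per-subunit profile.

    ``pair_values`` is a list of (depth_um, value_percent) sampling
    stations; each falls into the subunit containing its depth, a subunit's
    value is the mean of its stations, and unsampled subunits are missing.
    """
    n = n_subunits_for(fold_type)
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for depth, value in pair_values:
        k = assign_subunit(depth, total_depth_um, n) - 1
        sums[k] += value
        counts[k] += 1
    values = np.full(n, np.nan)
    sampled = counts > 0
    values[sampled] = sums[sampled] / counts[sampled]
    return SubunitProfile(animal_id=animal_id, fold_type=fold_type,
                          values=values, measure=measure)


def zone_means(profile: SubunitProfile, zone_map: ZoneMap | None = None
               ) -> dict[int, float]:
    """Zone mean over non-missing member subunits (NaN if all missing)."""
    if zone_map is None:
        zone_map = zone_map_for(profile.fold_type)
    if zone_map.fold_type != profile.fold_type:
        raise ValueError("zone map fold type does not match profile")
    out = {}
    for zid, members in zone_map.members.items():
        vals = profile.values[[s - 1 for s in members]]
        vals = vals[~np.isnan(vals)]
        out[zid] = float(vals.mean()) if vals.size else float("nan")
    return out


def profiles_frame(profiles: list[SubunitProfile]) -> pd.DataFrame:
    """Animals x subunits wide table (percent; NaN missing) for the stats
    layer."""
    if not profiles:
        raise ValueError("no profiles given")
    n = profiles[0].n_subunits
    if any(p.n_subunits != n for p in profiles):
        raise ValueError("profiles mix fold types")
    return pd.DataFrame(
        np.vstack([p.values for p in profiles]),
        index=[p.animal_id for p in profiles],
        columns=np.arange(1, n + 1))
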