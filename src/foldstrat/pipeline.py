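"""End-to-end orchestration: simulate, segment, sample, stratify, score,
test, report.

The pipeline mirrors the histomorphometric workflow: classify stain
colours into fibre masks, place paired 35-um ROIs along the fold midline,
average each pair into a station value, pool stations into proportional
subunits and hypothetical zones, score collagen diameters in 70-um ROIs,
and run the demarcation statistics within and between age groups.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import roi as roi_mod
from . import scoring as scoring_mod
from . import segmentation as seg
from . import stats as stats_mod
from . import stratigraphy as strat
from . import synth

log = logging.getLogger("foldstrat")

MEASURE_ROI_UM = 35.0
SCORING_ROI_UM = 70.0

_STAIN_OF = {"collagen": "trichrome_collagen",
             "elastic": "resorcin_elastic"}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one simulated experiment."""

    fold_type: str = "CauF"
    n_animals: int = 6
    cauf_depth_um: float = 700.0
    epithelium_um: float = 50.0
    pixel_size_um: float = 0.5
    width_um: float = 240.0
    roi_diameter_um: float = MEASURE_ROI_UM
    scoring_diameter_um: float = SCORING_ROI_UM
    roi_offset_factor: float = 1.0
    alpha: float = stats_mod.ALPHA
    seed: int = 0
    colour_rules: dict = field(default_factory=dict)
    outdir: str = "foldstrat_run"

    @property
    def lamina_depth_um(self) -> float:
        # cranial-fold connective tissue is twice as deep as the caudal's
        if self.fold_type == "CraF":
            return 2.0 * self.cauf_depth_um
        return self.cauf_depth_um

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def measure_profile(section: synth.StainedSection, measure: str, *,
                    rules: dict[str, seg.ColourRule] | None = None,
                    diameter_um: float = MEASURE_ROI_UM,
                    spacing_um: float | None = None,
                    offset_factor: float = 1.0,
                    animal_id: str = "animal") -> strat.SubunitProfile:
    """Measure apa.coll or apa.elast of one section as a subunit profile.

    ``measure`` is ``"collagen"`` or ``"elastic"``; the matching stain
    image is classified with its colour rule, paired ROIs are placed along
    the midline, each pair value is the mean of its two ROI area
    fractions (percent), and station values are pooled per proportional
    subunit.
    """
    rules = rules or seg.DEFAULT_RULES
    stain = _STAIN_OF[measure]
    image = (section.trichrome_image if measure == "collagen"
             else section.resorcin_image)
    mask = seg.classify(image, rules[stain])
    px = section.spec.pixel_size_um
    midline = roi_mod.build_midline(section.fold_mask,
                                    section.epithelium_mask, px)
    pairs = roi_mod.place_roi_pairs(midline, diameter_um, spacing_um,
                                    offset_factor=offset_factor)
    values = []
    for pair in pairs:
        fa = seg.area_fraction(mask, pair.roi_a, px)
        fb = seg.area_fraction(mask, pair.roi_b, px)
        values.append((pair.depth_um, 100.0 * (fa + fb) / 2.0))
    return strat.aggregate_profile(values, section.spec.fold_type,
                                   midline.total_length_um,
                                   animal_id=animal_id,
                                   measure=f"apa_{measure[:5]}")


def score_section(section: synth.StainedSection, *,
                  rules: dict[str, seg.ColourRule] | None = None,
                  diameter_um: float = SCORING_ROI_UM,
                  offset_factor: float = 1.0,
                  animal_id: str = "animal") -> pd.DataFrame:
    """Score collagen diameters of one section in 70-um ROI pairs.

    Both ROIs of a station are scored and the per-category counts of the
    two are averaged (rounded to the nearest integer) before scoring, so a
    station contributes one score per category, like one pair of
    measurement ROIs contributes one apa value.
    """
    rules = rules or seg.DEFAULT_RULES
    mask = seg.classify(section.trichrome_image,
                        rules["trichrome_collagen"])
    px = section.spec.pixel_size_um
    midline = roi_mod.build_midline(section.fold_mask,
                                    section.epithelium_mask, px)
    pairs = roi_mod.place_roi_pairs(midline, diameter_um,
                                    offset_factor=offset_factor)
    n_sub = section.spec.n_subunits
    records = []
    for pair in pairs:
        subunit = strat.assign_subunit(pair.depth_um,
                                       midline.total_length_um, n_sub)
        rec_a = scoring_mod.score_roi(mask, pair.roi_a, px,
                                      pair.station_index)
        rec_b = scoring_mod.score_roi(mask, pair.roi_b, px,
                                      pair.station_index)
        counts = {cat: int(round((rec_a.counts[cat] + rec_b.counts[cat])
                                 / 2.0))
                  for cat in scoring_mod.CATEGORY_NAMES}
        scores = {cat: scoring_mod.score_count(cat, n)
                  for cat, n in counts.items()}
        records.append((subunit, scoring_mod.ScoreRecord(
            pair.station_index, counts, scores)))
    return scoring_mod.score_table(records, animal_id,
                                   section.spec.fold_type)


def _group_sections(cfg: PipelineConfig, age_group: str
                    ) -> list[synth.StainedSection]:
    sections = []
    base = cfg.seed + (0 if age_group == "young" else 500)
    for i in range(cfg.n_animals):
        sections.append(synth.default_section(
            cfg.fold_type, age_group, seed=base + i + 1,
            lamina_depth_um=cfg.lamina_depth_um,
            epithelium_thickness_um=cfg.epithelium_um,
            pixel_size_um=cfg.pixel_size_um, width_um=cfg.width_um))
    return sections


@dataclass
class ResultBundle:
    """All tables produced by one experiment run."""

    config: PipelineConfig
    profiles: pd.DataFrame          # tidy apa per animal/subunit/measure
    zone_table: pd.DataFrame        # per animal/zone/measure zone means
    scores: pd.DataFrame            # tidy scores
    median_scores: pd.DataFrame     # per age group/subunit/category
    wilcoxon: pd.DataFrame          # all bar comparisons
    demarcation: pd.DataFrame       # per-boundary classification
    kruskal: pd.DataFrame           # between-age zone tests


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.1f s", name,
                     time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_experiment(cfg: PipelineConfig) -> ResultBundle:
    """Run the full young-versus-old experiment for one fold type."""
    rules = seg.rules_from_config(cfg.colour_rules)
    zmap = strat.zone_map_for(cfg.fold_type)
    n_sub = strat.n_subunits_for(cfg.fold_type)

    profiles_by = {}
    tidy_profiles = []
    zone_rows = []
    score_tables = {}
    median_rows = []

    for age in ("young", "old"):
        sections = _stage("simulate")(_group_sections)(cfg, age)
        for measure in ("collagen", "elastic"):
            plist = []
            for i, sec in enumerate(sections):
                prof = _stage("measure")(measure_profile)(
                    sec, measure, rules=rules,
                    diameter_um=cfg.roi_diameter_um,
                    offset_factor=cfg.roi_offset_factor,
                    animal_id=f"{age}_{i + 1}")
                plist.append(prof)
                df = prof.to_frame()
                df["age_group"] = age
                df["measure"] = f"apa_{measure[:5]}"
                tidy_profiles.append(df.rename(
                    columns={prof.measure: "value"}))
                for zid, mean in strat.zone_means(prof, zmap).items():
                    zone_rows.append({
                        "animal": prof.animal_id, "age_group": age,
                        "measure": f"apa_{measure[:5]}",
                        "zone": zid, "value": mean})
            profiles_by[(age, measure)] = strat.profiles_frame(plist)
        tables = [_stage("score")(score_section)(
            sec, rules=rules, diameter_um=cfg.scoring_diameter_um,
            animal_id=f"{age}_{i + 1}")
            for i, sec in enumerate(sections)]
        score_tables[age] = tables
        med = scoring_mod.median_score_profile(tables, n_sub)
        med["age_group"] = age
        median_rows.append(med.reset_index())

    wilcoxon_rows = []
    demarcation_rows = []
    for (age, measure), frame in profiles_by.items():
        b1 = stats_mod.bar1(frame, alpha=cfg.alpha)
        b2 = stats_mod.bar2(frame, alpha=cfg.alpha, bar1_results=b1)
        b3 = stats_mod.bar3(frame, zmap, alpha=cfg.alpha)
        for name, results in (("bar1", b1), ("bar2", b2), ("bar3", b3)):
            df = stats_mod.results_frame(
                results, comparison=f"{age}/{measure}/{name}")
            wilcoxon_rows.append(df)
        report = stats_mod.summarise_bars(b1, b2, b3, n_sub)
        df = report.to_frame()
        df.insert(0, "measure", measure)
        df.insert(0, "age_group", age)
        demarcation_rows.append(df)

    zone_table = pd.DataFrame(zone_rows)
    kruskal_rows = []
    for measure in ("collagen", "elastic"):
        m = f"apa_{measure[:5]}"
        for zid in sorted(zmap.members):
            sel = zone_table[(zone_table["measure"] == m)
                             & (zone_table["zone"] == zid)]
            res = stats_mod.kruskal_wallis_zone(
                sel[sel["age_group"] == "young"]["value"],
                sel[sel["age_group"] == "old"]["value"],
                alpha=cfg.alpha)
            kruskal_rows.append({
                "measure": m, "zone": zid, "H": res.statistic,
                "p_value": res.p_value, "significant": res.significant})

    all_scores = pd.concat([t for tables in score_tables.values()
                            for t in tables], ignore_index=True)
    for age, tables in score_tables.items():
        all_scores.loc[all_scores["animal"].str.startswith(age),
                       "age_group"] = age

    return ResultBundle(
        config=cfg,
        profiles=pd.concat(tidy_profiles, ignore_index=True),
        zone_table=zone_table,
        scores=all_scores,
        median_scores=pd.concat(median_rows, ignore_index=True),
        wilcoxon=pd.concat(wilcoxon_rows, ignore_index=True),
        demarcation=pd.concat(demarcation_rows, ignore_index=True),
        kruskal=pd.DataFrame(kruskal_rows))


def write_bundle(bundle: ResultBundle, outdir) -> dict[str, str]:
    """Write every bundle table as CSV plus a reproduction manifest."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("profiles", "zone_table", "scores", "median_scores",
                 "wilcoxon", "demarcation", "kruskal"):
        p = outdir / f"{name}.csv"
        getattr(bundle, name).to_csv(p, index=False)
        paths[name] = str(p)
    demarcation = {
        f"{row['age_group']}/{row['measure']}/boundary_{row['boundary']}":
        row["classification"]
        for _, row in bundle.demarcation.iterrows()}
    p = outdir / "demarcation.json"
    with open(p, "w") as fh:
        json.dump(demarcation, fh, indent=2, sort_keys=True)
    paths["demarcation_json"] = str(p)
    bundle.config.to_yaml(outdir / "manifest.yaml")
    paths["manifest"] = str(outdir / "manifest.yaml")
    return paths


def recover_zone_mean(fold_type: str, age_group: str, *, measure: str,
                      zone: int = 1, n_sections: int = 6,
                      seeds: list[int] | None = None,
                      seed_base: int = 0) -> float:
    """Group-mean apa of one zone recovered through the full pipeline.

    Generates ``n_sections`` sections under the default study conditions
    (one per animal), measures each with the 35-um ROI pipeline, and
    returns the across-animal mean of the requested zone in percent.
    """
    if seeds is None:
        seeds = [seed_base + i + 1 for i in range(n_sections)]
    zmap = strat.zone_map_for(fold_type)
    values = []
    for s in seeds:
        section = synth.default_section(fold_type, age_group, seed=s)
        prof = measure_profile(section, measure, animal_id=f"seed_{s}")
        values.append(strat.zone_means(prof, zmap)[zone])
    return float(np.nanmean(values))
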