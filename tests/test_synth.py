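"""Generator tests: determinism, conservation, composition validation and
the default depth profiles."""

import numpy as np
import pytest

from foldstrat import segmentation as seg, synth
from foldstrat.stratigraphy import zone_map_for


def _zero_zones(n):
    return [synth.ZoneComposition(zone_id=i + 1, collagen_area_fraction=0.0,
                                  elastic_area_fraction=0.0)
            for i in range(n)]


class TestSectionSpec:
    def test_rejects_coarse_pixels(self):
        with pytest.raises(ValueError, match="pixel_size_um"):
            synth.SectionSpec("CauF", "young", 200.0, pixel_size_um=1.5)

    @pytest.mark.parametrize("field,value", [
        ("lamina_depth_um", -1.0), ("width_um", 0.0),
        ("epithelium_thickness_um", 0.0)])
    def test_rejects_non_positive_lengths(self, field, value):
        kwargs = dict(fold_type="CauF", age_group="young",
                      lamina_depth_um=200.0)
        kwargs[field] = value
        with pytest.raises(ValueError, match=field):
            synth.SectionSpec(**kwargs)

    def test_default_pairing_doubles_cranial_depth(self):
        """The cranial fold's connective tissue is twice as deep as the
        caudal fold's under the default study geometry."""
        cauf = synth.default_section("CauF", "young", seed=1,
                                     lamina_depth_um=100.0, width_um=60.0)
        craf = synth.default_section("CraF", "young", seed=1,
                                     lamina_depth_um=200.0, width_um=60.0)
        assert (craf.spec.lamina_depth_um
                == 2 * cauf.spec.lamina_depth_um)


class TestCompositionValidation:
    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(synth.CompositionError, match="zone 3"):
            synth.ZoneComposition(zone_id=3, collagen_area_fraction=0.7,
                                  elastic_area_fraction=0.4)

    def test_clumps_require_old_age(self, small_spec):
        zones = _zero_zones(10)
        zones[4] = synth.ZoneComposition(zone_id=5,
                                         collagen_area_fraction=0.0,
                                         elastic_area_fraction=0.1,
                                         elastic_clump_fraction=0.5)
        with pytest.raises(synth.CompositionError, match="zone 5"):
            synth.generate_section(small_spec, zones)

    def test_reddish_requires_old_craf_superficial(self, small_spec):
        zones = _zero_zones(10)
        zones[0] = synth.ZoneComposition(zone_id=1,
                                         collagen_area_fraction=0.1,
                                         elastic_area_fraction=0.0,
                                         collagen_render="reddish")
        with pytest.raises(synth.CompositionError, match="zone 1"):
            synth.generate_section(small_spec, zones)

    def test_reddish_deep_zone_rejected_even_when_old_craf(self):
        spec = synth.SectionSpec("CraF", "old", 200.0, width_um=60.0,
                                 epithelium_thickness_um=20.0, seed=0)
        zones = _zero_zones(20)
        zones[19] = synth.ZoneComposition(zone_id=20,
                                          collagen_area_fraction=0.1,
                                          elastic_area_fraction=0.0,
                                          collagen_render="reddish")
        with pytest.raises(synth.CompositionError, match="zone 20"):
            synth.generate_section(spec, zones)

    def test_wrong_band_count_rejected(self, small_spec):
        with pytest.raises(synth.CompositionError, match="expected 10"):
            synth.generate_section(small_spec, _zero_zones(9))


class TestGenerateSection:
    def test_empty_composition_yields_fibre_free_section(self, small_spec):
        section = synth.generate_section(small_spec, _zero_zones(10))
        assert not section.collagen_mask.any()
        assert not section.elastic_mask.any()
        assert (section.ground_truth[["collagen_fraction",
                                      "elastic_fraction"]] == 0).all().all()
        for stain, img in (("trichrome_collagen", section.trichrome_image),
                           ("resorcin_elastic", section.resorcin_image)):
            mask = seg.classify(img, seg.DEFAULT_RULES[stain])
            assert mask.mask.sum() == 0

    def test_saturated_collagen_fills_fold(self):
        spec = synth.SectionSpec("CauF", "young", 100.0, width_um=60.0,
                                 epithelium_thickness_um=20.0, seed=3)
        zones = [synth.ZoneComposition(zone_id=i + 1,
                                       collagen_area_fraction=1.0,
                                       elastic_area_fraction=0.0)
                 for i in range(10)]
        section = synth.generate_section(spec, zones)
        assert (section.ground_truth["collagen_fraction"] > 0.99).all()
        mask = seg.classify(section.trichrome_image,
                            seg.DEFAULT_RULES["trichrome_collagen"])
        assert mask.mask[section.fold_mask].mean() > 0.99

    def test_deterministic_given_spec_and_seed(self, small_spec):
        zones = synth.calibrate_composition([0.1] * 10, [0.05] * 10,
                                            "CauF", "young")
        a = synth.generate_section(small_spec, zones)
        b = synth.generate_section(small_spec, zones)
        assert np.array_equal(a.trichrome_image, b.trichrome_image)
        assert np.array_equal(a.resorcin_image, b.resorcin_image)
        assert a.ground_truth.equals(b.ground_truth)

    def test_ground_truth_matches_independent_pixel_count(
            self, small_section):
        """Conservation: the ground-truth table equals direct pixel counts
        of the pre-rendering fibre masks, band by band."""
        spec = small_section.spec
        epi = int(round(spec.epithelium_thickness_um / spec.pixel_size_um))
        total = small_section.collagen_mask.shape[0]
        lamina = total - epi
        for s in range(1, 11):
            lo = epi + int(round(lamina * (s - 1) / 10))
            hi = epi + int(round(lamina * s / 10))
            for mask, col in ((small_section.collagen_mask,
                               "collagen_fraction"),
                              (small_section.elastic_mask,
                               "elastic_fraction")):
                expected = mask[lo:hi].sum() / mask[lo:hi].size
                assert small_section.ground_truth.loc[s, col] == pytest.approx(
                    expected, abs=1e-12)

    def test_rendered_fractions_hit_requested_targets(self, small_section):
        gt = small_section.ground_truth
        assert np.allclose(gt["collagen_fraction"], 0.15, atol=0.02)
        assert np.allclose(gt["elastic_fraction"], 0.08, atol=0.02)

    def test_monotone_in_requested_fraction(self, small_spec):
        fractions = [0.05, 0.15, 0.30]
        got = []
        for f in fractions:
            zones = synth.calibrate_composition([f] * 10, [0.0] * 10,
                                                "CauF", "young")
            sec = synth.generate_section(small_spec, zones)
            got.append(sec.ground_truth["collagen_fraction"].mean())
        assert got[0] < got[1] < got[2]

    def test_reddish_zones_have_no_green_but_keep_ground_truth(
            self, old_craf_section):
        """The anomalous trichrome reaction leaves ground truth intact but
        removes green-classifiable collagen from zones 1-3."""
        gt = old_craf_section.ground_truth
        zmap = zone_map_for("CraF")
        superficial = [s for z in (1, 2, 3) for s in zmap.members[z]]
        assert (gt.loc[superficial, "collagen_fraction"] > 0.10).all()
        mask = seg.classify(old_craf_section.trichrome_image,
                            seg.DEFAULT_RULES["trichrome_collagen"])
        spec = old_craf_section.spec
        epi = int(round(spec.epithelium_thickness_um / spec.pixel_size_um))
        lamina = mask.mask.shape[0] - epi
        hi = epi + int(round(lamina * max(superficial) / 20))
        assert mask.mask[epi:hi].mean() < 0.01


class TestCalibration:
    def test_zero_targets_give_zero_compositions(self):
        zones = synth.calibrate_composition([0.0] * 4, [0.0] * 4,
                                            "CauF", "young")
        assert len(zones) == 10
        assert all(z.collagen_area_fraction == 0 for z in zones)

    def test_zone_targets_expand_via_zone_map(self):
        zones = synth.calibrate_composition([0.1, 0.2, 0.3, 0.4],
                                            [0.0] * 4, "CauF", "young")
        by_band = [z.collagen_area_fraction for z in zones]
        assert by_band == [0.1, 0.2, 0.2, 0.2, 0.3, 0.3, 0.3,
                          0.4, 0.4, 0.4]

    def test_infeasible_targets_rejected(self):
        with pytest.raises(synth.CompositionError, match="exceed 1"):
            synth.calibrate_composition([0.8] * 10, [0.4] * 10,
                                        "CauF", "young")

    def test_old_cauf_targets_recovered_in_ground_truth(self):
        """Calibrating to the observed old-group caudal Z1 elastic mean
        (25.62%) renders that fraction to within 2 points."""
        spec = synth.SectionSpec("CauF", "old", 200.0, width_um=120.0,
                                 epithelium_thickness_um=30.0, seed=11)
        prof = synth.default_profiles("CauF", "old")
        zones = synth.calibrate_composition(prof["collagen"],
                                            prof["elastic"], "CauF", "old")
        sec = synth.generate_section(spec, zones)
        assert sec.ground_truth.loc[1, "elastic_fraction"] == pytest.approx(
            0.2562, abs=0.02)


class TestDefaultProfiles:
    def test_cauf_young_shape(self):
        prof = synth.default_profiles("CauF", "young")
        coll = prof["collagen"]
        assert coll[0] > coll[1]          # subepithelial band high
        assert coll[9] > coll[4]          # deep maximum in subunit 10

    def test_craf_young_elastic_intermediate_layer(self):
        zmap = zone_map_for("CraF")
        elast = synth.default_profiles("CraF", "young")["elastic"]

        def zmean(z):
            return np.mean([elast[s - 1] for s in zmap.members[z]])

        assert zmean(3) > zmean(2) and zmean(4) > zmean(2)
        assert zmean(3) > zmean(5) and zmean(4) > zmean(5)

    def test_craf_old_z1_elastic_sixfold(self):
        young = synth.default_profiles("CraF", "young")["elastic"][0]
        old = synth.default_profiles("CraF", "old")["elastic"][0]
        assert 5.0 < old / young < 6.5

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            synth.default_profiles("CauF", "geriatric")


class TestSimulateProfiles:
    def test_shape_and_bounds(self, rng):
        frame = synth.simulate_profiles([10.0] * 10, 6, rng)
        assert frame.shape == (6, 10)
        assert ((frame.values >= 0) & (frame.values <= 100)).all()

    def test_mean_tracks_targets(self, rng):
        targets = np.array([30.0, 8.0, 8.0, 8.0, 10.0, 12.0, 15.0,
                            18.0, 22.0, 30.0])
        frame = synth.simulate_profiles(targets, 400, rng)
        # lognormal animal effect has mean exp(sd^2/2) ~ 1.011
        assert np.allclose(frame.mean(axis=0), targets * 1.011, rtol=0.08,
                           atol=0.5)


def test_write_section_roundtrip(tmp_path, small_section):
    paths = synth.write_section(small_section, tmp_path / "sec")
    import pathlib

    import pandas as pd
    import tifffile
    import yaml
    img = tifffile.imread(paths["trichrome"])
    assert np.array_equal(img, small_section.trichrome_image)
    gt = pd.read_csv(paths["ground_truth"], index_col="subunit")
    assert np.allclose(gt["collagen_fraction"],
                       small_section.ground_truth["collagen_fraction"])
    manifest = yaml.safe_load(pathlib.Path(paths["manifest"]).read_text())
    assert manifest["spec"]["seed"] == small_section.spec.seed
    assert len(manifest["zones"]) == 10
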