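import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retquant import nucleus_quant as nq
from retquant.image_io import ChannelImage
from retquant.synthetic_retina import generate_ground_truth, render_bundle

from .conftest import random_label_maps, region_from_coords, square_region
from .oracles import pixel_sets, spillover_sets

SHAPE = (64, 64)


class TestExtractRegions:
    def test_one_region_per_label(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[0, 0:2] = 1
        labels[3, 3:6] = 2
        labels[7, 7] = 3
        regions = nq.extract_regions(labels)
        assert sorted(r.id for r in regions) == [1, 2, 3]

    def test_empty_map_gives_empty_list(self):
        assert nq.extract_regions(np.zeros((5, 5), dtype=np.int32)) == []

    def test_areas_conserve_foreground(self, default_config):
        gt = generate_ground_truth(default_config)
        labels = render_bundle(gt, default_config).label_maps["target"]
        regions = nq.extract_regions(labels)
        assert sum(r.area for r in regions) == int((labels > 0).sum())


class TestNormalization:
    def test_hand_oracle_two_regions(self):
        # regions of 4 px at intensities 8 and 16 -> pooled mean 12;
        # a background pixel at 6 maps to 0.5
        img = np.full(SHAPE, 6.0)
        r1 = square_region(SHAPE, 0, 0, 2, rid=1)
        r2 = square_region(SHAPE, 10, 10, 2, rid=2)
        img.ravel()[r1.pixels] = 8.0
        img.ravel()[r2.pixels] = 16.0
        normalized, m = nq.normalize_by_positive_nuclei(
            ChannelImage(img, "prox1"), [r1, r2])
        assert m == pytest.approx(12.0)
        assert normalized[40, 40] == pytest.approx(0.5)

    def test_mean_over_positive_union_is_one(self, default_config):
        gt = generate_ground_truth(default_config)
        bundle = render_bundle(gt, default_config)
        regions = nq.extract_regions(bundle.label_maps["prox1"])
        normalized, _ = nq.normalize_by_positive_nuclei(
            bundle.channels["prox1"], regions)
        union = np.unique(np.concatenate([r.pixels for r in regions]))
        assert normalized.ravel()[union].mean() == pytest.approx(1.0)

    def test_constant_image_normalizes_to_one(self):
        img = np.full(SHAPE, 10.0)
        r = square_region(SHAPE, 0, 0, 3)
        normalized, _ = nq.normalize_by_positive_nuclei(ChannelImage(img, "p"), [r])
        assert np.allclose(normalized, 1.0)

    @pytest.mark.parametrize("c", [0.5, 3.0, 117.0])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(1)
        img = rng.uniform(1, 50, SHAPE)
        r = square_region(SHAPE, 5, 5, 4)
        base, _ = nq.normalize_by_positive_nuclei(img, [r])
        scaled, _ = nq.normalize_by_positive_nuclei(img * c, [r])
        np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_no_regions_is_an_error(self):
        with pytest.raises(ValueError, match="cannot normalize"):
            nq.normalize_by_positive_nuclei(np.ones(SHAPE), [])

    def test_zero_mean_is_an_error(self):
        img = np.zeros(SHAPE)
        r = square_region(SHAPE, 0, 0, 2)
        with pytest.raises(ValueError, match="cannot normalize"):
            nq.normalize_by_positive_nuclei(img, [r])


class TestAreaFilter:
    def test_filter_is_strictly_greater_than(self):
        shape = (40, 40)
        regions = [
            region_from_coords([(0, i) for i in range(9)]
                               + [(r, c) for r in range(1, 20)
                                  for c in range(10)][:190], shape, rid=1),
        ]
        # construct regions of exactly 199, 200, 201 pixels
        regions = []
        for rid, n in enumerate([199, 200, 201], start=1):
            coords = [(r, c) for r in range(40) for c in range(40)][:n]
            regions.append(region_from_coords(coords, shape, rid=rid))
        kept = nq.filter_by_area(regions, min_pixels=200)
        assert [r.id for r in kept] == [3]
        assert kept[0].area == 201

    def test_empty_input(self):
        assert nq.filter_by_area([], 200) == []

    def test_all_large_all_kept(self):
        regions = [square_region((64, 64), 0, 0, 30, rid=1)]
        assert nq.filter_by_area(regions, 200) == regions


class TestSdc:
    def test_forced_arithmetic_low_overlap(self):
        a = {(0, c) for c in range(100)}
        b = {(1, c) for c in range(80)} | {(0, c) for c in range(20)}
        assert nq.compute_sdc(a, b, "sum_denominator") == pytest.approx(0.2)
        assert nq.compute_sdc(a, b, "union_denominator") == pytest.approx(40 / 180)

    def test_forced_arithmetic_high_overlap_union_exceeds_one(self):
        a = {(0, c) for c in range(100)}
        b = {(0, c) for c in range(80)} | {(1, c) for c in range(20)}
        assert nq.compute_sdc(a, b, "sum_denominator") == pytest.approx(0.8)
        assert nq.compute_sdc(a, b, "union_denominator") == pytest.approx(160 / 120)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = {(int(r), int(c)) for r, c in rng.integers(0, 12, (30, 2))}
            b = {(int(r), int(c)) for r, c in rng.integers(0, 12, (30, 2))}
            if not (a & b) or a <= b or b <= a:
                continue
            for variant in nq.SDC_VARIANTS:
                assert nq.compute_sdc(a, b, variant) == pytest.approx(
                    nq.compute_sdc(b, a, variant))

    def test_disjoint_sets_error(self):
        with pytest.raises(ValueError, match="overlap"):
            nq.compute_sdc({(0, 0)}, {(5, 5)})

    def test_subset_error(self):
        with pytest.raises(ValueError, match="subset"):
            nq.compute_sdc({(0, 0)}, {(0, 0), (0, 1)})


class TestSpilloverCorrect:
    def test_no_overlap_keeps_target_untouched(self):
        target = square_region(SHAPE, 0, 0, 10, rid=1)
        far = square_region(SHAPE, 30, 30, 10, rid=2)
        meas, records = nq.spillover_correct(target, [far])
        np.testing.assert_array_equal(meas.corrected_pixels, target.pixels)
        assert records == []

    def test_forced_twenty_pixel_overlap_removed(self):
        # |B| = 100, one neighbour |A| = 100 overlapping 20 px, SDC 0.2 < 0.5
        target = square_region(SHAPE, 0, 0, 10, rid=1)
        coords = [(r, c) for r in range(8, 10) for c in range(10)]       # 20 in B
        coords += [(r, c) for r in range(10, 18) for c in range(10)]     # 80 out
        neighbor = region_from_coords(coords, SHAPE, rid=2)
        meas, records = nq.spillover_correct(target, [neighbor])
        assert meas.corrected_area == 80
        [rec] = records
        assert rec.is_spillover and rec.sdc == pytest.approx(0.2)
        assert rec.overlap_area == 20

    def test_engulfed_target_is_emptied_under_sum_variant(self):
        # B (100 px) strictly inside A (400 px): SDC_sum = 200/500 = 0.4
        target = square_region(SHAPE, 5, 5, 10, rid=1)
        neighbor = square_region(SHAPE, 0, 0, 20, rid=2)
        meas, [rec] = nq.spillover_correct(target, [neighbor],
                                           variant="sum_denominator")
        assert rec.sdc == pytest.approx(0.4)
        assert meas.corrected_area == 0
        assert meas.excluded_reason == "empty_after_correction"

    def test_engulfed_target_survives_under_union_variant(self):
        # same geometry: SDC_union = 200/400 = 0.5, not < 0.5 -> kept
        target = square_region(SHAPE, 5, 5, 10, rid=1)
        neighbor = square_region(SHAPE, 0, 0, 20, rid=2)
        meas, [rec] = nq.spillover_correct(target, [neighbor],
                                           variant="union_denominator")
        assert rec.sdc == pytest.approx(0.5)
        assert not rec.is_spillover
        assert meas.corrected_area == 100

    def test_contained_prox1_nucleus_is_not_excluded(self):
        target = square_region(SHAPE, 0, 0, 12, rid=1)
        inner = square_region(SHAPE, 2, 2, 4, rid=2)
        meas, [rec] = nq.spillover_correct(target, [inner])
        assert rec.is_subset and not rec.is_spillover
        assert math.isnan(rec.sdc)
        assert meas.corrected_area == target.area

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        target, prox = random_label_maps(rng, max_size=40)
        targets = nq.extract_regions(target)
        neighbors = nq.extract_regions(prox, "prox1_map")
        if not targets or len(neighbors) < 2:
            pytest.skip("degenerate draw")
        b = targets[0]
        reference, _ = nq.spillover_correct(b, neighbors)
        for perm in itertools.permutations(neighbors):
            meas, _ = nq.spillover_correct(b, list(perm))
            np.testing.assert_array_equal(meas.corrected_pixels,
                                          reference.corrected_pixels)

    @pytest.mark.parametrize("variant", nq.SDC_VARIANTS)
    def test_matches_set_algebra_oracle(self, variant):
        rng = np.random.default_rng(4)
        for _ in range(50):
            target_map, prox_map = random_label_maps(rng)
            targets = nq.extract_regions(target_map)
            neighbors = nq.extract_regions(prox_map, "prox1_map")
            prox_sets = pixel_sets(prox_map)
            target_sets = pixel_sets(target_map)
            for b in targets:
                meas, _ = nq.spillover_correct(b, neighbors, 0.5, variant)
                expected = spillover_sets(target_sets[b.id], prox_sets,
                                          0.5, variant)
                got = {(int(p // target_map.shape[1]),
                        int(p % target_map.shape[1]))
                       for p in meas.corrected_pixels}
                assert got == expected

    def test_conservation_invariant(self):
        rng = np.random.default_rng(5)
        target_map, prox_map = random_label_maps(rng)
        neighbors = nq.extract_regions(prox_map, "prox1_map")
        for b in nq.extract_regions(target_map):
            meas, records = nq.spillover_correct(b, neighbors)
            assert np.isin(meas.corrected_pixels, b.pixels).all()
            spill_union = set()
            for rec in records:
                if rec.is_spillover:
                    a = next(n for n in neighbors if n.id == rec.neighbor_id)
                    spill_union |= set(np.intersect1d(a.pixels, b.pixels))
            assert len(spill_union) + meas.corrected_area == b.area


class TestNucleusMedian:
    def _measurement(self, pixels, shape=SHAPE):
        return nq.NucleusMeasurement(id=1, compartment="MG", area=len(pixels),
                                     corrected_pixels=np.asarray(pixels))

    def test_constant_region(self):
        img = np.full(SHAPE, 7.0)
        assert nq.nucleus_median(img, self._measurement([0, 1, 2])) == 7.0

    def test_even_count_averages_central_values(self):
        img = np.zeros(SHAPE)
        img.ravel()[[0, 1, 2, 3]] = [1, 2, 3, 100]
        assert nq.nucleus_median(img, self._measurement([0, 1, 2, 3])) == 2.5

    @given(st.permutations([10, 11, 12, 13, 14]))
    @settings(deadline=None, max_examples=20)
    def test_pixel_order_does_not_matter(self, order):
        img = np.arange(64.0 * 64).reshape(SHAPE)
        base = nq.nucleus_median(img, self._measurement([10, 11, 12, 13, 14]))
        assert nq.nucleus_median(img, self._measurement(list(order))) == base

    def test_empty_region_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            nq.nucleus_median(np.zeros(SHAPE), self._measurement([]))


class TestCompartments:
    def _masks(self):
        mg = np.zeros(SHAPE, dtype=bool)
        bc = np.zeros(SHAPE, dtype=bool)
        mg[:20] = True
        bc[30:50] = True
        return {"MG": mg, "BC": bc}

    def test_fully_inside_mask(self):
        region = square_region(SHAPE, 2, 2, 5)
        nq.assign_compartments([region], self._masks())
        assert region.compartment == "MG"

    def test_below_membership_fraction_is_other(self):
        # rows 24-33 against BC rows 30-49: 4/10 = 40% coverage
        region = square_region(SHAPE, 24, 0, 10)
        nq.assign_compartments([region], self._masks())
        assert region.compartment == "other"

    def test_sixty_percent_inside_is_assigned(self):
        # rows 26-35: 6/10 = 60% inside BC
        region = square_region(SHAPE, 26, 0, 10)
        nq.assign_compartments([region], self._masks())
        assert region.compartment == "BC"

    def test_overlapping_masks_error(self):
        masks = self._masks()
        masks["BC"][:20] = True  # now overlaps MG
        region = square_region(SHAPE, 2, 2, 5)
        with pytest.raises(ValueError, match="disjoint"):
            nq.assign_compartments([region], masks)


class TestQuantifyImage:
    def test_symmetric_intensities_give_unit_ratio(self, clean_config):
        means = {band: 100.0 for band in ("BC", "MG", "AC")}
        means.update(ONL=0.0, GCL=0.0)
        cfg = clean_config.replace(intensity_means={
            "prox1": means,
            "marker": clean_config.intensity_means["marker"],
            "dapi": clean_config.intensity_means["dapi"]})
        gt = generate_ground_truth(cfg)
        bundle = render_bundle(gt, cfg)
        q = nq.quantify_image(bundle)
        assert q.score.ratios["MG/BC"] == pytest.approx(1.0, rel=1e-12)

    def test_missing_reference_compartment_is_flagged(self, clean_config):
        counts = dict(clean_config.nuclei_per_band)
        counts["BC"] = 0
        cfg = clean_config.replace(nuclei_per_band=counts)
        gt = generate_ground_truth(cfg)
        bundle = render_bundle(gt, cfg)
        q = nq.quantify_image(bundle)
        assert not q.score.reference_defined
        assert math.isnan(q.score.ratios["MG/BC"])

    def test_correction_off_skips_overlap_records(self, default_config):
        gt = generate_ground_truth(default_config)
        bundle = render_bundle(gt, default_config)
        q = nq.quantify_image(bundle, nq.QuantConfig(correct_spillover=False))
        assert len(q.overlaps) == 0
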