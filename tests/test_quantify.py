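"""Regional statistics, laminar scoring and the patterning-score rules."""

import numpy as np
import pytest

from lamina import quantify as qt
from lamina import synthdata as sd
from lamina.images import image_array


class TestRegionMeanIntensity:
    def test_constant_region(self):
        img = np.full((10, 10), 10, np.uint8)
        mask = np.ones((10, 10), bool)
        assert qt.region_mean_intensity(img, mask).mint == 10.0

    def test_half_and_half(self):
        img = np.zeros((10, 10), np.uint8)
        img[:, 5:] = 20
        assert qt.region_mean_intensity(img, np.ones((10, 10), bool)).mint == 10.0

    def test_toy_grid_hand_sum(self):
        img = np.arange(9, dtype=np.uint8).reshape(3, 3)
        mask = np.zeros((3, 3), bool)
        mask.ravel()[[0, 2, 4, 6, 8]] = True
        rec = qt.region_mean_intensity(img, mask)
        assert rec.mint == pytest.approx((0 + 2 + 4 + 6 + 8) / 5)
        assert rec.pixel_count == 5

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            qt.region_mean_intensity(np.zeros((4, 4), np.uint8),
                                     np.zeros((4, 4), bool))


class TestAverageSeries:
    def test_single_series_equals_direct_formula(self):
        regional = [{"a": 6.0, "b": 2.0}]
        out = qt.average_series(regional, [4.0])
        assert out["a"] == pytest.approx(6 / 8 * 4)
        assert out["b"] == pytest.approx(2 / 8 * 4)

    def test_two_identical_series_match_single(self):
        regional = [{"a": 6.0, "b": 2.0}] * 2
        assert qt.average_series(regional, [4.0, 4.0]) == \
            qt.average_series(regional[:1], [4.0])

    def test_same_pattern_different_intensity_scales_by_mean(self):
        # two series, identical relative pattern, whole-image means 4 and 8:
        # regional values scale by the mean whole-image intensity, 6
        regional = [{"a": 3.0, "b": 1.0}, {"a": 6.0, "b": 2.0}]
        out = qt.average_series(regional, [4.0, 8.0])
        assert out["a"] == pytest.approx(0.75 * 6)
        assert out["b"] == pytest.approx(0.25 * 6)

    def test_all_zero_series_returns_unexpressed_zeros(self):
        out = qt.average_series([{"a": 0.0, "b": 0.0}], [0.0])
        assert out == {"a": 0.0, "b": 0.0}


class TestExpressionAndEnrichmentRules:
    @pytest.mark.parametrize("d, v, expected", [
        (1.0, 0.0, True),     # inclusive threshold
        (0.5, 0.99, False),
        (0.0, 255.0, True),
    ])
    def test_is_expressed(self, d, v, expected):
        assert qt.is_expressed(d, v) is expected

    def test_enrichment_strong_expression(self):
        enriched, norm = qt.regional_enrichment(10.0, 2.0)
        assert norm == pytest.approx(10 / 12)
        assert enriched

    def test_enrichment_weak_expression_needs_higher_share(self):
        # 3/(3+0.02) = 0.9934 >= 0.99 with 2 <= mINT < 5 -> enriched
        enriched, norm = qt.regional_enrichment(3.0, 0.02)
        assert norm == pytest.approx(3 / 3.02)
        assert enriched

    def test_enrichment_blocked_by_expressed_comparison_region(self):
        enriched, _ = qt.regional_enrichment(10.0, 5.0)
        assert not enriched

    def test_enrichment_undefined_when_both_zero(self):
        enriched, norm = qt.regional_enrichment(0.0, 0.0)
        assert not enriched
        assert np.isnan(norm)

    @pytest.mark.parametrize("a, b, expected", [
        (20.0, 2.0, True),
        (14.0, 14.0, False),
        (30.0, 16.0, False),   # neither region below 15
    ])
    def test_border_candidate(self, a, b, expected):
        assert qt.border_candidate(a, b) is expected


class TestHighIntensityMask:
    def test_constant_image_all_high(self):
        img = np.full((10, 10), 40, np.uint8)
        mask = np.ones((10, 10), bool)
        thr, high = qt.high_intensity_mask(img, mask)
        assert thr == 40.0
        assert high.all()

    def test_population_sd_threshold(self):
        vals = np.zeros(100, np.uint8)
        vals[0] = 100
        img = vals.reshape(10, 10)
        mask = np.ones((10, 10), bool)
        thr, high = qt.high_intensity_mask(img, mask)
        assert thr == pytest.approx(1 + 2 * np.sqrt(99))  # mean 1, pop SD 9.95
        assert high.sum() == 1

    def test_heatmap_mode_doubles_the_mean(self):
        img = np.full((10, 10), 10, np.uint8)
        thr, _ = qt.high_intensity_mask(img, np.ones((10, 10), bool),
                                        mode="heatmap")
        assert thr == 20.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            qt.high_intensity_mask(np.zeros((4, 4), np.uint8),
                                   np.zeros((4, 4), bool))


class TestLaminarScoring:
    def test_single_layer_fixture_relative_intensity(self):
        score = qt.score_from_measurements(
            {"II": 9.0, "III": 0.5, "V/VI": 0.5},
            {"II": 10, "III": 0, "V/VI": 0}, mec_mean=10 / 3)
        assert score.rel["II"] == pytest.approx(0.9)
        assert score.lmax == "II"

    def test_uniform_gene_symmetric_thirds(self):
        score = qt.score_from_measurements(
            {"II": 2.0, "III": 2.0, "V/VI": 2.0},
            {"II": 5, "III": 5, "V/VI": 5}, mec_mean=2.0)
        for v in score.rel.values():
            assert v == pytest.approx(1 / 3)

    def test_low_intensity_gene_not_evaluated(self):
        score = qt.score_from_measurements(
            {"II": 0.5, "III": 0.5, "V/VI": 0.5},
            {"II": 0, "III": 0, "V/VI": 0}, mec_mean=0.5)
        assert not score.eligible
        result = qt.patterning_scores(score)
        assert not result.evaluated

    def test_rel_and_prop_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            means = {l: float(rng.uniform(0.1, 200)) for l in qt.LAYER_ORDER}
            counts = {l: int(rng.integers(0, 50)) for l in qt.LAYER_ORDER}
            score = qt.score_from_measurements(means, counts, mec_mean=50.0)
            assert sum(score.rel.values()) == pytest.approx(1.0)
            if not score.no_high_pixels:
                assert sum(score.prop.values()) == pytest.approx(1.0)

    def test_tie_break_follows_fixed_layer_order(self):
        score = qt.score_from_measurements(
            {"II": 5.0, "III": 5.0, "V/VI": 5.0},
            {"II": 2, "III": 2, "V/VI": 2}, mec_mean=5.0)
        assert (score.lmax, score.lmid, score.lmin) == ("II", "III", "V/VI")

    def test_laminar_profile_measures_and_scores(self, geometry, clean_cohort):
        truths, records, _ = clean_cohort
        groups = geometry.group_masks()
        mec = geometry.mec_mask()
        rec = next(r for t, r in zip(truths, records)
                   if t.kind == "layer_specific" and t.target_layers == ("MEC_LII",))
        score = qt.laminar_profile(rec.expression, groups, mec)
        assert score.lmax == "II"
        assert score.rel["II"] > 0.85

    def test_disjointness_enforced(self, geometry):
        groups = geometry.group_masks()
        groups["III"] = groups["II"]
        with pytest.raises(ValueError):
            qt.laminar_profile(np.full((225, 300), 10, np.uint8), groups)


class TestPatterningScores:
    def test_scores_bounded_to_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            means = {l: float(rng.uniform(0, 250)) for l in qt.LAYER_ORDER}
            counts = {l: int(rng.integers(0, 40)) for l in qt.LAYER_ORDER}
            score = qt.score_from_measurements(means, counts,
                                               mec_mean=float(rng.uniform(1, 80)))
            if not score.eligible:
                continue
            res = qt.patterning_scores(score)
            assert 0.0 <= res.ps_single <= 1.0
            assert 0.0 <= res.ps_joint <= 1.0

    def test_no_high_pixel_override_uses_w_rel_0p9(self):
        score = qt.score_from_measurements(
            {"II": 9.0, "III": 0.5, "V/VI": 0.5},
            {"II": 0, "III": 0, "V/VI": 0}, mec_mean=10 / 3)
        assert score.no_high_pixels
        res = qt.patterning_scores(score)
        assert res.ps_single == pytest.approx(0.9 * 0.9 + 0.1 * 1.0)

    def test_moderate_threshold_is_a_parameter(self):
        score = qt.score_from_measurements(
            {"II": 5.0, "III": 2.0, "V/VI": 2.0},
            {"II": 6, "III": 2, "V/VI": 2}, mec_mean=3.0)
        strict = qt.patterning_scores(score, single_threshold=0.65)
        moderate = qt.patterning_scores(score, single_threshold=0.60)
        assert strict.ps_single == moderate.ps_single
        assert (moderate.candidate_class == "single") >= \
            (strict.candidate_class == "single")

    def test_invalid_weights_rejected(self):
        score = qt.score_from_measurements(
            {"II": 9.0, "III": 1.0, "V/VI": 1.0},
            {"II": 4, "III": 0, "V/VI": 0}, mec_mean=4.0)
        with pytest.raises(ValueError):
            qt.patterning_scores(score, qt.ScoreWeights(w_rel=0.5, w_prop=0.6))


@pytest.fixture(scope="module")
def cohort(scene_config):
    geom = sd.SceneGeometry(scene_config)
    truths = []
    for i in range(6):
        layer = "MEC_LVI" if i < 3 else "MEC_LII"
        truths.append(sd.SyntheticTruth(
            f"{'vi' if i < 3 else 'ii'}{i}", "layer_specific", (layer,),
            {l: (12.0 if l == layer else 0.5) for l in sd.CELLULAR_LAYERS}))
    records, _ = sd.generate_gene_cohort(truths, scene_config, seed=4,
                                         planes=("C",))
    roi = geom.mec_mask()
    return [(t.gene_id, r.expression) for t, r in zip(truths, records)], roi


class TestSimilaritySearch:
    def test_seed_gene_ranks_first_with_unit_correlation(self, cohort):
        pairs, roi = cohort
        ranked = qt.similarity_search(pairs[0][1], pairs, roi,
                                      mint_window=(0.0, 256.0))
        assert ranked[0][0] == pairs[0][0]
        assert ranked[0][1] == pytest.approx(1.0)

    def test_same_layer_truth_ranks_above_other_layer(self, cohort):
        pairs, roi = cohort
        ranked = qt.similarity_search(pairs[0][1], pairs, roi,
                                      mint_window=(0.0, 256.0))
        top3 = [g for g, _ in ranked[:3]]
        assert all(g.startswith("vi") for g in top3)

    def test_top_n_bound(self, cohort):
        pairs, roi = cohort
        ranked = qt.similarity_search(pairs[0][1], pairs, roi, top_n=2,
                                      mint_window=(0.0, 256.0))
        assert len(ranked) == 2

    def test_empty_cohort_after_filters_is_empty_result(self, cohort):
        pairs, roi = cohort
        ranked = qt.similarity_search(pairs[0][1], pairs, roi,
                                      mint_window=(250.0, 256.0))
        assert ranked == []
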