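"""Dorsoventral classification, gradient slopes, depth profiles and the
image/RNA-Seq comparison."""

import numpy as np
import pandas as pd
import pytest

from lamina import gradients as gr
from lamina import synthdata as sd


def _table(d_mean, v_mean, n=3, sig=None):
    cols = [f"d{i}" for i in range(n)] + [f"v{i}" for i in range(n)]
    groups = {c: ("dorsal" if c.startswith("d") else "ventral") for c in cols}
    values = pd.DataFrame([[d_mean] * n + [v_mean] * n], index=["g"],
                          columns=cols)
    s = None if sig is None else pd.Series([sig], index=["g"])
    return gr.ExpressionTable(values, groups, s)


class TestDvClassifyImage:
    @pytest.mark.parametrize("d, v, cls", [
        (2.0, 1.0, "D>V"),
        (2.0, 2.0, "NS"),
        (2.0, 2.4, "V>D"),       # log2(1.2) exactly: inclusive
        (1.0, 1.9, "unexpressed"),
        (0.0, 5.0, "V>D"),       # infinity sentinel
        (5.0, 0.0, "D>V"),
    ])
    def test_rule_examples(self, d, v, cls):
        assert gr.dv_classify_image(d, v).dv_class == cls

    def test_classes_mutually_exclusive_and_scale_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            d, v = rng.uniform(0.1, 50, 2)
            c = rng.uniform(0.5, 4)
            r1 = gr.dv_classify_image(d, v)
            r2 = gr.dv_classify_image(c * d, c * v)
            assert not (r1.dv_class == "D>V" and r1.dv_class == "V>D")
            if min(d, v) * c >= 2 and min(d, v) >= 2:
                assert r1.dv_class == r2.dv_class

    def test_plane_averaging(self):
        d, v = gr.plane_averaged_dv({"C": (2.0, 4.0), "L1": (4.0, 2.0)})
        assert (d, v) == (3.0, 3.0)
        assert gr.plane_averaged_dv({"L1": (2.0, 4.0)}) == (2.0, 4.0)


class TestDvClassifyFpkm:
    def test_thirty_eight_percent_difference_is_candidate(self):
        out = gr.dv_classify_fpkm(_table(1.0, 1.3))
        assert out.loc["g", "dv_class"] == "V>D"
        assert out.loc["g", "log2_ratio"] == pytest.approx(np.log2(1.3))

    def test_below_expression_floor(self):
        out = gr.dv_classify_fpkm(_table(0.05, 0.05))
        assert out.loc["g", "dv_class"] == "unexpressed"

    def test_equal_means_not_significant(self):
        out = gr.dv_classify_fpkm(_table(1.0, 1.0))
        assert out.loc["g", "dv_class"] == "NS"

    def test_untested_genes_stay_ns(self):
        out = gr.dv_classify_fpkm(_table(0.3, 0.6))
        assert out.loc["g", "tested"].item() is False
        assert out.loc["g", "dv_class"] == "NS"

    def test_significance_requires_external_flag(self):
        flagged = gr.dv_classify_fpkm(_table(2.0, 4.0, sig=True))
        unflagged = gr.dv_classify_fpkm(_table(2.0, 4.0, sig=False))
        assert flagged.loc["g", "significant"].item() is True
        assert unflagged.loc["g", "significant"].item() is False

    def test_missing_group_rejected(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            gr.ExpressionTable(values, {"a": "dorsal", "b": "dorsal"})


class TestGradientSlopes:
    def _masks(self):
        layer = np.zeros((50, 10), bool)
        layer[:, :] = True
        subs = []
        for i in range(5):
            m = np.zeros((50, 10), bool)
            m[i * 10:(i + 1) * 10] = True
            subs.append(m)
        return {"L": layer}, subs

    def test_exact_line_recovered(self):
        layers, subs = self._masks()
        img = np.zeros((50, 10), np.uint8)
        for i, v in enumerate([10, 8, 6, 4, 2]):
            img[i * 10:(i + 1) * 10] = v
        slopes = gr.dv_gradient_slopes(img, layers, subs)
        assert slopes["L"] == pytest.approx(-2.0)
        assert slopes["MEC"] == pytest.approx(-2.0)

    def test_constant_image_zero_slope(self):
        layers, subs = self._masks()
        img = np.full((50, 10), 7, np.uint8)
        assert gr.dv_gradient_slopes(img, layers, subs)["L"] == pytest.approx(0.0)

    def test_sign_matches_generating_coefficient(self, scene_config, geometry):
        truth = sd.SyntheticTruth(
            "g", "uniform", layer_bases={l: 60.0 for l in sd.CELLULAR_LAYERS},
            dv_g=1.0)
        records, _ = sd.generate_gene_cohort([truth], scene_config, 0,
                                             planes=("C",))
        slopes = gr.dv_gradient_slopes(records[0].expression,
                                       geometry.group_masks(),
                                       geometry.dv_subregions(5))
        assert slopes["MEC"] > 0  # ventral-high coefficient: intensity grows

    def test_undefined_with_single_subregion(self):
        layers, subs = self._masks()
        img = np.full((50, 10), 7, np.uint8)
        empty = [np.zeros((50, 10), bool)] * 4 + [subs[0]]
        assert np.isnan(gr.dv_gradient_slopes(img, layers, empty)["L"])


class TestCompareAbaRnaseq:
    def test_identity_line(self):
        x = np.linspace(-1, 1, 10)
        slope, r, p, n = gr.compare_aba_rnaseq(x, x)
        assert slope == pytest.approx(1.0)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_doubled_slope(self):
        x = np.linspace(-1, 1, 10)
        slope, r, _, _ = gr.compare_aba_rnaseq(2 * x, x)
        assert slope == pytest.approx(2.0)
        assert r == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10)
        y = 0.7 * x + rng.normal(0, 0.3, 10)
        slope, r, p, _ = gr.compare_aba_rnaseq(y, x)
        xc = x - x.mean()
        yc = y - y.mean()
        assert slope == pytest.approx((xc @ yc) / (xc @ xc))
        assert r == pytest.approx((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))

    def test_non_finite_pairs_excluded(self):
        x = np.array([0.0, 1.0, 2.0, np.inf, 3.0])
        y = np.array([0.0, 1.0, 2.0, 1.0, np.nan])
        _, _, _, n = gr.compare_aba_rnaseq(y, x)
        assert n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            gr.compare_aba_rnaseq([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestDepthProfile:
    def _geometry(self):
        inner = np.zeros((10, 40), bool)
        outer = np.zeros((10, 40), bool)
        inner[:, 0] = True
        outer[:, 39] = True
        region = np.ones((10, 40), bool)
        return region, inner, outer

    def test_boundary_pixels_land_in_edge_bins(self):
        region, inner, outer = self._geometry()
        img = np.full((10, 40), 50, np.uint8)
        prof = gr.depth_profile(img, region, inner, outer)
        assert prof.bin_counts[0] > 0     # d = 0 at the white-matter line
        assert prof.bin_counts[19] > 0    # d = 1 on the pial line

    def test_uniform_image_flat_profile(self):
        region, inner, outer = self._geometry()
        img = np.full((10, 40), 50, np.uint8)
        prof = gr.depth_profile(img, region, inner, outer)
        nz = prof.bin_counts > 0
        assert np.allclose(prof.bin_means[nz], 50.0)

    def test_intensity_mass_conserved(self, geometry, reference_image):
        inner, outer = geometry.boundary_masks()
        mec = geometry.mec_mask()
        prof = gr.depth_profile(reference_image, mec, inner, outer)
        mass = np.nansum(prof.bin_means * prof.bin_counts)
        arr = reference_image.data
        assert mass == pytest.approx(float(arr[mec].sum()))

    def test_minmax_normalization(self):
        region, inner, outer = self._geometry()
        img = np.tile(np.linspace(0, 200, 40).astype(np.uint8), (10, 1))
        prof = gr.depth_profile(img, region, inner, outer,
                                normalization="minmax")
        assert np.nanmin(prof.bin_means) == pytest.approx(0.0)
        assert np.nanmax(prof.bin_means) == pytest.approx(1.0)


class TestDeepSuperficial:
    def _profile(self, deep_mass, sup_mass):
        means = np.zeros(20)
        counts = np.ones(20)
        means[:10] = deep_mass / 10
        means[10:] = sup_mass / 10
        return gr.DepthProfile("g", "MEC", means, counts)

    def test_all_mass_deep(self):
        frac, dev, cls = gr.deep_superficial_stat(self._profile(10, 0), 0.5, 1.0)
        assert frac == 1.0
        assert dev == 0.0
        assert cls == "deep"

    def test_equal_mass_neither(self):
        frac, _, cls = gr.deep_superficial_stat(self._profile(5, 5), 0.5)
        assert frac == pytest.approx(0.5)
        assert cls == "neither"

    def test_seventy_thirty_split_is_deep_enriched(self):
        frac, _, cls = gr.deep_superficial_stat(self._profile(7, 3), 0.5)
        assert frac == pytest.approx(0.7)
        assert cls == "deep"

    def test_boundary_validation(self):
        with pytest.raises(ValueError):
            gr.deep_superficial_stat(self._profile(5, 5), 1.5)


class TestLayerCorrelationMatrix:
    def test_duplicated_layer_correlates_perfectly(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 3, 8)
        df = pd.DataFrame({"mec_II": a, "neo_II": a,
                           "neo_V": rng.normal(5, 2, 8)})
        mat = gr.layer_correlation_matrix(df)
        assert mat.loc["mec_II", "neo_II"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(0, 1, (10, 4)),
                          columns=list("abcd"))
        mat = gr.layer_correlation_matrix(df)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)

    def test_five_gene_toy_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        mat = gr.layer_correlation_matrix(pd.DataFrame({"x": x, "y": y}))
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert mat.loc["x", "y"] == pytest.approx(expected)

    def test_constant_layer_reported_missing(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        mat = gr.layer_correlation_matrix(df)
        assert np.isnan(mat.loc["a", "b"])


class TestPermutationTest:
    def test_separated_groups_give_small_p(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 20)
        b = rng.normal(3, 1, 20)
        diff, p = gr.permutation_group_test(a, b, n_permutations=2000, seed=1)
        assert diff < 0
        assert p < 0.01

    def test_same_distribution_large_p(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        _, p = gr.permutation_group_test(a, b, n_permutations=2000, seed=1)
        assert p > 0.05
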