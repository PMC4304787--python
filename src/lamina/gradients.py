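"""Dorsoventral gradient analysis for images and RNA-Seq tables.

Classifies dorsoventral (DV) expression with the inclusive 20% threshold
``log2(1.2)`` on the log2 ventral/dorsal ratio, fits per-layer DV gradient
slopes over 5 subregions, computes cortical depth profiles (20 bins of
normalized depth between the white-matter and pial boundaries), deep vs
superficial statistics, layer correlation matrices, and the image-vs-RNA-Seq
regression.  Inferential group comparisons are provided as a seeded
permutation test on group means alongside the descriptive statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import distance_transform_edt

from .images import image_array

#: Inclusive DV classification threshold: a 20% difference in expression.
DV_LOG2_THRESHOLD = float(np.log2(1.2))


@dataclass
class DVRecord:
    gene_id: str
    mint_dorsal: float
    mint_ventral: float
    log2_ratio: float
    dv_class: str           # "D>V", "V>D", "NS" or "unexpressed"


@dataclass
class ExpressionTable:
    """Gene x sample FPKM matrix with dorsal/ventral group labels.

    The significance flag is externally supplied (an FDR < 0.05 indicator
    from the upstream differential-expression caller); it is consumed here,
    never recomputed.
    """

    values: pd.DataFrame
    groups: dict
    significant: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be nonnegative")
        have = set(self.groups.values())
        if have != {"dorsal", "ventral"}:
            raise ValueError("need nonempty dorsal and ventral groups")

    def group_means(self) -> pd.DataFrame:
        cols = {g: [c for c, gg in self.groups.items() if gg == g]
                for g in ("dorsal", "ventral")}
        return pd.DataFrame({g: self.values[c].mean(axis=1)
                             for g, c in cols.items()})

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = [f"{c}:{self.groups[c]}" for c in out.columns]
        if self.significant is not None:
            out["significant"] = self.significant.astype(int)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        sig = None
        if "significant" in df.columns:
            sig = df.pop("significant").astype(bool)
        groups = {}
        rename = {}
        for c in df.columns:
            name, grp = c.rsplit(":", 1)
            rename[c] = name
            groups[name] = grp
        return cls(df.rename(columns=rename), groups, sig)


@dataclass
class DepthProfile:
    """Mean intensity versus normalized cortical depth (20 bins).

    Depth d = 0 at the white-matter (or subicular) boundary, d = 1 at the
    pial surface; ``bin_means`` holds the mean intensity per bin and
    ``bin_counts`` the pixels per bin (intensity mass is conserved:
    sum(bin_means * bin_counts) equals the summed masked intensities).
    """

    gene_id: str
    region: str
    bin_means: np.ndarray
    bin_counts: np.ndarray
    excluded_pixels: int = 0
    n_bins: int = 20


# ---------------------------------------------------------------------------
# DV classification
# ---------------------------------------------------------------------------

def dv_classify_image(mint_dorsal: float, mint_ventral: float,
                      gene_id: str = "") -> DVRecord:
    """Classify one image's DV expression from its regional means.

    Genes below mean intensity 2 in both boxes are unexpressed for this
    analysis.  A zero denominator with an expressed numerator keeps its sign
    class and records an infinite ratio sentinel.
    """
    d, v = float(mint_dorsal), float(mint_ventral)
    if max(d, v) < 2.0:
        return DVRecord(gene_id, d, v, float("nan"), "unexpressed")
    if d == 0.0:
        return DVRecord(gene_id, d, v, float("inf"), "V>D")
    if v == 0.0:
        return DVRecord(gene_id, d, v, float("-inf"), "D>V")
    with np.errstate(divide="ignore"):
        ratio = float(np.log2(v / d))
    if ratio <= -DV_LOG2_THRESHOLD:
        cls = "D>V"
    elif ratio >= DV_LOG2_THRESHOLD:
        cls = "V>D"
    else:
        cls = "NS"
    return DVRecord(gene_id, d, v, ratio, cls)


def plane_averaged_dv(records_by_plane: dict) -> tuple:
    """Average dorsal/ventral means over planes C and L1 when both exist."""
    planes = [p for p in ("C", "L1") if p in records_by_plane]
    if not planes:
        raise ValueError("need a C or L1 record")
    d = float(np.mean([records_by_plane[p][0] for p in planes]))
    v = float(np.mean([records_by_plane[p][1] for p in planes]))
    return d, v


def dv_classify_fpkm(table: ExpressionTable) -> pd.DataFrame:
    """Per-gene DV classes and filter flags for an FPKM table.

    Expressed iff mean FPKM >= 0.1 in either group; tested iff mean FPKM over
    all samples >= 1; D>V / V>D by the inclusive 20% rule on group means;
    "significant" additionally requires the externally supplied flag.
    """
    means = table.group_means()
    overall = table.values.mean(axis=1)
    expressed = (means["dorsal"] >= 0.1) | (means["ventral"] >= 0.1)
    tested = overall >= 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(means["ventral"] / means["dorsal"])
    cls = pd.Series("NS", index=means.index)
    cls[ratio <= -DV_LOG2_THRESHOLD] = "D>V"
    cls[ratio >= DV_LOG2_THRESHOLD] = "V>D"
    cls[~tested] = "NS"
    cls[~expressed] = "unexpressed"
    sig = table.significant if table.significant is not None else pd.Series(
        False, index=means.index)
    out = pd.DataFrame({
        "mean_dorsal": means["dorsal"], "mean_ventral": means["ventral"],
        "log2_ratio": ratio, "expressed": expressed, "tested": tested,
        "dv_class": cls,
        "significant": sig & tested & (cls != "NS"),
    })
    return out


# ---------------------------------------------------------------------------
# gradients, profiles, correlations
# ---------------------------------------------------------------------------

def dv_gradient_slopes(image, layer_masks: dict, subregion_masks: list) -> dict:
    """OLS slope of mean intensity versus DV subregion index, per layer.

    Subregion 0 is dorsal.  Layers with fewer than 2 nonempty subregion cells
    get a NaN slope.  The "MEC" entry pools all layers.
    """
    arr = image_array(image).astype(float)
    out = {}
    for layer, lmask in list(layer_masks.items()) + [("MEC", None)]:
        xs, ys = [], []
        for i, smask in enumerate(subregion_masks):
            cell = smask if lmask is None else (np.asarray(lmask, bool) & smask)
            if cell.any():
                xs.append(i)
                ys.append(arr[cell].mean())
        if len(xs) < 2:
            out[layer] = float("nan")
            continue
        res = stats.linregress(xs, ys)
        out[layer] = float(res.slope)
    return out


def compare_aba_rnaseq(image_ratios, rnaseq_ratios) -> tuple:
    """(slope, Pearson r, two-sided p, n_used) for paired log2 DV ratios.

    Non-finite pairs are excluded (and counted against n_used); at least 3
    finite pairs are required and either coordinate being constant is an
    error (undefined correlation).
    """
    x = np.asarray(rnaseq_ratios, dtype=float)
    y = np.asarray(image_ratios, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 finite pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue), float(res.pvalue), int(len(x))


def depth_profile(image, region_mask, inner_boundary, outer_boundary,
                  n_bins: int = 20, gene_id: str = "", region: str = "MEC",
                  normalization: str | None = None) -> DepthProfile:
    """Bin region pixels by normalized depth and average their intensity.

    Depth of a pixel is d = D_in / (D_in + D_out) with D_* the Euclidean
    distances to the inner (white-matter) and outer (pial) boundary
    polylines; bin k covers [k/n, (k+1)/n), the last bin closed.  Pixels
    where both distances vanish are excluded and counted.  Optional
    normalization of the bin means: "sum" (divide by total) or "minmax".
    """
    arr = image_array(image).astype(float)
    region_mask = np.asarray(region_mask, dtype=bool)
    d_in = distance_transform_edt(~np.asarray(inner_boundary, dtype=bool))
    d_out = distance_transform_edt(~np.asarray(outer_boundary, dtype=bool))
    total = d_in + d_out
    ok = region_mask & (total > 0)
    excluded = int(region_mask.sum() - ok.sum())
    d = np.clip(d_in[ok] / total[ok], 0.0, 1.0)
    bins = np.minimum((d * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    sums = np.bincount(bins, weights=arr[ok], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if normalization == "sum":
        tot = np.nansum(means)
        if tot > 0:
            means = means / tot
    elif normalization == "minmax":
        lo, hi = np.nanmin(means), np.nanmax(means)
        if hi > lo:
            means = (means - lo) / (hi - lo)
    return DepthProfile(gene_id, region, means, counts, excluded, n_bins)


def deep_superficial_stat(profile: DepthProfile, boundary: float = 0.5,
                          expected: float | None = None) -> tuple:
    """(deep fraction, deviation from expectation, enrichment class).

    Deep means depth below ``boundary`` (toward the white matter).  The
    fraction is the deep share of intensity mass; a gene is deep-enriched
    above 0.6 and superficial-enriched below 0.4 (a 50% difference).
    """
    if not 0.0 < boundary < 1.0:
        raise ValueError("boundary must lie strictly inside (0, 1)")
    centers = (np.arange(profile.n_bins) + 0.5) / profile.n_bins
    mass = np.nan_to_num(profile.bin_means) * profile.bin_counts
    total = mass.sum()
    if total <= 0:
        raise ValueError("zero intensity mass; fraction undefined")
    frac = float(mass[centers < boundary].sum() / total)
    deviation = float("nan") if expected is None else float(abs(frac - expected))
    if frac > 0.6:
        cls = "deep"
    elif frac < 0.4:
        cls = "superficial"
    else:
        cls = "neither"
    return frac, deviation, cls


def layer_correlation_matrix(intensities: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between layer columns across genes.

    ``intensities`` is genes x layer columns (possibly spanning several
    cortical regions).  Constant columns yield NaN entries, reported missing.
    Requires at least 3 genes with finite values everywhere.
    """
    df = intensities.dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 genes with finite layer values")
    return df.corr(method="pearson")


def permutation_group_test(values_a, values_b, n_permutations: int = 10000,
                           seed: int = 0) -> tuple:
    """Two-sided permutation test on the difference of group means.

    A seeded label-shuffling alternative to parametric group inference;
    returns (observed difference, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = a.mean() - b.mean()
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = perm[:len(a)].mean() - perm[len(a):].mean()
        if abs(diff) >= abs(observed) - 1e-12:
            count += 1
    return float(observed), float((count + 1) / (n_permutations + 1))
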