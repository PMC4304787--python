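"""Regional and laminar intensity quantification and patterning scores.

Works on registered 8-bit expression images and atlas label masks.  The
central quantities:

* ``mINT`` — mean pixel intensity over a region mask (0-255);
* ``mINT_norm`` — the share A/(A+B) comparing two regions (0.5 = equal);
* laminar statistics per scoring layer x in {II, III, V/VI}: relative mean
  intensity ``Lx_rel`` (layer mean / sum of layer means), relative proportion
  of high-intensity pixels ``Lx_prop``, and a bounded absolute term
  ``Lx_abs = Lx_rel * 3 * MEC_mean``;
* patterning scores combining them,
  ``PS_single = w_rel*Lmax_rel + w_prop*Lmax_prop + w_abs*min(Lmax_abs, 1)``
  and the joint two-layer analogue, with default weights w_rel=0.4,
  w_prop=0.5, w_abs=0.1 and candidate thresholds PS_single >= 0.65 or
  PS_joint >= 0.88 (0.60 is the "moderate enrichment" alternative).

A high-intensity pixel is one with intensity >= MEC mean + 2 SD (population
SD) in scoring mode, or >= 2 * MEC mean in heatmap mode.  When an image has
no high-intensity pixels the proportion terms are zero and w_rel is raised
to 0.9 (leaving w_abs = 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import image_array

#: Fixed layer order used for deterministic tie-breaking in the ranking.
LAYER_ORDER = ("II", "III", "V/VI")


@dataclass
class RegionIntensity:
    gene_id: str
    probe_id: str
    plane: str
    region: str
    mint: float
    pixel_count: int


@dataclass
class ScoreWeights:
    """Patterning-score weights; ``w_abs`` is the remainder to 1."""

    w_rel: float = 0.4
    w_prop: float = 0.5
    w_mean: float = 0.4          # joint-score weight on the rel terms
    w_rel_no_high: float = 0.9   # override when no high-intensity pixels exist

    @property
    def w_abs(self) -> float:
        return 1.0 - (self.w_rel + self.w_prop)

    def validate(self) -> None:
        if min(self.w_rel, self.w_prop, self.w_abs, self.w_mean) < 0:
            raise ValueError("weights must be nonnegative")
        if abs(self.w_rel + self.w_prop + self.w_abs - 1.0) > 1e-9:
            raise ValueError("single-score weights must sum to 1")
        if abs(self.w_mean + self.w_prop + self.w_abs - 1.0) > 1e-9:
            raise ValueError("joint-score weights must sum to 1")


@dataclass
class LaminarScore:
    """Per-gene laminar statistics over the scoring layers."""

    layer_means: dict
    layer_high_counts: dict
    mec_mean: float
    high_threshold: float
    rel: dict = field(default_factory=dict)
    prop: dict = field(default_factory=dict)
    abs_: dict = field(default_factory=dict)
    lmax: str = ""
    lmid: str = ""
    lmin: str = ""
    lmax_diff: float = 0.0
    lmax_absjoint: float = 0.0
    no_high_pixels: bool = False
    eligible: bool = True


@dataclass
class PatterningResult:
    ps_single: float
    ps_joint: float
    candidate_class: str      # "single", "joint" or "none"
    evaluated: bool
    lmax: str = ""


# ---------------------------------------------------------------------------
# elementary regional statistics
# ---------------------------------------------------------------------------

def region_mean_intensity(image, mask, gene_id: str = "", probe_id: str = "",
                          plane: str = "", region: str = "") -> RegionIntensity:
    arr = image_array(image)
    m = np.asarray(mask, dtype=bool)
    if m.shape != arr.shape:
        raise ValueError("mask shape must match image")
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty region mask")
    return RegionIntensity(gene_id, probe_id, plane, region,
                           float(arr[m].mean()), n)


def average_series(series_regional_means, series_whole_means) -> dict:
    """Average replicate image series into comparable regional intensities.

    ``series_regional_means`` is a list of {region: mINT} dicts (one per
    series, same regions); ``series_whole_means`` the whole-image mean per
    series.  Each series contributes its *relative* regional pattern (regional
    mean / sum over regions); the mean relative pattern is rescaled by the
    mean whole-image intensity across series, so replicate sets whose overall
    staining differs agree on pattern and carry a common intensity scale.
    Returns all-zero values when no series shows any signal (unexpressed).
    """
    if not series_regional_means:
        raise ValueError("need at least one series")
    regions = list(series_regional_means[0])
    whole = np.asarray(series_whole_means, dtype=float)
    rel_rows = []
    for rec in series_regional_means:
        vals = np.array([rec[r] for r in regions], dtype=float)
        total = vals.sum()
        rel_rows.append(vals / total if total > 0 else np.zeros_like(vals))
    rel_mean = np.mean(rel_rows, axis=0)
    scale = whole.mean()
    if scale == 0 or rel_mean.sum() == 0:
        return {r: 0.0 for r in regions}
    return {r: float(rel_mean[i] * scale) for i, r in enumerate(regions)}


def is_expressed(mint_dorsal: float, mint_ventral: float) -> bool:
    """Expressed iff the dorsal or ventral regional mean reaches 1 (of 255)."""
    return max(mint_dorsal, mint_ventral) >= 1.0


def regional_enrichment(mint_mec: float, mint_other: float) -> tuple:
    """(enriched flag, mINT_norm) for MEC against one comparison region.

    Enriched iff the comparison region stays below 5 and either
    mINT_MEC >= 5 with norm >= 0.8, or 2 <= mINT_MEC < 5 with norm >= 0.99.
    """
    total = mint_mec + mint_other
    if total <= 0:
        return False, float("nan")
    norm = mint_mec / total
    if mint_other >= 5.0:
        return False, norm
    if mint_mec >= 5.0:
        return norm >= 0.8, norm
    if mint_mec >= 2.0:
        return norm >= 0.99, norm
    return False, norm


def border_candidate(mint_a: float, mint_b: float) -> bool:
    """Candidate border gene: < 15 in one region, differential > 15."""
    return min(mint_a, mint_b) < 15.0 and abs(mint_a - mint_b) > 15.0


def high_intensity_mask(image, mec_mask, mode: str = "scoring") -> tuple:
    """(threshold, mask of high-intensity pixels inside the MEC).

    "scoring" mode: threshold = MEC mean + 2 * population SD;
    "heatmap" mode: threshold = 2 * MEC mean.  Comparison is inclusive.
    """
    arr = image_array(image)
    m = np.asarray(mec_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty MEC mask")
    vals = arr[m].astype(float)
    if mode == "scoring":
        thr = float(vals.mean() + 2.0 * vals.std())
    elif mode == "heatmap":
        thr = float(2.0 * vals.mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mask = np.zeros_like(m)
    mask[m] = arr[m] >= thr
    return thr, mask


# ---------------------------------------------------------------------------
# laminar scoring
# ---------------------------------------------------------------------------

def score_from_measurements(layer_means: dict, layer_high_counts: dict,
                            mec_mean: float, high_threshold: float = float("nan"),
                            overall_mean: float | None = None) -> LaminarScore:
    """Assemble a :class:`LaminarScore` from measured layer statistics.

    Separated from image measurement so that hand-specified fixtures can be
    scored exactly.  Ranking is by Lx_rel + Lx_prop, descending, with ties
    broken by the fixed layer order II < III < V/VI.
    """
    layers = list(layer_means)
    means = np.array([layer_means[l] for l in layers], dtype=float)
    counts = np.array([layer_high_counts[l] for l in layers], dtype=float)
    score = LaminarScore(dict(layer_means), dict(layer_high_counts),
                         float(mec_mean), float(high_threshold))
    overall = mec_mean if overall_mean is None else overall_mean
    if means.sum() <= 0:
        score.eligible = False
        return score
    score.eligible = bool(overall >= 1.0 and means.max() >= 2.0)
    rel = means / means.sum()
    no_high = counts.sum() == 0
    prop = np.zeros_like(counts) if no_high else counts / counts.sum()
    score.no_high_pixels = bool(no_high)
    score.rel = {l: float(rel[i]) for i, l in enumerate(layers)}
    score.prop = {l: float(prop[i]) for i, l in enumerate(layers)}
    score.abs_ = {l: float(rel[i] * 3.0 * mec_mean) for i, l in enumerate(layers)}
    combined = rel + prop
    order = sorted(range(len(layers)),
                   key=lambda i: (-combined[i], LAYER_ORDER.index(layers[i])
                                  if layers[i] in LAYER_ORDER else i))
    score.lmax, score.lmid, score.lmin = (layers[order[0]], layers[order[1]],
                                          layers[order[2]])
    rmax, rmid, rmin = (score.rel[score.lmax], score.rel[score.lmid],
                        score.rel[score.lmin])
    amax = score.abs_[score.lmax]
    score.lmax_diff = ((rmax - rmid) ** 2 * amax / 255.0) * 30.0
    score.lmax_absjoint = ((rmax + rmid - rmin) ** 2 * amax / 255.0) * 30.0
    return score


def laminar_profile(image, layer_masks: dict, mec_mask=None,
                    mode: str = "scoring") -> LaminarScore:
    """Measure layer means and high-pixel counts, then score.

    ``layer_masks`` maps scoring-layer names to disjoint boolean masks;
    ``mec_mask`` (default: their union) defines the population for the
    high-intensity threshold and the overall eligibility mean.  Genes need an
    overall MEC mean >= 1 and >= 2 in at least one layer to be evaluated.
    """
    arr = image_array(image)
    masks = {l: np.asarray(m, dtype=bool) for l, m in layer_masks.items()}
    if len(masks) != 3:
        raise ValueError("expected the three scoring layers")
    stack = np.stack(list(masks.values()))
    if (stack.sum(axis=0) > 1).any():
        raise ValueError("layer masks must be disjoint")
    if any(not m.any() for m in masks.values()):
        raise ValueError("layer masks must be nonempty")
    if mec_mask is None:
        mec = stack.any(axis=0)
    else:
        mec = np.asarray(mec_mask, dtype=bool)
    thr, high = high_intensity_mask(arr, mec, mode)
    means = {l: float(arr[m].mean()) for l, m in masks.items()}
    counts = {l: int((high & m).sum()) for l, m in masks.items()}
    return score_from_measurements(means, counts, float(arr[mec].mean()), thr,
                                   overall_mean=float(arr[mec].mean()))


def patterning_scores(score: LaminarScore,
                      weights: ScoreWeights | None = None,
                      single_threshold: float = 0.65,
                      joint_threshold: float = 0.88) -> PatterningResult:
    """PS_single / PS_joint and the candidate call for one laminar score."""
    weights = weights or ScoreWeights()
    weights.validate()
    if not score.eligible:
        return PatterningResult(float("nan"), float("nan"), "none", False)
    w_rel, w_prop, w_mean = weights.w_rel, weights.w_prop, weights.w_mean
    w_abs = weights.w_abs
    if score.no_high_pixels:
        # Proportion terms vanish; w_rel rises to 0.9, leaving w_abs = 0.1.
        # Applied symmetrically to the joint score's w_mean.
        w_rel = w_mean = weights.w_rel_no_high
        w_prop = 0.0
        w_abs = 1.0 - weights.w_rel_no_high
    rmax, rmid = score.rel[score.lmax], score.rel[score.lmid]
    pmax, pmid = score.prop[score.lmax], score.prop[score.lmid]
    ps_single = (w_rel * rmax + w_prop * pmax
                 + w_abs * min(score.abs_[score.lmax], 1.0))
    ps_joint = (w_mean * (rmax + rmid) + w_prop * (pmax + pmid)
                + w_abs * min(score.lmax_absjoint, 1.0))
    if ps_single >= single_threshold:
        cls = "single"
    elif ps_joint >= joint_threshold:
        cls = "joint"
    else:
        cls = "none"
    return PatterningResult(float(ps_single), float(ps_joint), cls, True,
                            score.lmax)


# ---------------------------------------------------------------------------
# cross-correlation similarity search
# ---------------------------------------------------------------------------

def similarity_search(seed_image, cohort, roi_mask, top_n: int = 30,
                      mint_window: tuple = (1.0, 5.0),
                      ssd_vectors: dict | None = None,
                      ssd_tol: float = 0.0) -> list:
    """Rank cohort genes by pattern similarity to a seed gene over an ROI.

    ``cohort`` is a list of ``(gene_id, image)`` pairs.  Genes are first
    filtered to a mean-intensity window over the ROI; when ``ssd_vectors``
    (gene_id -> region-mean vector, with the seed under gene id ``None`` or
    its own id) is given, candidates must additionally have a sum-of-squares
    difference <= ``ssd_tol`` from the seed vector (exact zeros are attainable
    after integer quantization of region means).  Survivors are ranked by the
    Pearson correlation of ROI pixels with the seed.  An empty post-filter
    cohort yields an empty list.
    """
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    seed_vals = image_array(seed_image)[roi].astype(float)
    if seed_vals.std() == 0:
        raise ValueError("seed has no variance over the ROI")
    seed_vec = None
    if ssd_vectors is not None:
        seed_vec = np.asarray(ssd_vectors.get(None), dtype=float)
    ranked = []
    for gene_id, img in cohort:
        vals = image_array(img)[roi].astype(float)
        mint = vals.mean()
        if not (mint_window[0] <= mint < mint_window[1]):
            continue
        if seed_vec is not None:
            vec = np.asarray(ssd_vectors.get(gene_id), dtype=float)
            if vec is None or np.sum((vec - seed_vec) ** 2) > ssd_tol:
                continue
        if vals.std() == 0:
            continue
        r = float(np.corrcoef(seed_vals, vals)[0, 1])
        ranked.append((gene_id, r))
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked[:top_n]
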