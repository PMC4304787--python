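"""Synthetic medial entorhinal cortex (MEC) scenes with known ground truth.

This module fabricates everything the downstream stages consume, so the whole
pipeline is testable without any atlas download:

* a reference scene — an anatomy-like 8-bit image of a sagittal MEC wedge with
  5 cellular layers (II, III, Va, Vb, VI), the cell-sparse layer I and lamina
  dissecans, and neighboring regions, plus a label mask that tiles the wedge;
* gene-image cohorts — one expression image (and a companion pseudo-ISH image)
  per gene/plane/replicate, drawn from a truth record that fixes the laminar
  class (layer-specific, differentially expressed, island, inter-island,
  uniform, none), per-layer base intensities, a dorsoventral log2 gradient
  coefficient and a pixel-noise level;
* deformed copies under a smooth random B-spline warp with a known field, as
  registration fixtures;
* FPKM tables statistically coupled to the image gradients, emulating pooled
  dorsal/ventral RNA-Seq samples.

Geometry conventions: row 0 is dorsal, the dorsoventral axis runs down the
rows; cortical depth runs along the columns from the white-matter boundary
(left, depth 0) to the pial surface (right, depth 1).  The dorsoventral
modulation of a gene with coefficient ``g`` is ``2**(g * u(row))`` where ``u``
is 0 at the dorsal sampling box center and 1 at the ventral one, so the
log2 ventral/dorsal ratio of box means equals ``g`` up to pixelation and
8-bit quantization.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .images import IntensityImage, LabelMask, as_uint8, image_array

# Cellular layers in generation order, deep to superficial, as (name, depth span).
LAYER_SPANS = (
    ("MEC_LVI", 0.00, 0.18),
    ("MEC_LVb", 0.18, 0.33),
    ("MEC_LVa", 0.33, 0.47),
    ("MEC_LD", 0.47, 0.55),   # lamina dissecans (layer IV), cell sparse
    ("MEC_LIII", 0.55, 0.75),
    ("MEC_LII", 0.75, 0.92),
    ("MEC_LI", 0.92, 1.0001),  # molecular layer under the pial surface
)

MEC_LAYERS = tuple(name for name, _, _ in LAYER_SPANS)
CELLULAR_LAYERS = ("MEC_LII", "MEC_LIII", "MEC_LVa", "MEC_LVb", "MEC_LVI")

#: Laminar scoring groups: V and VI are pooled, as their border is unclear in
#: sagittal sections.
SCORING_GROUPS = {
    "II": ("MEC_LII",),
    "III": ("MEC_LIII",),
    "V/VI": ("MEC_LVa", "MEC_LVb", "MEC_LVI"),
}

DEFAULT_VOCABULARY = (
    "background",
    *MEC_LAYERS,
    "parasubiculum",   # dorsal neighbor
    "ventral_cortex",  # ventral neighbor
    "subiculum",       # medial neighbor at the deep border
)

# Anatomy (cell-density proxy) intensities for the reference/pseudo-ISH image.
_ANATOMY_BASE = {
    "background": 0,
    "MEC_LI": 30,
    "MEC_LII": 140,
    "MEC_LIII": 90,
    "MEC_LD": 20,
    "MEC_LVa": 100,
    "MEC_LVb": 75,
    "MEC_LVI": 110,
    "parasubiculum": 85,
    "ventral_cortex": 70,
    "subiculum": 45,
}

GENE_KINDS = ("layer_specific", "de", "island", "inter_island", "uniform", "none")


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and vocabulary of the synthetic reference frame.

    The default 300x225 frame at 40 um/px is a 4x scale-down of the full-size
    1200x900 processing canvas; pass ``width=1200, height=900,
    pixel_size_um=10`` for the full-scale convention.
    """

    width: int = 300
    height: int = 225
    pixel_size_um: float = 40.0
    col_span: tuple = (0.35, 0.88)     # white matter / pial columns, as width fractions
    row_span: tuple = (0.08, 0.92)     # dorsal / ventral extent, as height fractions
    curvature_px: float = 8.0          # parabolic bowing of the laminar boundaries
    dv_box_frac: float = 0.18          # dorsal/ventral sampling-box height fraction
    vocabulary: tuple = DEFAULT_VOCABULARY
    seed: int = 0

    def validate(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("frame must be at least 64x64 pixels")
        if not (0 <= self.col_span[0] < self.col_span[1] <= 1):
            raise ValueError("invalid column span")
        if not (0 <= self.row_span[0] < self.row_span[1] <= 1):
            raise ValueError("invalid row span")
        band_px = (self.col_span[1] - self.col_span[0]) * self.width
        if band_px - self.curvature_px < 20:
            raise ValueError(
                "frame too small to contain the configured band geometry"
            )
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("duplicate labels in vocabulary")


class SceneGeometry:
    """Deterministic geometry derived from a :class:`SceneConfig`.

    Exposes the label grid, the continuous depth coordinate ``t`` (0 at the
    white-matter boundary, 1 at the pial surface), the dorsoventral coordinate
    ``u`` (0/1 at the dorsal/ventral box centers) and boundary polyline masks.
    """

    def __init__(self, config: SceneConfig):
        config.validate()
        self.config = config
        H, W = config.height, config.width
        self.r0 = int(round(config.row_span[0] * H))
        self.r1 = int(round(config.row_span[1] * H))
        c0 = config.col_span[0] * W
        c1 = config.col_span[1] * W

        rows = np.arange(H, dtype=float)
        rm = 0.5 * (self.r0 + self.r1 - 1)
        rh = 0.5 * (self.r1 - self.r0)
        bow = config.curvature_px * ((rows - rm) / rh) ** 2
        self.wm_col = c0 - 0.6 * bow
        self.pial_col = c1 - bow

        cols = np.arange(W, dtype=float)
        t = (cols[None, :] - self.wm_col[:, None]) / (
            self.pial_col[:, None] - self.wm_col[:, None]
        )
        in_rows = (rows >= self.r0) & (rows < self.r1)
        self.in_mec = in_rows[:, None] & (t >= 0.0) & (t <= 1.0)
        self.t = np.where(self.in_mec, t, np.nan)

        labels = np.zeros((H, W), dtype=np.int64)
        legend = {name: i for i, name in enumerate(config.vocabulary)}
        for name, lo, hi in LAYER_SPANS:
            sel = self.in_mec & (t >= lo) & (t < hi)
            labels[sel] = legend[name]

        # Neighbor regions share the wedge column profile.
        nh = max(4, int(round(0.07 * H)))
        band = (t >= 0.0) & (t <= 1.0)
        dorsal_rows = (rows >= self.r0 - nh) & (rows < self.r0)
        ventral_rows = (rows >= self.r1) & (rows < self.r1 + nh)
        labels[dorsal_rows[:, None] & band] = legend["parasubiculum"]
        labels[ventral_rows[:, None] & band] = legend["ventral_cortex"]
        aw = max(4, int(round(0.08 * W)))
        medial = in_rows[:, None] & (
            (cols[None, :] >= self.wm_col[:, None] - aw)
            & (cols[None, :] < self.wm_col[:, None])
        )
        labels[medial] = legend["subiculum"]

        self.labels = labels
        self.legend = legend

        # Dorsoventral coordinate normalized to the sampling-box centers.
        h = max(2, int(round(config.dv_box_frac * (self.r1 - self.r0))))
        self.box_height = h
        rd = self.r0 + 0.5 * (h - 1)
        rv = self.r1 - 1 - 0.5 * (h - 1)
        self.u = (rows - rd) / (rv - rd)

    # -- derived masks -----------------------------------------------------
    def label_mask(self) -> LabelMask:
        return LabelMask(self.labels.copy(), dict(self.legend))

    def mec_mask(self) -> np.ndarray:
        out = np.zeros_like(self.in_mec)
        for name in MEC_LAYERS:
            out |= self.labels == self.legend[name]
        return out

    def group_masks(self) -> dict:
        """Masks for the II / III / V-VI scoring groups, in fixed order."""
        return {
            group: np.isin(self.labels, [self.legend[n] for n in names])
            for group, names in SCORING_GROUPS.items()
        }

    def dv_boxes(self) -> tuple:
        mec = self.mec_mask()
        rows = np.arange(self.config.height)
        dorsal = mec & (rows[:, None] < self.r0 + self.box_height)
        ventral = mec & (rows[:, None] >= self.r1 - self.box_height)
        return dorsal, ventral

    def boundary_masks(self) -> tuple:
        """(inner white-matter, outer pial) boundary polylines as pixel masks."""
        H, W = self.labels.shape
        inner = np.zeros((H, W), dtype=bool)
        outer = np.zeros((H, W), dtype=bool)
        for r in range(self.r0, self.r1):
            ci = int(np.ceil(self.wm_col[r]))
            co = int(np.floor(self.pial_col[r]))
            inner[r, np.clip(ci, 0, W - 1)] = True
            outer[r, np.clip(co, 0, W - 1)] = True
        return inner, outer

    def dv_subregions(self, n: int = 5) -> list:
        """MEC masks for n equal row bands along the dorsoventral axis."""
        mec = self.mec_mask()
        edges = np.linspace(self.r0, self.r1, n + 1)
        rows = np.arange(self.config.height)[:, None]
        out = []
        for i in range(n):
            hi = edges[i + 1] if i < n - 1 else self.r1 + 0.5
            out.append(mec & (rows >= edges[i]) & (rows < hi))
        return out


@dataclass
class SyntheticTruth:
    """Ground-truth record for one simulated gene."""

    gene_id: str
    kind: str
    target_layers: tuple = ()
    layer_bases: dict = field(default_factory=dict)
    dv_g: float = 0.0
    noise_sd: float = 0.0
    n_probes: int = 1
    n_replicates: int = 1
    fpkm_base: float = 5.0
    #: Noise-free log2(V/D) actually encoded in the rendered image; equals
    #: dv_g for r-homogeneous patterns but differs for island substructure
    #: (island placement modulates the box means).  Set by the cohort
    #: generator; None means "not rendered yet" and falls back to dv_g.
    realized_log2_dv: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown gene class {self.kind!r}")
        for name, base in self.layer_bases.items():
            if name not in MEC_LAYERS:
                raise ValueError(f"layer {name!r} outside vocabulary")
            if not 0 <= base <= 255:
                raise ValueError("base intensities must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")

    @property
    def expressed(self) -> bool:
        return self.kind != "none"

    @property
    def expected_group(self):
        """Scoring group a laminar classifier should assign, or None."""
        if self.kind in ("layer_specific",):
            target = self.target_layers[0]
            for group, names in SCORING_GROUPS.items():
                if target in names:
                    return group
        if self.kind in ("island", "inter_island"):
            return "II"
        return None

    @property
    def effective_dv(self) -> float:
        """The dorsoventral log2 ratio the rendered scene actually carries."""
        return self.dv_g if self.realized_log2_dv is None else self.realized_log2_dv

    @property
    def expected_dv_class(self) -> str:
        if not self.expressed:
            return "unexpressed"
        thr = float(np.log2(1.2))
        if self.effective_dv <= -thr:
            return "D>V"
        if self.effective_dv >= thr:
            return "V>D"
        return "NS"


@dataclass
class GroundTruthDeformation:
    """Known B-spline warp used to fabricate registration fixtures."""

    grid_spacing: float
    displacements: np.ndarray   # (2, n_ctrl_rows, n_ctrl_cols), pixels
    amplitude: float
    shape: tuple

    def dense_field(self) -> np.ndarray:
        from .register import BsplineField

        f = BsplineField(self.shape, self.grid_spacing)
        f.coeff = self.displacements.astype(float)
        return f.dense_field()

    def inverse_field(self, n_iter: int = 30) -> np.ndarray:
        """Exact inverse displacement by fixed-point iteration.

        Returns the field u with image(x + d(x + u(x))) == image(x), i.e. the
        displacement a registration recovering this warp should report.
        """
        d = self.dense_field()
        H, W = self.shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        u = -d.copy()
        for _ in range(n_iter):
            sy = yy + u[0]
            sx = xx + u[1]
            dy = map_coordinates(d[0], [sy, sx], order=1, mode="nearest")
            dx = map_coordinates(d[1], [sy, sx], order=1, mode="nearest")
            u = -np.stack([dy, dx])
        return u


@dataclass
class GeneImageRecord:
    """One simulated expression/pseudo-ISH image pair."""

    gene_id: str
    probe_id: str
    plane: str
    replicate: int
    expression: IntensityImage
    ish: IntensityImage


# ---------------------------------------------------------------------------
# reference scene
# ---------------------------------------------------------------------------

def generate_reference_scene(config: SceneConfig) -> tuple:
    """Anatomy-like reference image plus its label mask.

    Deterministic for a fixed ``config.seed``; every label of the vocabulary
    is present in the mask.
    """
    geom = SceneGeometry(config)
    rng = np.random.default_rng(config.seed)
    img = np.zeros((config.height, config.width), dtype=float)
    for name, value in _ANATOMY_BASE.items():
        img[geom.labels == geom.legend[name]] = value
    texture = rng.normal(0.0, 4.0, img.shape)
    img = np.where(geom.labels > 0, img + texture, img)
    _, outer = geom.boundary_masks()
    img[outer] = 185.0
    return IntensityImage(as_uint8(img), {"role": "reference", "plane": "C"}), geom.label_mask()


# ---------------------------------------------------------------------------
# gene cohorts
# ---------------------------------------------------------------------------

def _island_field(geom: SceneGeometry, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of Poisson-disc-placed elliptical islands inside layer II."""
    lo, hi = 0.75, 0.92
    tc = 0.5 * (lo + hi)
    H, W = geom.labels.shape
    centers = []
    min_gap = 18.0
    for _ in range(200):
        r = rng.uniform(geom.r0 + 6, geom.r1 - 6)
        if all(abs(r - rc) >= min_gap for rc in centers):
            centers.append(r)
    rows = np.arange(H, dtype=float)[:, None]
    inside = np.zeros((H, W), dtype=bool)
    for rc in centers:
        rr = rng.uniform(5.0, 8.0)
        rt = 0.55 * (hi - lo)
        e = ((rows - rc) / rr) ** 2 + ((geom.t - tc) / rt) ** 2
        inside |= np.nan_to_num(e, nan=np.inf) <= 1.0
    lii = geom.labels == geom.legend["MEC_LII"]
    return inside & lii


def expression_field(truth: SyntheticTruth, geom: SceneGeometry,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Noise-free continuous expression field for one gene.

    Applies per-layer base intensities, island/inter-island substructure and
    the dorsoventral modulation ``2**(g*u)``, then rescales globally so the
    field fits in [0, 255] (a global rescale preserves all ratios).
    """
    field_ = np.zeros(geom.labels.shape, dtype=float)
    for name, base in truth.layer_bases.items():
        field_[geom.labels == geom.legend[name]] = base
    if truth.kind in ("island", "inter_island"):
        if rng is None:
            rng = np.random.default_rng(0)
        islands = _island_field(geom, rng)
        lii = geom.labels == geom.legend["MEC_LII"]
        keep = islands if truth.kind == "island" else (lii & ~islands)
        field_[lii & ~keep] = min(4.0, field_[lii].max() * 0.03)
    if truth.dv_g != 0.0:
        field_ = field_ * np.power(2.0, truth.dv_g * geom.u)[:, None]
    peak = field_.max()
    if peak > 255.0:
        field_ *= 255.0 / peak
    return field_


def _add_lognormal_noise(field_: np.ndarray, sd: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Mean-preserving lognormal pixel noise with SD ``sd`` intensity units."""
    if sd <= 0:
        return field_
    m = np.maximum(field_, 1e-9)
    sigma2 = np.log1p(sd ** 2 / m ** 2)
    mu = np.log(m) - 0.5 * sigma2
    noisy = np.exp(rng.normal(mu, np.sqrt(sigma2)))
    return np.where(field_ > 0, noisy, 0.0)


def generate_gene_cohort(truths: Sequence[SyntheticTruth], config: SceneConfig,
                         seed: int, planes: tuple = ("C", "L1")) -> tuple:
    """Render one expression + pseudo-ISH image per gene/probe/plane/replicate.

    Returns ``(records, truth_table)``; the table is a tidy DataFrame with one
    row per gene carrying the generating parameters.
    """
    if not truths:
        raise ValueError("truth list must be non-empty")
    geom = SceneGeometry(config)
    anatomy = image_array(generate_reference_scene(config)[0]).astype(float)
    rng = np.random.default_rng(seed)
    records = []
    dorsal_box, ventral_box = geom.dv_boxes()
    for truth in truths:
        island_rng = np.random.default_rng(rng.integers(2 ** 31))
        base = expression_field(truth, geom, island_rng)
        md, mv = base[dorsal_box].mean(), base[ventral_box].mean()
        truth.realized_log2_dv = (float(np.log2(mv / md))
                                  if md > 0 and mv > 0 else None)
        for probe in range(truth.n_probes):
            for plane in planes:
                for rep in range(truth.n_replicates):
                    noisy = _add_lognormal_noise(
                        base, truth.noise_sd, np.random.default_rng(rng.integers(2 ** 31))
                    )
                    expr = IntensityImage(
                        as_uint8(noisy),
                        {"gene_id": truth.gene_id, "probe_id": f"{truth.gene_id}.p{probe}",
                         "plane": plane, "replicate": rep},
                    )
                    ish = IntensityImage(
                        as_uint8(np.maximum(anatomy, 0.7 * noisy)),
                        dict(expr.meta, role="ish"),
                    )
                    records.append(GeneImageRecord(
                        truth.gene_id, f"{truth.gene_id}.p{probe}", plane, rep, expr, ish
                    ))
    table = pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in truths],
            "kind": [t.kind for t in truths],
            "target_layers": ["+".join(t.target_layers) for t in truths],
            "expected_group": [t.expected_group or "" for t in truths],
            "dv_g": [t.dv_g for t in truths],
            "realized_log2_dv": [t.effective_dv if t.expressed else float("nan")
                                 for t in truths],
            "expected_dv_class": [t.expected_dv_class for t in truths],
            "noise_sd": [t.noise_sd for t in truths],
            "fpkm_base": [t.fpkm_base for t in truths],
        }
    )
    return records, table


def make_default_truth(n: int = 200, seed: int = 0,
                       noise_sd: float = 2.0) -> list:
    """Default cohort mix: per 20 genes, 5 layer-specific (one per cellular
    layer), 3 differentially expressed two-group pairs, 1 island, 1
    inter-island, 6 uniform and 4 unexpressed; dorsoventral coefficients cycle
    through {0, +/-0.585, +/-1.0}."""
    rng = np.random.default_rng(seed)
    on, off = 120.0, 4.0
    de_pairs = (
        ("MEC_LII", "MEC_LIII"),
        ("MEC_LIII", "MEC_LVa", "MEC_LVb", "MEC_LVI"),
        ("MEC_LII", "MEC_LVa", "MEC_LVb", "MEC_LVI"),
    )
    g_cycle = (0.0, 0.585, -0.585, 1.0, 0.0, -1.0)
    truths = []
    gi = 0

    def add(kind, targets=(), bases=None, fpkm=5.0):
        nonlocal gi
        g = g_cycle[gi % len(g_cycle)] if kind != "none" else 0.0
        truths.append(SyntheticTruth(
            gene_id=f"g{gi:04d}", kind=kind, target_layers=tuple(targets),
            layer_bases=bases or {}, dv_g=g, noise_sd=noise_sd if kind != "none" else 0.0,
            fpkm_base=fpkm,
        ))
        gi += 1

    while gi < n:
        for layer in CELLULAR_LAYERS:
            bases = {l: (on if l == layer else off) for l in CELLULAR_LAYERS}
            add("layer_specific", (layer,), bases, fpkm=8.0)
        for pair in de_pairs:
            bases = {l: (on if l in pair else off) for l in CELLULAR_LAYERS}
            add("de", pair, bases, fpkm=10.0)
        add("island", ("MEC_LII",),
            {l: (140.0 if l == "MEC_LII" else off) for l in CELLULAR_LAYERS}, fpkm=6.0)
        add("inter_island", ("MEC_LII",),
            {l: (140.0 if l == "MEC_LII" else off) for l in CELLULAR_LAYERS}, fpkm=6.0)
        for _ in range(6):
            add("uniform", (), {l: 30.0 for l in CELLULAR_LAYERS}, fpkm=7.0)
        for _ in range(4):
            add("none", (), {}, fpkm=0.01)
    del rng  # composition is deterministic; rng reserved for future jitter
    return truths[:n]


# ---------------------------------------------------------------------------
# registration fixtures
# ---------------------------------------------------------------------------

def generate_deformed_copy(image, amplitude: float, seed: int,
                           grid_spacing: float = 32.0) -> tuple:
    """Warp an image by a smooth random B-spline field of bounded amplitude.

    The warped image is the pull-back ``out(x) = image(x + d(x))`` with
    bilinear sampling; the ground-truth field ``d`` is returned.  Amplitudes
    above a quarter of the frame size are rejected (risk of folding).
    """
    arr = image_array(image)
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if amplitude > min(arr.shape) / 4:
        raise ValueError("amplitude larger than a quarter of the frame")
    from .register import BsplineField

    f = BsplineField(arr.shape, grid_spacing)
    rng = np.random.default_rng(seed)
    f.coeff = rng.uniform(-amplitude, amplitude, size=f.coeff.shape)
    truth = GroundTruthDeformation(grid_spacing, f.coeff.copy(), amplitude, arr.shape)
    d = f.dense_field()
    H, W = arr.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    warped = map_coordinates(arr.astype(float), [yy + d[0], xx + d[1]],
                             order=1, cval=0.0)
    meta = dict(image.meta) if isinstance(image, IntensityImage) else {}
    meta["deformed"] = True
    return IntensityImage(as_uint8(warped), meta), truth


# ---------------------------------------------------------------------------
# artifacts for the quality-control classifier
# ---------------------------------------------------------------------------

def inject_artifacts(image, geom: SceneGeometry, seed: int,
                     holes: bool = True, streak: bool = True) -> IntensityImage:
    """Add tissue holes (zeroed discs) and/or a bright pial-surface streak."""
    arr = image_array(image).astype(float)
    rng = np.random.default_rng(seed)
    H, W = arr.shape
    if holes:
        # Bubbles only read as holes where they occlude stained tissue.
        stained = (geom.labels > 0) & (arr >= 20.0)
        ys, xs = np.nonzero(stained if stained.any() else (geom.labels > 0))
        yy, xx = np.mgrid[0:H, 0:W]
        for _ in range(rng.integers(3, 8)):
            i = rng.integers(len(ys))
            rad = rng.uniform(6.0, 16.0)   # 240-640 um bubbles at 40 um/px
            arr[(yy - ys[i]) ** 2 + (xx - xs[i]) ** 2 <= rad ** 2] = 0.0
    if streak:
        _, outer = geom.boundary_masks()
        from scipy.ndimage import binary_dilation

        band = binary_dilation(outer, iterations=int(rng.integers(1, 3)))
        arr[band] = 235.0
    meta = dict(image.meta) if isinstance(image, IntensityImage) else {}
    meta["artifact"] = True
    return IntensityImage(as_uint8(arr), meta)


def generate_qc_cohort(config: SceneConfig, n_clean: int, n_artifact: int,
                       seed: int, noise_sd: float = 2.0) -> tuple:
    """Clean vs artifact-injected expression images for classifier training.

    Both groups are drawn from the same gene mix so the classifier must key on
    the artifacts, not on gene identity.  Returns ``(images, labels)`` with
    label 1 for artifact-laden images.
    """
    geom = SceneGeometry(config)
    truths = [t for t in make_default_truth(40, seed, noise_sd) if t.kind != "none"]
    rng = np.random.default_rng(seed + 1)
    images, labels = [], []
    for i in range(n_clean + n_artifact):
        truth = truths[int(rng.integers(len(truths)))]
        f = expression_field(truth, geom, np.random.default_rng(rng.integers(2 ** 31)))
        f = _add_lognormal_noise(f, noise_sd, np.random.default_rng(rng.integers(2 ** 31)))
        img = IntensityImage(as_uint8(f), {"gene_id": truth.gene_id})
        if i >= n_clean:
            which = int(rng.integers(3))  # holes, streak, or both
            img = inject_artifacts(img, geom, int(rng.integers(2 ** 31)),
                                   holes=which != 1, streak=which != 0)
            labels.append(1)
        else:
            labels.append(0)
        images.append(img)
    return images, labels


# ---------------------------------------------------------------------------
# FPKM tables
# ---------------------------------------------------------------------------

def generate_fpkm_table(truths: Sequence[SyntheticTruth], n_replicates: int = 4,
                        noise_sd: float = 0.15, seed: int = 0):
    """Dorsal/ventral FPKM table coupled to the image dorsoventral gradients.

    Group means are ``fpkm_base * 2**(-g/2)`` (dorsal) and
    ``fpkm_base * 2**(+g/2)`` (ventral); replicates are lognormally perturbed
    with log-SD ``noise_sd``.  Genes marked unexpressed get FPKM < 0.1.  The
    emitted significance flag emulates an external differential-expression
    call (|g| past the 20% threshold), as such flags are consumed, never
    computed, downstream.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    if noise_sd < 0:
        raise ValueError("noise SD must be nonnegative")
    from .gradients import DV_LOG2_THRESHOLD, ExpressionTable

    rng = np.random.default_rng(seed)
    cols = [f"dorsal_{i+1}" for i in range(n_replicates)] + \
           [f"ventral_{i+1}" for i in range(n_replicates)]
    groups = {c: ("dorsal" if c.startswith("d") else "ventral") for c in cols}
    rows, sig = [], []
    for t in truths:
        base = t.fpkm_base if t.expressed else 0.01
        g = t.effective_dv
        means = [base * 2.0 ** (-g / 2)] * n_replicates + \
                [base * 2.0 ** (g / 2)] * n_replicates
        if noise_sd > 0:
            vals = [m * float(np.exp(rng.normal(-noise_sd ** 2 / 2, noise_sd)))
                    for m in means]
        else:
            vals = means
        rows.append(vals)
        sig.append(bool(t.expressed and base >= 1.0
                        and abs(g) >= DV_LOG2_THRESHOLD))
    values = pd.DataFrame(rows, index=[t.gene_id for t in truths], columns=cols)
    values.index.name = "gene_id"
    return ExpressionTable(values, groups, pd.Series(sig, index=values.index))


def scaled_config(config: SceneConfig, factor: int) -> SceneConfig:
    """Scale the frame up (e.g. 4x to the full 1200x900 convention)."""
    return replace(config, width=config.width * factor,
                   height=config.height * factor,
                   pixel_size_um=config.pixel_size_um / factor,
                   curvature_px=config.curvature_px * factor)
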