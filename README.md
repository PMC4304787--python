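# lamina

Laminar- and dorsoventral-resolution analysis of gene-expression images of
the medial entorhinal cortex (MEC), with a built-in synthetic benchmark.

Large in-situ hybridization (ISH) atlases encode a gene's expression as an
8-bit "expression image" whose pixel intensity proxies transcript abundance.
Turning ~10⁴ such images into statements like *"this gene is specific to MEC
layer II"* or *"this gene is expressed dorsally but not ventrally"* requires
a chain of image processing and scoring steps: preprocessing that strips
gene-specific signal while keeping anatomical landmarks, mutual-information
B-spline registration of every image into a common reference frame,
automated quality control, laminar intensity quantification with a
patterning-score classification, dorsoventral (DV) gradient analysis
cross-validated against RNA-Seq, and gene-set overrepresentation statistics.
`lamina` implements that chain for anyone who wants to quantify laminar or
graded cortical expression — and, because the real atlas corpus is not
shippable, pairs it with a first-class synthetic-data generator whose scenes
carry exact ground truth, so every stage is testable end to end.

## The statistics at the core

For each gene, with layer set x ∈ {II, III, V/VI} (V and VI pooled):

- `Lx_rel` — layer mean intensity / Σ layer means,
- `Lx_prop` — layer share of *high-intensity* pixels (intensity ≥ MEC mean
  + 2·SD),
- `Lx_abs = Lx_rel × 3 × MEC_mean`,
- layers ranked by `Lx_rel + Lx_prop` into Lmax / Lmid / Lmin,
- `Lmax_absjoint = ((Lmax_rel + Lmid_rel − Lmin_rel)² × Lmax_abs / 255) × 30`.

Patterning scores with weights w_rel = 0.4, w_prop = 0.5,
w_abs = 1 − (w_rel + w_prop) (w_rel → 0.9 if the image has no
high-intensity pixels):

    PS_single = w_rel·Lmax_rel + w_prop·Lmax_prop + w_abs·min(Lmax_abs, 1)
    PS_joint  = w_mean·(Lmax_rel + Lmid_rel) + w_prop·(Lmax_prop + Lmid_prop)
                + w_abs·min(Lmax_absjoint, 1)

A gene is a layer-patterned candidate iff PS_single ≥ 0.65 or
PS_joint ≥ 0.88.  Dorsoventral classification uses the inclusive 20% rule on
regional means: D>V iff log₂(V/D) ≤ −log₂(1.2) = −0.2630, V>D iff ≥ +0.2630,
applied identically to image intensities and FPKM tables.  Registration
maximizes mutual information of a cubic B-spline warp under a bending-energy
penalty (weight λ = 0.1); QC fails an image iff its MI score is poor or at
least two of {cross-correlation offset, classifier probability > 0.13}
flags are raised.  Enrichment uses exact one/two-sided Fisher tests with
Benjamini–Hochberg adjustment and Cohen's-kappa clustering of redundant
terms (report a term only if no more significant term overlaps it at
κ ≥ 0.7).

## Worked example

```python
from lamina import synthdata as sd, quantify as qt
from lamina.gradients import dv_classify_image
from lamina.images import image_array

config = sd.SceneConfig()                      # 300x225 frame, 40 um/px
geometry = sd.SceneGeometry(config)
truth = sd.SyntheticTruth(
    "demo", "layer_specific", ("MEC_LII",),
    {l: (120.0 if l == "MEC_LII" else 4.0) for l in sd.CELLULAR_LAYERS},
    dv_g=-1.0)                                 # 2-fold dorsal enrichment
records, _ = sd.generate_gene_cohort([truth], config, seed=1, planes=("C",))

image = records[0].expression
score = qt.laminar_profile(image, geometry.group_masks(), geometry.mec_mask())
result = qt.patterning_scores(score)
print(result.lmax, round(result.ps_single, 3), result.candidate_class)

arr = image_array(image)
dorsal, ventral = geometry.dv_boxes()
rec = dv_classify_image(arr[dorsal].mean(), arr[ventral].mean())
print(round(rec.log2_ratio, 3), rec.dv_class)
```

prints

```
II 0.975 single
-0.999 D>V
```

i.e. the gene is called a layer-II-specific candidate (PS_single = 0.975,
above the 0.65 threshold) and dorsally enriched with the measured
log₂(ventral/dorsal) ratio within a hundredth of the generating coefficient
−1.

The numbered scripts under `analysis/` run the full study on the synthetic
cohort (simulation, registration benchmark, QC benchmark, laminar
quantification, dorsoventral analysis, enrichment) and write their tables
under `results/`.  The same pipeline is scriptable from a shell:
`lamina run --seed 7 --out results/run` or `lamina simulate --genes 200
--out results/sim`.

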