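"""End-to-end orchestration: simulate -> preprocess -> register -> qc ->
quantify -> gradients -> enrich, from a single validated configuration.

Every stage parameter defaults to the analysis' standard value (patterning
thresholds 0.65/0.88, DV threshold log2(1.2), classifier flag 0.13, border
rule 15/15, enrichment rules 5/0.8/0.99, 20 depth bins, 5 DV subregions,
rolling-ball radius 1, regularization weight 0.1, weights 0.4/0.5).  Runs are
fully reproducible from the seed; the JSON report contains no timestamps, so
two identical runs hash identically (timings go to the log stream only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gradients as gradmod
from . import qc as qcmod
from . import quantify as quantmod
from . import register as regmod
from . import synthdata
from .enrich import TermGeneSets, fisher_enrichment, kappa_matrix, cluster_terms, results_to_frame
from .images import image_array, write_image, write_mask

log = logging.getLogger("lamina")


def _from_dict(cls, data: dict):
    """Build a dataclass from a dict, rejecting unknown keys (typo guard)."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _from_dict(f.type, value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class StageToggles:
    simulate: bool = True
    preprocess: bool = True
    register: bool = True
    qc: bool = True
    quantify: bool = True
    gradients: bool = True
    enrich: bool = True


@dataclass
class CohortConfig:
    n: int = 60
    noise_sd: float = 2.0
    planes: tuple = ("C", "L1")


@dataclass
class RegisterStageConfig:
    deform_amplitude: float = 0.0   # warp applied before registration (0 = aligned input)
    grid_spacing: float = 16.0
    lam: float = 0.1
    bins: int = 32


@dataclass
class QCStageConfig:
    n_clean_train: int = 30
    n_artifact_train: int = 30
    mi_min: float = 0.15
    max_offset_px: float = 5.0
    classifier_threshold: float = qcmod.CLASSIFIER_FLAG_THRESHOLD


@dataclass
class QuantifyStageConfig:
    single_threshold: float = 0.65
    joint_threshold: float = 0.88
    w_rel: float = 0.4
    w_prop: float = 0.5
    w_mean: float = 0.4


@dataclass
class GradientStageConfig:
    n_subregions: int = 5
    n_depth_bins: int = 20


@dataclass
class FpkmStageConfig:
    n_replicates: int = 4
    noise_sd: float = 0.15


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/run"
    save_images: bool = False
    stages: StageToggles = field(default_factory=StageToggles)
    scene: synthdata.SceneConfig = field(default_factory=synthdata.SceneConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    register: RegisterStageConfig = field(default_factory=RegisterStageConfig)
    qc: QCStageConfig = field(default_factory=QCStageConfig)
    quantify: QuantifyStageConfig = field(default_factory=QuantifyStageConfig)
    gradients: GradientStageConfig = field(default_factory=GradientStageConfig)
    fpkm: FpkmStageConfig = field(default_factory=FpkmStageConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key, sub in (("stages", StageToggles), ("scene", synthdata.SceneConfig),
                         ("cohort", CohortConfig), ("register", RegisterStageConfig),
                         ("qc", QCStageConfig), ("quantify", QuantifyStageConfig),
                         ("gradients", GradientStageConfig), ("fpkm", FpkmStageConfig)):
            if key in data and isinstance(data[key], dict):
                data[key] = _from_dict(sub, data[key])
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        def norm(obj):
            if isinstance(obj, dict):
                return {k: norm(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [norm(v) for v in obj]
            return obj

        return norm(dataclasses.asdict(self))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def _run_id(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    A stage failure aborts with the failing stage named; outputs written so
    far are retained.  The report includes stage outputs, QC pass rates and,
    because the synthetic truth is available, truth-recovery tallies and a
    confusion matrix whose rows sum to the cohort size.
    """
    t_start = time.time()
    run_id = _run_id(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s %(message)s")
    log.info("run %s starting (seed %d)", run_id, config.seed)
    report = {"run_id": run_id, "seed": config.seed, "stages": {}}
    state = {}
    stage_order = ["simulate", "preprocess", "register", "qc", "quantify",
                   "gradients", "enrich"]
    for stage in stage_order:
        if not getattr(config.stages, stage):
            log.info("stage %s disabled", stage)
            continue
        t0 = time.time()
        try:
            _STAGES[stage](config, state, report, out)
        except Exception:
            log.error("stage %s failed", stage)
            report["failed_stage"] = stage
            (out / "report.json").write_text(json.dumps(report, indent=1,
                                                        sort_keys=True, default=str))
            raise
        log.info("stage %s done in %.1fs", stage, time.time() - t0)
    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                sort_keys=True, default=str))
    log.info("run %s finished in %.1fs", run_id, time.time() - t_start)
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, state, report, out) -> None:
    geom = synthdata.SceneGeometry(config.scene)
    ref_img, label_mask = synthdata.generate_reference_scene(config.scene)
    truths = synthdata.make_default_truth(config.cohort.n, config.seed,
                                          config.cohort.noise_sd)
    records, truth_table = synthdata.generate_gene_cohort(
        truths, config.scene, config.seed, tuple(config.cohort.planes))
    fpkm = synthdata.generate_fpkm_table(truths, config.fpkm.n_replicates,
                                         config.fpkm.noise_sd, config.seed + 1)
    state.update(geom=geom, reference=ref_img, label_mask=label_mask,
                 truths=truths, records=records, truth_table=truth_table,
                 fpkm=fpkm)
    truth_table.to_csv(out / "truth.tsv", sep="\t", index=False)
    fpkm.to_tsv(out / "fpkm.tsv")
    if config.save_images:
        write_image(out / "reference.png", ref_img)
        write_mask(out / "labels.tif", label_mask)
    report["stages"]["simulate"] = {
        "n_genes": len(truths), "n_images": len(records),
        "noise_sd": config.cohort.noise_sd,
    }


def _stage_preprocess(config, state, report, out) -> None:
    from .imageprep import PreprocessParams, preprocess_ish

    params = PreprocessParams(frame=(config.scene.height, config.scene.width))
    state["reference_prep"] = preprocess_ish(state["reference"], params)
    n = 0
    for rec in state["records"]:
        rec.ish = preprocess_ish(rec.ish, params)
        n += 1
    report["stages"]["preprocess"] = {"n_images": n}


def _stage_register(config, state, report, out) -> None:
    rc = config.register
    cfg = regmod.RegistrationConfig(grid_spacing=rc.grid_spacing, lam=rc.lam,
                                    bins=rc.bins)
    reference = state.get("reference_prep", state["reference"])
    mi_scores = {}
    n_warped = 0
    rng = np.random.default_rng(config.seed + 2)
    for rec in state["records"]:
        key = (rec.probe_id, rec.plane, rec.replicate)
        if rc.deform_amplitude > 0:
            seed = int(rng.integers(2 ** 31))
            moving, _ = synthdata.generate_deformed_copy(
                rec.ish, rc.deform_amplitude, seed)
            result = regmod.register_pairwise(moving, reference, cfg)
            expr_moved, _ = synthdata.generate_deformed_copy(
                rec.expression, rc.deform_amplitude, seed)
            rec.expression = regmod.apply_transform(expr_moved, result.model)
            rec.ish = regmod.apply_transform(moving, result.model)
            mi_scores[key] = result.mi_final
            n_warped += 1
        else:
            mi_scores[key] = regmod.mutual_information(rec.ish, reference,
                                                       rc.bins)
    state["mi_scores"] = mi_scores
    report["stages"]["register"] = {
        "n_images": len(state["records"]), "n_warped": n_warped,
        "lambda": rc.lam,
    }


def _stage_qc(config, state, report, out) -> None:
    qcc = config.qc
    geom = state["geom"]
    thresholds = qcmod.QCThresholds(qcc.mi_min, qcc.max_offset_px,
                                    qcc.classifier_threshold)
    train_imgs, train_labels = synthdata.generate_qc_cohort(
        config.scene, qcc.n_clean_train, qcc.n_artifact_train,
        config.seed + 3, config.cohort.noise_sd)
    feats = [qcmod.image_features(im) for im in train_imgs]
    model = qcmod.train_error_classifier(feats, train_labels, config.seed)
    mec = geom.mec_mask()
    reference = state.get("reference_prep", state["reference"])
    mi_scores = state.get("mi_scores", {})
    rows, passed = [], []
    for rec in state["records"]:
        key = (rec.probe_id, rec.plane, rec.replicate)
        mi = mi_scores.get(key)
        if mi is None:
            mi = regmod.mutual_information(rec.ish, reference, config.register.bins)
        try:
            xc = qcmod.xcorr_offset(rec.ish, image_array(reference), mec)
        except ValueError:
            xc = (0.0, (0, 0))
        prob = float(qcmod.error_probability(
            model, qcmod.image_features(rec.expression))[0])
        rep = qcmod.qc_report(f"{rec.probe_id}:{rec.plane}:{rec.replicate}",
                              mi, xc, prob, thresholds)
        rows.append(rep)
        if rep.status == "pass":
            passed.append(rec)
    pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
        out / "qc.tsv", sep="\t", index=False)
    state["records_passed"] = passed
    report["stages"]["qc"] = {
        "n_images": len(rows),
        "n_pass": len(passed),
        "pass_rate": round(len(passed) / max(len(rows), 1), 4),
    }


def _stage_quantify(config, state, report, out) -> None:
    qc_cfg = config.quantify
    geom = state["geom"]
    groups = geom.group_masks()
    mec = geom.mec_mask()
    weights = quantmod.ScoreWeights(qc_cfg.w_rel, qc_cfg.w_prop, qc_cfg.w_mean)
    records = state.get("records_passed", state["records"])
    by_gene = {}
    for rec in records:
        if rec.plane == "C" and rec.replicate == 0:
            by_gene.setdefault(rec.gene_id, rec)
    truth_by_id = {t.gene_id: t for t in state["truths"]}
    legend = geom.legend
    neighbor_masks = {
        "parasubiculum": geom.labels == legend["parasubiculum"],
        "ventral_cortex": geom.labels == legend["ventral_cortex"],
        "subiculum": geom.labels == legend["subiculum"],
    }
    rows = []
    for gene_id, rec in sorted(by_gene.items()):
        img = rec.expression
        score = quantmod.laminar_profile(img, groups, mec)
        result = quantmod.patterning_scores(score, weights,
                                            qc_cfg.single_threshold,
                                            qc_cfg.joint_threshold)
        arr = image_array(img)
        mint_mec = float(arr[mec].mean())
        neigh = {n: float(arr[m].mean()) for n, m in neighbor_masks.items()}
        enriched = all(quantmod.regional_enrichment(mint_mec, v)[0]
                       for v in neigh.values()) if mint_mec >= 2 else False
        border = quantmod.border_candidate(neigh["parasubiculum"], mint_mec)
        truth = truth_by_id[gene_id]
        if not result.evaluated or result.candidate_class == "none":
            predicted = "none"
        elif result.candidate_class == "single":
            predicted = f"layer:{result.lmax}"
        else:
            predicted = "de"
        rows.append({
            "gene_id": gene_id, "kind": truth.kind,
            "expected_group": truth.expected_group or "",
            "eligible": score.eligible,
            "mint_mec": mint_mec,
            **{f"mean_{g}": score.layer_means.get(g, float("nan")) for g in groups},
            "ps_single": result.ps_single, "ps_joint": result.ps_joint,
            "candidate": result.candidate_class, "lmax": result.lmax,
            "predicted": predicted,
            "mec_enriched_vs_all": enriched,
            "dorsal_border_candidate": border,
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "scores.tsv", sep="\t", index=False)
    state["scores"] = df

    # truth recovery ------------------------------------------------------
    spec = df[df.kind == "layer_specific"]
    correct = spec[(spec.candidate == "single")
                   & (spec.lmax == spec.expected_group)]
    uniform = df[df.kind == "uniform"]
    de = df[df.kind.isin(["de", "island", "inter_island"])]
    sensitivity = len(correct) / len(spec) if len(spec) else float("nan")
    fpr = float((uniform.candidate != "none").mean()) if len(uniform) else float("nan")
    de_recall = float((de.candidate != "none").mean()) if len(de) else float("nan")

    expected = df.apply(
        lambda r: (f"layer:{r.expected_group}" if r.expected_group
                   else ("de" if r.kind == "de" else "none")), axis=1)
    confusion = pd.crosstab(expected, df.predicted)
    report["stages"]["quantify"] = {
        "n_genes": len(df),
        "layer_specific_sensitivity": round(sensitivity, 4),
        "uniform_false_positive_rate": round(fpr, 4),
        "de_recall": round(de_recall, 4),
        "confusion": {str(k): {str(c): int(v) for c, v in row.items()}
                      for k, row in confusion.iterrows()},
    }


def _stage_gradients(config, state, report, out) -> None:
    geom = state["geom"]
    gc = config.gradients
    dorsal_box, ventral_box = geom.dv_boxes()
    records = state.get("records_passed", state["records"])
    per_gene_plane = {}
    for rec in records:
        if rec.replicate != 0 or rec.plane not in ("C", "L1"):
            continue
        arr = image_array(rec.expression)
        per_gene_plane.setdefault(rec.gene_id, {})[rec.plane] = (
            float(arr[dorsal_box].mean()), float(arr[ventral_box].mean()))
    truth_by_id = {t.gene_id: t for t in state["truths"]}
    subregions = geom.dv_subregions(gc.n_subregions)
    groups = geom.group_masks()
    rows = []
    for gene_id, planes in sorted(per_gene_plane.items()):
        d, v = gradmod.plane_averaged_dv(planes)
        rec = gradmod.dv_classify_image(d, v, gene_id)
        truth = truth_by_id[gene_id]
        rows.append({
            "gene_id": gene_id, "mint_dorsal": d, "mint_ventral": v,
            "log2_ratio": rec.log2_ratio, "dv_class": rec.dv_class,
            "truth_g": truth.effective_dv, "expected_dv": truth.expected_dv_class,
        })
    dv = pd.DataFrame(rows).set_index("gene_id")
    fpkm_cls = gradmod.dv_classify_fpkm(state["fpkm"])
    joined = dv.join(fpkm_cls[["log2_ratio", "dv_class"]],
                     rsuffix="_fpkm", how="inner")
    both = joined[(joined.dv_class != "unexpressed")
                  & (joined.dv_class_fpkm != "unexpressed")]
    agreement = float((both.dv_class == both.dv_class_fpkm).mean()) if len(both) else float("nan")
    finite = both[np.isfinite(both.log2_ratio) & np.isfinite(both.log2_ratio_fpkm)]
    slope, r, p, n_used = gradmod.compare_aba_rnaseq(
        finite.log2_ratio, finite.log2_ratio_fpkm)
    large = dv[(dv.expected_dv.isin(["D>V", "V>D"]))
               & (dv.truth_g.abs() >= 0.585)]
    dv_recall = float((large.dv_class == large.expected_dv).mean()) if len(large) else float("nan")
    dv_accuracy = float((dv.dv_class == dv.expected_dv).mean())

    # per-layer DV slopes for one representative strong-gradient gene
    slope_example = {}
    strong = dv[dv.truth_g.abs() >= 1.0]
    if len(strong):
        gid = strong.index[0]
        rec0 = next(r for r in records
                    if r.gene_id == gid and r.plane == "C" and r.replicate == 0)
        slope_example = {k: (None if not np.isfinite(v) else round(v, 4))
                         for k, v in gradmod.dv_gradient_slopes(
                             rec0.expression, groups, subregions).items()}

    dv.to_csv(out / "dv.tsv", sep="\t")
    fpkm_cls.to_csv(out / "dv_fpkm.tsv", sep="\t")
    state["dv"] = dv
    report["stages"]["gradients"] = {
        "n_genes": len(dv),
        "counts": {k: int(v) for k, v in dv.dv_class.value_counts().items()},
        "dv_recall_large_effect": round(dv_recall, 4),
        "dv_accuracy": round(dv_accuracy, 4),
        "image_fpkm_agreement": round(agreement, 4),
        "aba_rnaseq": {"slope": round(slope, 4), "r": round(r, 4),
                       "p": float(p), "n": n_used},
        "example_layer_slopes": slope_example,
    }


def _stage_enrich(config, state, report, out) -> None:
    scores = state["scores"]
    truth_by_id = {t.gene_id: t for t in state["truths"]}
    universe = set(scores[scores.eligible].gene_id)
    if len(universe) < 5:
        report["stages"]["enrich"] = {"skipped": "universe too small"}
        return
    terms = {}
    for gid in universe:
        t = truth_by_id[gid]
        key = f"truth:{t.expected_group or t.kind}"
        terms.setdefault(key, set()).add(gid)
    sets = TermGeneSets(terms, {k: k for k in terms}, universe)
    sets.to_gmt(out / "truth_terms.gmt")
    candidates = set(scores[(scores.candidate == "single")
                            & (scores.lmax == "II")].gene_id)
    if not candidates:
        report["stages"]["enrich"] = {"skipped": "no layer II candidates"}
        return
    results = fisher_enrichment(candidates, universe, sets, "one")
    if len(sets.terms) >= 2:
        kap = kappa_matrix(sets)
        cluster_terms(results, kap)
    df = results_to_frame(results)
    df.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    top = df.sort_values(["p_adjusted", "term_id"]).iloc[0]
    report["stages"]["enrich"] = {
        "n_terms": len(df),
        "top_term": str(top.term_id),
        "top_term_p_adjusted": float(top.p_adjusted),
        "layer_ii_term_significant": bool(
            df[df.term_id == "truth:II"].p_adjusted.lt(0.05).any()),
    }


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "register": _stage_register,
    "qc": _stage_qc,
    "quantify": _stage_quantify,
    "gradients": _stage_gradients,
    "enrich": _stage_enrich,
}
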