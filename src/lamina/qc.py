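"""Registration and artifact quality control.

Three per-image metrics feed a fixed combination rule:

1. the final mutual-information score of the registration (flagged when it
   falls below a configurable floor),
2. the offset of the normalized cross-correlation peak between the
   MEC-containing region of the registered image and a larger window of the
   reference (flagged when the peak sits further than a limit from zero
   offset),
3. the error probability from a radial-basis SVM trained on multi-scale
   gradient-orientation features of clean versus artifact-laden images
   (flagged above probability 0.13).

An image fails QC iff its MI is flagged, or at least two of the remaining
measures are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import match_template
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .images import image_array

#: Classifier flag threshold on the error probability.
CLASSIFIER_FLAG_THRESHOLD = 0.13


@dataclass
class QCThresholds:
    mi_min: float = 0.15          # calibrated on synthetic cohorts
    max_offset_px: float = 5.0    # infinity-norm offset limit
    classifier: float = CLASSIFIER_FLAG_THRESHOLD


@dataclass
class QCReport:
    image_id: str
    mi_score: float
    mi_flag: bool
    xcorr_score: float
    xcorr_offset: tuple
    offset_flag: bool
    error_probability: float
    classifier_flag: bool
    status: str = "pass"


def xcorr_offset(registered, reference, roi_mask, margin: int = 20) -> tuple:
    """Normalized cross-correlation peak and its displacement from zero.

    The ROI bounding box of the registered image is matched against a window
    of the reference enlarged by ``margin`` pixels on every side.  Returns
    ``(peak score in [-1, 1], (d_row, d_col))`` where the offset is the
    displacement of the registered content relative to the reference (an
    image shifted down by 4 rows reports ``(4, 0)``).  Integer translations
    of noiseless images are recovered exactly.
    """
    reg = image_array(registered).astype(float)
    ref = image_array(reference).astype(float)
    roi = np.asarray(roi_mask, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    rows, cols = np.nonzero(roi)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    template = reg[r0:r1, c0:c1]
    if template.std() == 0:
        raise ValueError("ROI has zero variance; correlation undefined")
    R0, C0 = max(0, r0 - margin), max(0, c0 - margin)
    R1 = min(ref.shape[0], r1 + margin)
    C1 = min(ref.shape[1], c1 + margin)
    search = ref[R0:R1, C0:C1]
    ncc = match_template(search, template)
    peak = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    score = float(ncc[peak])
    nominal = (r0 - R0, c0 - C0)
    offset = (int(nominal[0] - peak[0]), int(nominal[1] - peak[1]))
    return score, offset


def image_features(image, roi_mask=None, scales: tuple = (1.0, 2.0, 4.0, 8.0),
                   grid: tuple = (4, 4), orientations: int = 8) -> np.ndarray:
    """Fixed-length multi-scale gradient-orientation spatial histogram.

    For each Gaussian scale the ROI bounding box is divided into a spatial
    grid; magnitude-weighted histograms of unsigned gradient orientation are
    accumulated per cell and L1-normalized per scale.  The feature length is
    ``len(scales) * grid[0] * grid[1] * orientations`` regardless of image
    content, and the computation is deterministic.
    """
    arr = image_array(image).astype(float)
    if roi_mask is not None:
        roi = np.asarray(roi_mask, dtype=bool)
        if not roi.any():
            raise ValueError("empty ROI")
        rows, cols = np.nonzero(roi)
        arr = arr[rows.min():rows.max() + 1, cols.min():cols.max() + 1]
    H, W = arr.shape
    gr, gc = grid
    cell_r = np.minimum((np.arange(H) * gr) // max(H, 1), gr - 1)
    cell_c = np.minimum((np.arange(W) * gc) // max(W, 1), gc - 1)
    features = []
    for sigma in scales:
        sm = gaussian_filter(arr, sigma)
        gy, gx = np.gradient(sm)
        mag = np.hypot(gy, gx)
        ang = np.mod(np.arctan2(gy, gx), np.pi)
        obin = np.minimum((ang / np.pi * orientations).astype(int),
                          orientations - 1)
        hist = np.zeros((gr, gc, orientations))
        np.add.at(hist, (cell_r[:, None].repeat(W, 1),
                         cell_c[None, :].repeat(H, 0), obin), mag)
        total = hist.sum()
        if total > 0:
            hist /= total
        features.append(hist.ravel())
    return np.concatenate(features)


def train_error_classifier(features, labels, seed: int = 0, cv_folds: int = 3):
    """Radial-basis SVM with sigmoid probability calibration.

    Hyperparameters (C, gamma) are picked by stratified cross-validation on a
    margin classifier; the winning settings are refit under a calibration
    wrapper so the model emits genuine probabilities.  Reproducible for a
    fixed seed; rejects single-class training sets.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    grid = GridSearchCV(
        SVC(kernel="rbf", random_state=seed),
        {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 0.1, 0.01]},
        cv=cv, n_jobs=1,
    )
    grid.fit(X, y)
    model = CalibratedClassifierCV(
        SVC(kernel="rbf", random_state=seed, **grid.best_params_),
        method="sigmoid", cv=cv, ensemble=False)
    model.fit(X, y)
    return model


def error_probability(model, features) -> np.ndarray:
    """Calibrated probability that each image is erroneous (class 1)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    idx = list(model.classes_).index(1)
    return model.predict_proba(X)[:, idx]


def combine_error_status(mi_flag: bool, other_flags) -> str:
    """Fail iff the MI flag is raised, or at least 2 of the other measures.

    ``other_flags`` holds the offset flag, the classifier flag and any
    additional configured flags.  Monotone: adding a flag never converts a
    fail into a pass.
    """
    others = [bool(f) for f in other_flags]
    if len(others) < 2:
        raise ValueError("need at least the offset and classifier flags")
    return "fail" if (bool(mi_flag) or sum(others) >= 2) else "pass"


def qc_report(image_id: str, mi_score: float, xcorr_result: tuple,
              probability: float,
              thresholds: QCThresholds | None = None) -> QCReport:
    """Assemble flags and the final status for one registered image."""
    thr = thresholds or QCThresholds()
    score, offset = xcorr_result
    mi_flag = mi_score < thr.mi_min
    offset_flag = max(abs(offset[0]), abs(offset[1])) > thr.max_offset_px
    cls_flag = probability > thr.classifier
    status = combine_error_status(mi_flag, [offset_flag, cls_flag])
    return QCReport(image_id, mi_score, mi_flag, score, offset, offset_flag,
                    float(probability), cls_flag, status)
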