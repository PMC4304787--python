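"""Mutual-information B-spline registration to a reference frame.

Implements the registration stack used throughout the pipeline:

* a closed-form two-point similarity (rigid + isotropic scale) alignment,
* a mutual-information (MI) estimator on the joint intensity histogram,
* free-form deformation (FFD) registration: a cubic B-spline control grid
  optimized by gradient ascent on ``MI - lambda * bending_energy`` through a
  multi-resolution pyramid, with a monotone backtracking line search (the
  accepted objective never decreases, so the final MI is never below the
  initial MI at identity, where the bending penalty is zero),
* pull-back resampling of intensity images and masks under either transform,
* reference building by iterative register-to-median, a groupwise surrogate.

MI is reported in nats.  The MI gradient with respect to the control-point
displacements is analytic: the joint histogram is built with partial-volume
(linear) weighting along the moving-intensity axis, so the derivative of MI
with respect to each warped sample value is the difference of joint/marginal
log-ratios of the two bins it straddles; chaining with the moving-image
spatial gradient and projecting onto the B-spline basis gives the control
gradient in two matrix products.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import rescale

from .images import IntensityImage, as_uint8, image_array

_EPS = 1e-12


# ---------------------------------------------------------------------------
# rigid / similarity alignment
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Similarity transform: rotation, isotropic scale and translation.

    Maps a source point ``p`` (row, col) to ``s * R(angle) @ p + t``.
    """

    angle: float
    scale: float
    translation: tuple

    def as_complex(self) -> tuple:
        a = self.scale * complex(math.cos(self.angle), math.sin(self.angle))
        t = complex(self.translation[1], self.translation[0])
        return a, t

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        a, t = self.as_complex()
        z = pts[:, 1] + 1j * pts[:, 0]
        w = a * z + t
        return np.stack([w.imag, w.real], axis=1)

    def inverse(self) -> "RigidTransform":
        a, t = self.as_complex()
        ai = 1.0 / a
        ti = -t / a
        return RigidTransform(math.atan2(ai.imag, ai.real), abs(ai),
                              (ti.imag, ti.real))


def rigid_align_two_point(image, src_points, dst_points,
                          interpolation: str = "linear") -> tuple:
    """Closed-form similarity alignment from two corresponding landmarks.

    Treating (row, col) points as complex numbers z = col + i*row, the unique
    similarity with ``a*z_src + t = z_dst`` for both pairs is
    ``a = (d2-d1)/(s2-s1)``, ``t = d1 - a*s1``.  The image is resampled onto
    the destination frame by the pull-back of the inverse map.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != (2, 2) or dst.shape != (2, 2):
        raise ValueError("expected exactly two (row, col) points per image")
    s1, s2 = src[:, 1] + 1j * src[:, 0]
    d1, d2 = dst[:, 1] + 1j * dst[:, 0]
    if s1 == s2 or d1 == d2:
        raise ValueError("landmark points must be distinct")
    a = (d2 - d1) / (s2 - s1)
    t = d1 - a * s1
    transform = RigidTransform(math.atan2(a.imag, a.real), abs(a),
                               (t.imag, t.real))
    return apply_transform(image, transform, interpolation), transform


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def mutual_information(a, b, bins: int = 64) -> float:
    """MI (nats) between two equal-shape 8-bit images from hard binning.

    Symmetric and nonnegative; ``mutual_information(x, x)`` equals the
    marginal entropy of ``x`` at the same binning.
    """
    arr_a, arr_b = image_array(a), image_array(b)
    if arr_a.shape != arr_b.shape:
        raise ValueError("images must share a shape")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    joint, _, _ = np.histogram2d(arr_a.ravel(), arr_b.ravel(), bins=bins,
                                 range=[[0, 256], [0, 256]])
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    p = joint / max(joint.sum(), _EPS)
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    denom = np.outer(pa, pb)
    return float(np.sum(p[nz] * np.log(p[nz] / np.maximum(denom[nz], _EPS))))


# ---------------------------------------------------------------------------
# B-spline free-form deformation
# ---------------------------------------------------------------------------

def _bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support |t| < 2, partition of unity."""
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1
    m2 = (at >= 1) & (at < 2)
    out[m1] = (4 - 6 * at[m1] ** 2 + 3 * at[m1] ** 3) / 6
    out[m2] = (2 - at[m2]) ** 3 / 6
    return out


class BsplineField:
    """Displacement field parameterized by a cubic B-spline control grid.

    Control points sit at ``(i - 2) * spacing`` along each axis in full-frame
    pixel coordinates; zero coefficients give the identity map.  Displacements
    are in pixels, component order (row, col).
    """

    def __init__(self, shape: tuple, spacing: float):
        if spacing < 8:
            raise ValueError("control-point spacing must be >= 8 px")
        self.shape = tuple(shape)
        self.spacing = float(spacing)
        nr = int(np.ceil((shape[0] - 1) / spacing)) + 5
        nc = int(np.ceil((shape[1] - 1) / spacing)) + 5
        self.coeff = np.zeros((2, nr, nc), dtype=float)

    def basis(self, coords: np.ndarray, n_ctrl: int) -> np.ndarray:
        """Basis matrix B with B[k, j] = B3(coords[k]/spacing - (j - 2))."""
        j = np.arange(n_ctrl, dtype=float)
        return _bspline3(coords[:, None] / self.spacing - (j[None, :] - 2.0))

    def dense_field(self, row_coords=None, col_coords=None) -> np.ndarray:
        """Evaluate the displacement on a grid (defaults to the full frame)."""
        if row_coords is None:
            row_coords = np.arange(self.shape[0], dtype=float)
        if col_coords is None:
            col_coords = np.arange(self.shape[1], dtype=float)
        Br = self.basis(np.asarray(row_coords, float), self.coeff.shape[1])
        Bc = self.basis(np.asarray(col_coords, float), self.coeff.shape[2])
        return np.stack([Br @ self.coeff[i] @ Bc.T for i in range(2)])


@dataclass
class DeformationModel:
    """Serializable B-spline deformation (reference -> moving coordinates)."""

    grid_spacing: float
    coeff: np.ndarray
    lam: float = 0.1
    metric: str = "mi"
    shape: tuple = (0, 0)

    def field(self) -> BsplineField:
        f = BsplineField(self.shape, self.grid_spacing)
        f.coeff = np.asarray(self.coeff, dtype=float)
        return f

    def dense_field(self) -> np.ndarray:
        return self.field().dense_field()

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "grid_spacing": self.grid_spacing,
            "coeff": np.asarray(self.coeff).tolist(),
            "lambda": self.lam,
            "metric": self.metric,
            "shape": list(self.shape),
        }))

    @classmethod
    def from_json(cls, path) -> "DeformationModel":
        d = json.loads(Path(path).read_text())
        return cls(d["grid_spacing"], np.asarray(d["coeff"]), d["lambda"],
                   d["metric"], tuple(d["shape"]))


@dataclass
class RegistrationConfig:
    """Optimizer settings for :func:`register_pairwise`.

    ``lam`` is the dimensionless bending-penalty weight (default 0.1, the
    value that bounds deformation scale); ``bins`` the MI histogram bins;
    ``levels`` the pyramid downsampling factors coarse-to-fine.
    """

    grid_spacing: float = 16.0
    lam: float = 0.1
    bins: int = 32
    levels: tuple = (4, 2, 1)
    iterations: tuple = (120, 80, 50)
    step_px: float = 2.0
    tol: float = 1e-5
    presmooth_sigma: float = 2.0


@dataclass
class RegistrationResult:
    model: DeformationModel
    mi_initial: float
    mi_final: float
    converged: bool
    history: list = field(default_factory=list)


def _pv_joint_hist(ref_bin: np.ndarray, mov_vals: np.ndarray, bins: int,
                   binw: float) -> np.ndarray:
    """Joint histogram, hard bins for the reference, partial-volume (linear)
    weighting along the moving axis."""
    pos = np.clip(mov_vals / binw, 0.0, bins - 1 - 1e-9)
    b0 = pos.astype(np.int64)
    w1 = pos - b0
    joint = np.zeros((bins, bins))
    np.add.at(joint, (ref_bin, b0), 1.0 - w1)
    np.add.at(joint, (ref_bin, np.minimum(b0 + 1, bins - 1)), w1)
    return joint


def _bending_energy_grad(coeff: np.ndarray, spacing: float = 16.0) -> tuple:
    """Bending energy of the control lattice and its analytic gradient.

    Sum over both components of squared second differences (d_rr^2 +
    2*d_rc^2 + d_cc^2) of the displacement in units of the grid spacing,
    averaged over control points: a discrete, dimensionless thin-plate
    energy, zero for affine control fields.  In these units lambda = 0.1
    caps the deformation scale without penalizing smooth warps of a few
    pixels.
    """
    n = coeff[0].size
    energy = 0.0
    grad = np.zeros_like(coeff)
    for i in range(2):
        c = coeff[i] / spacing
        drr = c[2:, :] - 2 * c[1:-1, :] + c[:-2, :]
        dcc = c[:, 2:] - 2 * c[:, 1:-1] + c[:, :-2]
        drc = c[1:, 1:] - c[1:, :-1] - c[:-1, 1:] + c[:-1, :-1]
        energy += (np.sum(drr ** 2) + np.sum(dcc ** 2) + 2 * np.sum(drc ** 2)) / n
        g = np.zeros_like(c)
        g[2:, :] += 2 * drr; g[1:-1, :] -= 4 * drr; g[:-2, :] += 2 * drr
        g[:, 2:] += 2 * dcc; g[:, 1:-1] -= 4 * dcc; g[:, :-2] += 2 * dcc
        g[1:, 1:] += 4 * drc; g[1:, :-1] -= 4 * drc
        g[:-1, 1:] -= 4 * drc; g[:-1, :-1] += 4 * drc
        grad[i] = g / (n * spacing)
    return energy, grad


class _LevelProblem:
    """One pyramid level: cached basis matrices, histogram, MI and gradient."""

    def __init__(self, moving: np.ndarray, reference: np.ndarray, factor: int,
                 fld: BsplineField, cfg: RegistrationConfig):
        self.factor = factor
        self.cfg = cfg
        self.fld = fld
        self.mov = moving
        self.ref = reference
        h, w = reference.shape
        self.yy, self.xx = np.mgrid[0:h, 0:w].astype(float)
        # full-frame coordinates of this level's pixel centers
        rows_full = (np.arange(h) + 0.5) * factor - 0.5
        cols_full = (np.arange(w) + 0.5) * factor - 0.5
        self.Br = fld.basis(rows_full, fld.coeff.shape[1])
        self.Bc = fld.basis(cols_full, fld.coeff.shape[2])
        self.binw = 256.0 / cfg.bins
        self.ref_bin = np.clip(reference / self.binw, 0, cfg.bins - 1).astype(np.int64).ravel()
        self.gy, self.gx = np.gradient(moving)

    def warp(self, coeff: np.ndarray) -> tuple:
        uy = (self.Br @ coeff[0] @ self.Bc.T) / self.factor
        ux = (self.Br @ coeff[1] @ self.Bc.T) / self.factor
        sy, sx = self.yy + uy, self.xx + ux
        vals = map_coordinates(self.mov, [sy, sx], order=1, cval=0.0)
        return vals, sy, sx

    def objective(self, coeff: np.ndarray) -> tuple:
        vals, _, _ = self.warp(coeff)
        joint = _pv_joint_hist(self.ref_bin, vals.ravel(), self.cfg.bins, self.binw)
        mi = _mi_from_joint(joint)
        energy, _ = _bending_energy_grad(coeff, self.fld.spacing)
        return mi - self.cfg.lam * energy, mi

    def gradient(self, coeff: np.ndarray) -> tuple:
        vals, sy, sx = self.warp(coeff)
        flat = vals.ravel()
        joint = _pv_joint_hist(self.ref_bin, flat, self.cfg.bins, self.binw)
        N = flat.size
        mi = _mi_from_joint(joint)
        na = joint.sum(axis=1, keepdims=True)
        nb = joint.sum(axis=0, keepdims=True)
        L = np.log(np.maximum(joint, 0.5)) - np.log(np.maximum(na, 0.5)) \
            - np.log(np.maximum(nb, 0.5))
        pos = np.clip(flat / self.binw, 0.0, self.cfg.bins - 1 - 1e-9)
        b0 = pos.astype(np.int64)
        b1 = np.minimum(b0 + 1, self.cfg.bins - 1)
        force = (L[self.ref_bin, b1] - L[self.ref_bin, b0]) / (N * self.binw)
        force = force.reshape(vals.shape)
        gys = map_coordinates(self.gy, [sy, sx], order=1, cval=0.0)
        gxs = map_coordinates(self.gx, [sy, sx], order=1, cval=0.0)
        scale = 1.0 / self.factor
        grad_mi = np.stack([
            self.Br.T @ (force * gys * scale) @ self.Bc,
            self.Br.T @ (force * gxs * scale) @ self.Bc,
        ])
        energy, grad_e = _bending_energy_grad(coeff, self.fld.spacing)
        return grad_mi - self.cfg.lam * grad_e, mi - self.cfg.lam * energy, mi


def register_pairwise(moving, reference,
                      config: RegistrationConfig | None = None) -> RegistrationResult:
    """Register ``moving`` onto ``reference`` with an MI-optimized B-spline.

    Both images are lightly Gaussian-smoothed before optimization (the model
    is later applied to the originals).  A single control grid, fixed in
    full-frame coordinates, is optimized coarse-to-fine; every accepted step
    increases the penalized objective, so ``mi_final >= mi_initial``.
    """
    cfg = config or RegistrationConfig()
    mov = image_array(moving).astype(float)
    ref = image_array(reference).astype(float)
    if mov.shape != ref.shape:
        raise ValueError("moving and reference must share a frame")
    if np.array_equal(mov, ref):
        # Bit-identical images: the identity is the exact optimum.
        model = DeformationModel(cfg.grid_spacing,
                                 BsplineField(ref.shape, cfg.grid_spacing).coeff,
                                 cfg.lam, "mi", ref.shape)
        mi = mutual_information(image_array(moving), image_array(reference),
                                cfg.bins)
        return RegistrationResult(model, mi, mi, True, [])
    if cfg.presmooth_sigma > 0:
        mov = gaussian_filter(mov, cfg.presmooth_sigma)
        ref = gaussian_filter(ref, cfg.presmooth_sigma)

    fld = BsplineField(ref.shape, cfg.grid_spacing)
    coeff = fld.coeff.copy()
    history = []
    mi_initial = mi_final = None
    converged = False
    for factor, iters in zip(cfg.levels, cfg.iterations):
        if factor > 1:
            mov_l = rescale(mov, 1.0 / factor, anti_aliasing=True,
                            preserve_range=True)
            ref_l = rescale(ref, 1.0 / factor, anti_aliasing=True,
                            preserve_range=True)
        else:
            mov_l, ref_l = mov, ref
        prob = _LevelProblem(mov_l, ref_l, factor, fld, cfg)
        obj, mi = prob.objective(coeff)
        if mi_initial is None:
            mi_initial = mi
        step = cfg.step_px
        fails = 0
        for _ in range(iters):
            grad, obj, mi = prob.gradient(coeff)
            if not np.isfinite(obj):
                raise FloatingPointError("registration objective is not finite")
            gmax = np.abs(grad).max()
            if gmax < _EPS:
                converged = True
                break
            accepted = False
            while step > 1e-3:
                trial = coeff + grad * (step / gmax)
                trial_obj, trial_mi = prob.objective(trial)
                if trial_obj > obj:
                    rel = abs(trial_obj - obj) / max(abs(obj), _EPS)
                    coeff, obj, mi = trial, trial_obj, trial_mi
                    accepted = True
                    step = min(step * 1.3, cfg.step_px)
                    if rel < cfg.tol:
                        converged = True
                    break
                step *= 0.5
            history.append((factor, obj, mi))
            if accepted:
                fails = 0
            else:
                # The finite-histogram gradient can misestimate near an
                # optimum; retry with a fresh trust radius before giving up.
                fails += 1
                step = cfg.step_px
                if fails >= 3:
                    converged = True
            if converged:
                break
        mi_final = mi

    model = DeformationModel(cfg.grid_spacing, coeff, cfg.lam, "mi", ref.shape)
    # Report MI on the unsmoothed full-resolution images for the QC stage.
    mi0 = mutual_information(image_array(moving), image_array(reference), cfg.bins)
    warped = apply_transform(moving, model)
    mi1 = mutual_information(warped, image_array(reference), cfg.bins)
    return RegistrationResult(model, float(mi_initial), float(mi_final),
                              converged, history + [("full", mi0, mi1)])


def apply_transform(image, model, interpolation: str = "linear") -> IntensityImage:
    """Pull-back resampling: each reference pixel samples the moving image.

    ``interpolation`` is "linear" for intensities or "nearest" for label
    masks; samples outside the moving frame are filled with 0 (background),
    never wrapped.
    """
    arr = image_array(image).astype(float)
    order = 0 if interpolation == "nearest" else 1
    if isinstance(model, RigidTransform):
        H, W = arr.shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        a, t = model.inverse().as_complex()
        z = (xx + 1j * yy)
        w = a * z + t
        sy, sx = w.imag, w.real
    elif isinstance(model, DeformationModel):
        d = model.dense_field()
        H, W = model.shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        sy, sx = yy + d[0], xx + d[1]
    else:
        raise TypeError("model must be a RigidTransform or DeformationModel")
    out = map_coordinates(arr, [sy, sx], order=order, cval=0.0)
    meta = dict(image.meta) if isinstance(image, IntensityImage) else {}
    meta["registered"] = True
    return IntensityImage(as_uint8(out), meta)


# ---------------------------------------------------------------------------
# reference building
# ---------------------------------------------------------------------------

def build_reference(images, landmark_pairs=None, rounds: int = 2,
                    config: RegistrationConfig | None = None) -> tuple:
    """Groupwise surrogate: rigid-align, then iterate register-to-median.

    ``landmark_pairs`` is an optional list of (src_points, dst_points) per
    image for the initial two-point alignment; omitted entries (or ``None``)
    skip the rigid step.  At least 3 images and 2 refinement rounds are
    required; the final pixelwise median is returned together with the last
    round's deformation models.
    """
    if len(images) < 3:
        raise ValueError("reference building needs at least 3 images")
    if rounds < 2:
        raise ValueError("at least 2 register-to-median rounds required")
    cfg = config or RegistrationConfig()
    aligned = []
    for i, img in enumerate(images):
        pair = landmark_pairs[i] if landmark_pairs else None
        if pair is not None:
            out, _ = rigid_align_two_point(img, pair[0], pair[1])
            aligned.append(image_array(out).astype(float))
        else:
            aligned.append(image_array(img).astype(float))
    median = np.median(np.stack(aligned), axis=0)
    models = []
    for _ in range(rounds):
        models = []
        warped = []
        for arr in aligned:
            res = register_pairwise(as_uint8(arr), as_uint8(median), cfg)
            models.append(res.model)
            warped.append(image_array(apply_transform(as_uint8(arr), res.model)).astype(float))
        median = np.median(np.stack(warped), axis=0)
    return IntensityImage(as_uint8(median), {"role": "reference"}), models
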