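"""Image-quality metrics on maximum intensity projections and volumes.

Five metrics, as used to score reconstructions against the reference
standard:

* NMSE and PSNR — simple pixelwise error measures on the craniocaudal MIPs;
* SSIM — mean of local structural similarity over 8x8 sliding windows;
* forced-keypoint SIFT distance — descriptors computed on the reconstructed
  MIP at the reference MIP's key locations, mean Euclidean distance;
* artery-to-parenchyma CNR — computed on the full 3D volumes, with the noise
  estimated as the SD of (reference - reconstruction) over parenchyma.

Mask restriction: the 3D brain mask is applied to the *volume* before
projecting (so out-of-mask structures along the ray are removed), and the
images are normalized so the relevant reference MIP has maximum 1 before any
metric is computed (hence PSNR MAX = 1 and the SSIM dynamic range is 1).
With this convention, altering voxels outside the brain mask changes the
masked metrics by exactly zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InvalidArgumentError, NoKeypointsError
from .phantom import AXIS_LABELS, MaskSet, Volume
from .sift import compute_descriptors, detect_keypoints
from .sift import sift_forced_distance as _sift_forced_distance


@dataclass
class MIPImage:
    """A maximum intensity projection of a (possibly masked) volume."""

    data: np.ndarray
    axis_projected: str = "craniocaudal"
    masked: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise InvalidArgumentError("MIP must be 2D")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SSIMConfig:
    """SSIM window and stabilization constants; c1 = (0.01 L)^2, c2 = (0.03 L)^2."""

    window: int = 8
    dynamic_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03

    def __post_init__(self):
        if self.window < 2:
            raise InvalidArgumentError("window must be >= 2")
        if self.dynamic_range <= 0:
            raise InvalidArgumentError("dynamic_range must be > 0")

    @property
    def c1(self):
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self):
        return (self.k2 * self.dynamic_range) ** 2


def _asvol(v) -> np.ndarray:
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    return np.abs(data) if np.iscomplexobj(data) else data


def _asimg(m) -> np.ndarray:
    return m.data if isinstance(m, MIPImage) else np.asarray(m)


def mip(vol, mask: np.ndarray | None = None, axis: str = "craniocaudal") -> MIPImage:
    """Maximum intensity projection; out-of-mask voxels are zeroed first."""
    data = _asvol(vol)
    if axis not in AXIS_LABELS:
        raise InvalidArgumentError(
            f"unknown axis label {axis!r}; one of {sorted(AXIS_LABELS)}"
        )
    ax = AXIS_LABELS[axis]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape:
            raise InvalidArgumentError("mask shape must match volume shape")
        data = np.where(mask, data, 0.0)
    return MIPImage(data.max(axis=ax), axis_projected=axis, masked=mask is not None)


def mse(ref, rec) -> float:
    x = _asimg(ref)
    y = _asimg(rec)
    if x.shape != y.shape:
        raise InvalidArgumentError("images must have the same shape")
    return float(np.mean((x - y) ** 2))


def nmse(ref, rec) -> float:
    """MSE(ref, rec) / MSE(ref, 0)."""
    x = _asimg(ref)
    denom = float(np.mean(x**2))
    if denom == 0:
        raise ZeroDivisionError("reference image is all zero; NMSE undefined")
    return mse(ref, rec) / denom


def psnr(ref, rec, max_value: float = 1.0) -> float:
    """10 log10(MAX^2 / MSE) in dB; identical images give math.inf."""
    m = mse(ref, rec)
    if m == 0:
        return math.inf
    return 10.0 * math.log10(max_value**2 / m)


def _window_stats(img, w):
    v = sliding_window_view(img, (w, w))
    return v.mean(axis=(-2, -1)), v


def ssim(ref, rec, cfg: SSIMConfig | None = None) -> float:
    """Mean local SSIM over all valid sliding windows (uniform, stride 1).

    Population (ddof 0) variances and covariance per window.
    """
    if cfg is None:
        cfg = SSIMConfig()
    x = np.asarray(_asimg(ref), dtype=float)
    y = np.asarray(_asimg(rec), dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("images must have the same shape")
    w = cfg.window
    if min(x.shape) < w:
        raise InvalidArgumentError(f"image smaller than the {w}x{w} window")
    mux, vx = _window_stats(x, w)
    muy, vy = _window_stats(y, w)
    sxx = (vx**2).mean(axis=(-2, -1)) - mux**2
    syy = (vy**2).mean(axis=(-2, -1)) - muy**2
    sxy = (vx * vy).mean(axis=(-2, -1)) - mux * muy
    c1, c2 = cfg.c1, cfg.c2
    num = (2 * mux * muy + c1) * (2 * sxy + c2)
    den = (mux**2 + muy**2 + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


def sift_forced_distance(ref, rec):
    """Forced-correspondence SIFT distance between two MIPs (see csmra.sift)."""
    return _sift_forced_distance(_asimg(ref), _asimg(rec))


def cnr_artery_parenchyma(rec, ref, masks: MaskSet) -> float:
    """(S_artery - S_parenchyma) / SD_parenchyma over the full 3D volumes.

    The noise SD is taken from the subtraction image (reference minus
    reconstruction) over the parenchymal mask (population SD).  Identical
    images give an infinite sentinel with a warning.
    """
    r = _asvol(rec)
    g = _asvol(ref)
    if r.shape != g.shape or r.shape != masks.arterial.shape:
        raise InvalidArgumentError("volume and mask shapes must conform")
    s_art = float(r[masks.arterial].mean())
    s_par = float(r[masks.parenchymal].mean())
    sd = float((g - r)[masks.parenchymal].std(ddof=0))
    if sd == 0:
        warnings.warn("zero parenchymal noise SD; CNR is infinite", RuntimeWarning)
        return math.inf
    return (s_art - s_par) / sd


def slice_nmse(ref, rec, axis: str = "craniocaudal") -> float:
    """Mean over (non-empty reference) slices of the per-slice 2D NMSE."""
    x = _asvol(ref)
    y = _asvol(rec)
    if x.shape != y.shape:
        raise InvalidArgumentError("volumes must have the same shape")
    ax = AXIS_LABELS[axis]
    x = np.moveaxis(x, ax, 0)
    y = np.moveaxis(y, ax, 0)
    vals = []
    for xs, ys in zip(x, y):
        denom = float(np.mean(xs**2))
        if denom == 0:
            continue
        vals.append(float(np.mean((xs - ys) ** 2)) / denom)
    if not vals:
        raise ZeroDivisionError("all reference slices are zero; slice NMSE undefined")
    return float(np.mean(vals))


#: metric key -> ranking direction used throughout the sweep reports
METRIC_DIRECTIONS = {
    "nmse": "lower_better",
    "psnr_db": "higher_better",
    "ssim": "higher_better",
    "nmse_masked": "lower_better",
    "psnr_masked": "higher_better",
    "ssim_masked": "higher_better",
    "sift_dist_masked": "lower_better",
    "cnr": "higher_better",
    "slice_nmse_mean": "lower_better",
}


def evaluate_all(
    ref,
    rec,
    masks: MaskSet,
    ssim_cfg: SSIMConfig | None = None,
    ref_keypoints=None,
) -> dict:
    """All metric values for one reconstruction against the reference.

    ``ref`` and ``rec`` are 3D volumes (complex reconstructions are reduced
    to magnitude).  Unmasked NMSE/PSNR/SSIM use the whole craniocaudal MIP
    normalized so the reference MIP max is 1; masked variants apply the
    brain mask to the volumes before projection and renormalize by the
    masked reference MIP max.  ``ref_keypoints`` may carry pre-detected
    keypoints of the masked, normalized reference MIP (as produced by
    :func:`csmra.sift.detect_keypoints`) to avoid re-detection in sweeps.
    """
    g = _asvol(ref)
    r = _asvol(rec)

    out = {}
    mip_ref = mip(g).data
    mip_rec = mip(r).data
    scale = float(mip_ref.max())
    if scale == 0:
        raise InvalidArgumentError("reference volume is all zero")
    mref = mip_ref / scale
    mrec = mip_rec / scale
    cfg = ssim_cfg or SSIMConfig()
    out["nmse"] = nmse(mref, mrec)
    out["psnr_db"] = psnr(mref, mrec, max_value=cfg.dynamic_range)
    out["ssim"] = ssim(mref, mrec, cfg)

    bmip_ref = mip(g, mask=masks.brain).data
    bmip_rec = mip(r, mask=masks.brain).data
    bscale = float(bmip_ref.max())
    bref = bmip_ref / bscale
    brec = bmip_rec / bscale
    out["nmse_masked"] = nmse(bref, brec)
    out["psnr_masked"] = psnr(bref, brec, max_value=cfg.dynamic_range)
    out["ssim_masked"] = ssim(bref, brec, cfg)
    if ref_keypoints is None:
        ref_keypoints = detect_keypoints(bref)
    if len(ref_keypoints) == 0:
        raise NoKeypointsError("no keypoints on the masked reference MIP")
    d_ref = compute_descriptors(bref, ref_keypoints)
    d_rec = compute_descriptors(brec, ref_keypoints)
    out["sift_dist_masked"] = float(np.mean(np.linalg.norm(d_ref - d_rec, axis=1)))

    out["cnr"] = cnr_artery_parenchyma(r / scale, g / scale, masks)
    out["slice_nmse_mean"] = slice_nmse(g, r)
    return out
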