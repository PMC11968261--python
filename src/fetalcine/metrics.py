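"""Quantitative image-quality metrics: SNR, contrast, CNR, PIQE, NRMSD.

SNR follows the ROI convention of clinical cardiac MR reading: mean blood-pool
signal divided by the standard deviation measured in a noise ROI near the
edge of the field of view (no Rayleigh correction).  Contrast is the
blood/myocardium signal ratio — a scale-free quantity dominated by the
densely sampled low spatial frequencies.  PIQE is a no-reference,
block-based perceptual quality score in [0, 100] (lower is better) built on
mean-subtracted contrast-normalized (MSCN) coefficients.  NRMSD is the
L2 difference between a reconstruction and a reference, normalized by the
reference norm over an anatomy mask, in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import Roi

__all__ = [
    "QualityReport",
    "roi_quality",
    "pique_score",
    "nrmsd",
]


@dataclass
class QualityReport:
    snr: float
    contrast: float
    cnr: float
    pique: float
    nrmsd_pct: float | None = None
    rois: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"snr": self.snr, "contrast": self.contrast, "cnr": self.cnr,
             "pique": self.pique}
        if self.nrmsd_pct is not None:
            d["nrmsd_pct"] = self.nrmsd_pct
        return d


def _roi_values(image: np.ndarray, roi) -> np.ndarray:
    if isinstance(roi, Roi):
        return roi.extract(image).ravel()
    mask = np.asarray(roi, dtype=bool)
    return image[mask]


def roi_quality(image: np.ndarray, roi_noise, roi_blood,
                roi_myo) -> tuple[float, float, float]:
    """(snr, contrast, cnr) from three ROIs on a magnitude image.

    snr = mean(blood)/sd(noise); contrast = mean(blood)/mean(myo);
    cnr = (mean(blood) - mean(myo))/sd(noise).
    """
    image = np.abs(np.asarray(image))
    noise = _roi_values(image, roi_noise)
    blood = _roi_values(image, roi_blood)
    myo = _roi_values(image, roi_myo)
    if noise.size == 0 or blood.size == 0 or myo.size == 0:
        raise ValueError("all three ROIs must be nonempty")
    sd = float(noise.std(ddof=1))
    if sd == 0:
        raise ValueError("noise ROI has zero standard deviation "
                         "(noiseless input)")
    mb, mm = float(blood.mean()), float(myo.mean())
    return mb / sd, mb / mm, (mb - mm) / sd


# ---------------------------------------------------------------------------
# PIQE: perception-based no-reference quality
# ---------------------------------------------------------------------------

_PIQE_BLOCK = 16
_PIQE_ACTIVITY_THR = 0.1
_PIQE_SEG_THR = 0.1     # near-uniform edge segment => blur/blockiness
_PIQE_NOISE_STD = 0.5   # uniformly high MSCN variance => noise
_PIQE_NOISE_CV = 0.15
_PIQE_BLUR_WEIGHT = 0.3  # blur is penalized more mildly than noise


def _mscn(image: np.ndarray) -> np.ndarray:
    mu = gaussian_filter(image, sigma=7 / 6, truncate=3.0)
    sigma = np.sqrt(np.clip(gaussian_filter(image * image, sigma=7 / 6,
                                            truncate=3.0) - mu * mu, 0, None))
    return (image - mu) / (sigma + 1.0)


def pique_score(image: np.ndarray) -> float:
    """Block-based no-reference perceptual quality score in [0, 100].

    The magnitude image is rescaled to [0, 255] and transformed to MSCN
    coefficients; 16x16 blocks with MSCN variance above 0.1 count as
    spatially active.  An active block is distorted when it shows a
    noticeable artifact (some 6-pixel segment along its edges is nearly
    uniform — blockiness/blur) or noise (uniformly high MSCN variance across
    its quadrants).  The score pools the distorted fraction of active blocks,
    scaled to [0, 100]; lower is better.  A constant image (no active
    blocks) scores 100 with a warning.
    """
    img = np.abs(np.asarray(image, dtype=float))
    if img.ndim != 2 or min(img.shape) < 64:
        raise ValueError("image must be 2-D with min side >= 64")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        warnings.warn("constant image: no active blocks, score = 100",
                      stacklevel=2)
        return 100.0
    img = (img - lo) / (hi - lo) * 255.0
    m = _mscn(img)
    b = _PIQE_BLOCK
    nr, nc = img.shape[0] // b, img.shape[1] // b
    n_active = 0
    dist_sum = 0.0
    for i in range(nr):
        for j in range(nc):
            blk = m[i * b:(i + 1) * b, j * b:(j + 1) * b]
            if blk.var() < _PIQE_ACTIVITY_THR:
                continue
            n_active += 1
            h = b // 2
            quads = [blk[:h, :h], blk[:h, h:], blk[h:, :h], blk[h:, h:]]
            qs = np.array([q.std() for q in quads])
            noisy = (qs.mean() > _PIQE_NOISE_STD
                     and qs.std() / max(qs.mean(), 1e-12) < _PIQE_NOISE_CV)
            if noisy:
                dist_sum += min(1.0, float(qs.mean()))
                continue
            edges = [blk[0, :], blk[-1, :], blk[:, 0], blk[:, -1]]
            seg_min = min(seg[k:k + 6].std()
                          for seg in edges for k in (0, 5, 10))
            if seg_min < _PIQE_SEG_THR:   # graded blur/blockiness distortion
                dist_sum += _PIQE_BLUR_WEIGHT * (1.0 - seg_min / _PIQE_SEG_THR)
    if n_active == 0:
        warnings.warn("no spatially active blocks, score = 100", stacklevel=2)
        return 100.0
    return float(np.clip(100.0 * (dist_sum + 1.0) / (n_active + 1.0),
                         0.0, 100.0))


def nrmsd(test: np.ndarray, reference: np.ndarray, mask: np.ndarray) -> float:
    """Normalized root-mean-squared difference in percent over a mask.

    100 * ||test - reference||_2 / ||reference||_2 over masked pixels of all
    phases/frames, computed on magnitude images.
    """
    test = np.abs(np.asarray(test))
    reference = np.abs(np.asarray(reference))
    if test.shape != reference.shape:
        raise ValueError("test and reference must have the same shape")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != test.shape[-2:]:
        raise ValueError("mask must match the image grid")
    if not mask.any():
        raise ValueError("mask is empty")
    t = test[..., mask]
    r = reference[..., mask]
    denom = np.linalg.norm(r)
    if denom == 0:
        raise ValueError("reference has zero energy inside the mask")
    return 100.0 * float(np.linalg.norm(t - r) / denom)
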