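"""Imaging quantification on two-channel intensity matrices.

Three standard fluorescence-microscopy metrics: Manders' M1 overlap
coefficient (thresholded co-localization), corrected total cell fluorescence
(integrated ROI density minus area × mean background), and intensity
correlation analysis (sum of centered cross-channel intensity products per
ROI), plus percent-of-control normalization for group comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np


def _check_pair(a: np.ndarray, b: np.ndarray):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("intensities must be finite")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("intensities must be nonnegative")
    return a, b


def otsu_threshold(image) -> float:
    """Otsu's automatic threshold (maximal between-class variance)."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(image, dtype=float)))


def manders_m1(a, b, threshold_a: float = 0.0, threshold_b: float = 0.0) -> float:
    """M1 = Σ A_i over pixels above both thresholds / Σ A_i above threshold_a.

    0 means no overlap of channel-A intensity with channel-B signal; 1 means
    complete co-localization.
    """
    a, b = _check_pair(a, b)
    if threshold_a < 0 or threshold_b < 0:
        raise ValueError("thresholds must be nonnegative")
    in_a = a > threshold_a
    denom = a[in_a].sum()
    if denom == 0:
        raise ValueError("no channel-A intensity above threshold; M1 undefined")
    num = a[in_a & (b > threshold_b)].sum()
    return float(num / denom)


def ctcf(image, roi_mask, background_rois) -> float:
    """Corrected total cell fluorescence:
    integrated ROI density − ROI area × mean of background-ROI means."""
    img = np.asarray(image, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != img.shape:
        raise ValueError("ROI shape differs from image")
    area = int(roi.sum())
    if area == 0:
        raise ValueError("empty ROI")
    if not background_rois:
        raise ValueError("at least one background ROI required")
    bg_means = []
    for bg in background_rois:
        bg = np.asarray(bg, dtype=bool)
        if bg.shape != img.shape:
            raise ValueError("background ROI shape differs from image")
        if bg.sum() == 0:
            raise ValueError("empty background ROI")
        bg_means.append(img[bg].mean())
    integrated = img[roi].sum()
    return float(integrated - area * np.mean(bg_means))


def ica_score(a, b, roi_mask=None) -> float:
    """Intensity correlation analysis over an ROI:
    Σ (A_i − mean A)·(B_i − mean B), means taken over the ROI."""
    a, b = _check_pair(a, b)
    if roi_mask is None:
        roi = np.ones(a.shape, dtype=bool)
    else:
        roi = np.asarray(roi_mask, dtype=bool)
        if roi.shape != a.shape:
            raise ValueError("ROI shape differs from image")
    if roi.sum() == 0:
        raise ValueError("empty ROI")
    av, bv = a[roi], b[roi]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        warnings.warn("constant channel within ROI; ICA score is 0")
        return 0.0
    return float(((av - av.mean()) * (bv - bv.mean())).sum())


def ica_percentage(roi_scores) -> float:
    """Share of ROIs with positive intensity-correlation score, in percent."""
    s = np.asarray(list(roi_scores), dtype=float)
    if len(s) == 0:
        raise ValueError("no ROI scores given")
    return float(100.0 * (s > 0).mean())


def normalize_to_control(group_values, control_values) -> np.ndarray:
    """Express values as percent of the control-group mean."""
    g = np.asarray(group_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(c) == 0 or c.mean() <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * g / c.mean()
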