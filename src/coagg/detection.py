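"""Single-channel particle detection.

The assay images show sparse, roughly circular, diffraction-limited bright
particles (each one an aggregate) on a noisy camera background.  Detection
runs two complementary operators on the histogram-equalized image — a
contour (thresholded connected-component) detector and a Hough circle
detector — and merges their outputs with distance-based non-maximum
suppression.  The contour branch is robust for compact and irregular bright
particles; the Hough branch votes on gradient (edge) evidence and catches
ring-like or low-contrast circular structures.

Because the foreground occupies well under 1% of pixels, a plain Otsu
threshold on the raw or equalized image would split the background mode;
the contour branch therefore band-passes the equalized image with a matched
Gaussian filter first, and enforces a robust noise floor (median + k*MAD)
under the Otsu threshold so that blank fields yield zero detections.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure, feature, measure, transform

from .types import DetectConfig, DualChannelField, ParameterError, Spot

__all__ = [
    "enhance",
    "detect_spots_contour",
    "detect_spots_hough",
    "detect_spots",
    "detect_field",
]


# ---------------------------------------------------------------------------
# Enhancement
# ---------------------------------------------------------------------------

def enhance(image: np.ndarray, method: str = "global") -> np.ndarray:
    """Histogram-equalize a single-channel image to 8 bits.

    Global equalization maps each input level v to round(255 * CDF(v)) over
    the image's empirical distribution, so the output depends only on the
    rank order of input levels (any strictly increasing relabeling of the
    input gives the same output).  ``method='clahe'`` uses contrast-limited
    adaptive equalization instead.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if np.any(img < 0):
        raise ValueError("image must be nonnegative")
    if method == "clahe":
        out = exposure.equalize_adapthist(img.astype(np.float64) / max(img.max(), 1))
        return np.rint(out * 255).astype(np.uint8)
    if method != "global":
        raise ParameterError(f"equalization: unknown method {method!r}")
    levels, inv, counts = np.unique(img, return_inverse=True, return_counts=True)
    cdf = np.cumsum(counts) / img.size
    mapped = np.rint(255.0 * cdf).astype(np.uint8)
    return mapped[inv].reshape(img.shape)


# ---------------------------------------------------------------------------
# Contour (connected-component) detector
# ---------------------------------------------------------------------------

def _bandpass(image: np.ndarray, sigma: float) -> np.ndarray:
    """Matched Gaussian filter minus a coarse local background (difference
    of Gaussians); output has zero-mean background with spots positive."""
    img = image.astype(np.float64)
    fine = ndimage.gaussian_filter(img, sigma)
    coarse = ndimage.gaussian_filter(img, 4.0 * sigma)
    return fine - coarse


def _circularity(region) -> float:
    per = region.perimeter
    if per <= 0:  # single-pixel or degenerate region: treat as circular
        return 1.0
    return float(4.0 * np.pi * region.area / per ** 2)


def detect_spots_contour(image: np.ndarray, cfg: DetectConfig | None = None,
                         intensity_image: np.ndarray | None = None,
                         channel: str = "") -> list[Spot]:
    """Detect bright particles by threshold + connected components.

    The (enhanced) image is band-passed with a matched filter of width
    ``smooth_sigma_px``; the threshold is Otsu's on the band-passed image
    (or ``fixed_threshold``), floored at median + ``noise_floor_k`` * MAD so
    pure-noise fields produce no components.  Components are kept when their
    area lies in [min_area_px, max_area_px] and circularity 4*pi*A/P^2 is at
    least ``min_circularity``; centers are intensity-weighted sub-pixel
    centroids, radius = sqrt(A/pi).  Output is sorted by (y, x).
    """
    cfg = cfg or DetectConfig()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    bp = _bandpass(img, cfg.smooth_sigma_px)
    if cfg.threshold_method == "fixed":
        thr = float(cfg.fixed_threshold)
    else:
        med = np.median(bp)
        mad = np.median(np.abs(bp - med))
        floor = med + cfg.noise_floor_k * 1.4826 * mad
        if bp.max() <= bp.min() + 1e-12:
            return []
        from skimage.filters import threshold_otsu
        thr = max(float(threshold_otsu(bp)), floor)
    mask = bp > thr
    labels = measure.label(mask, connectivity=2)
    weights = bp - thr  # positive inside mask; used for sub-pixel centroids
    meas = intensity_image if intensity_image is not None else img
    spots = []
    for region in measure.regionprops(labels):
        if not (cfg.min_area_px <= region.area <= cfg.max_area_px):
            continue
        if _circularity(region) < cfg.min_circularity:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        wts = np.maximum(weights[rr, cc], 1e-12)
        cy = float(np.sum(rr * wts) / np.sum(wts))
        cx = float(np.sum(cc * wts) / np.sum(wts))
        spots.append(Spot(
            x_px=cx, y_px=cy,
            radius_px=float(np.sqrt(region.area / np.pi)),
            mean_intensity=float(np.mean(meas[rr, cc])),
            method="contour", channel=channel))
    spots.sort(key=lambda s: (s.y_px, s.x_px))
    return spots


# ---------------------------------------------------------------------------
# Hough circle detector
# ---------------------------------------------------------------------------

def detect_spots_hough(image: np.ndarray, cfg: DetectConfig | None = None,
                       intensity_image: np.ndarray | None = None,
                       channel: str = "") -> list[Spot]:
    """Detect circular particles by gradient-based Hough accumulator voting.

    Canny edges of the (enhanced) image vote in circle space over radii
    [hough_r_min_px, hough_r_max_px]; circumference-normalized accumulator
    peaks above ``hough_vote_threshold`` are returned.  Deterministic given
    input and config.
    """
    cfg = cfg or DetectConfig()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if cfg.hough_r_max_px >= min(img.shape) / 2:
        raise ParameterError("hough_r_max_px: must be < min(image dims)/2")
    # edge detection on the band-passed image with robust noise-scaled
    # hysteresis thresholds: equalization gives background noise full
    # contrast, so fixed/quantile canny thresholds would fire everywhere
    bp = _bandpass(img, cfg.smooth_sigma_px)
    sm = ndimage.gaussian_filter(bp, 1.0)
    gmag = np.hypot(ndimage.sobel(sm, axis=0), ndimage.sobel(sm, axis=1))
    # Sobel magnitude matches canny's internal gradient; for pure noise it is
    # Rayleigh-distributed with median = sigma * sqrt(2 ln 2)
    gsd = np.median(gmag) / 1.1774
    if gsd <= 0:
        return []
    edges = feature.canny(bp, sigma=1.0, low_threshold=3.0 * gsd,
                          high_threshold=5.0 * gsd)
    if not edges.any():
        return []
    radii = np.arange(cfg.hough_r_min_px, cfg.hough_r_max_px + 1)
    accum = transform.hough_circle(edges, radii, normalize=True)
    min_d = max(int(np.ceil(cfg.merge_dist_px)), 1)
    acc, cx, cy, rad = transform.hough_circle_peaks(
        accum, radii, min_xdistance=min_d, min_ydistance=min_d,
        threshold=cfg.hough_vote_threshold)
    meas = intensity_image if intensity_image is not None else img
    h, w = img.shape
    spots = []
    for a, x, y, r in zip(acc, cx, cy, rad):
        x = float(np.clip(x, 0, w - 1))
        y = float(np.clip(y, 0, h - 1))
        y0, y1 = max(int(y - r), 0), min(int(y + r) + 1, h)
        x0, x1 = max(int(x - r), 0), min(int(x + r) + 1, w)
        spots.append(Spot(x_px=x, y_px=y, radius_px=float(r),
                          mean_intensity=float(np.mean(meas[y0:y1, x0:x1])),
                          method="hough", channel=channel))
    spots.sort(key=lambda s: (s.y_px, s.x_px))
    return spots


# ---------------------------------------------------------------------------
# Combined detector
# ---------------------------------------------------------------------------

def detect_spots(image: np.ndarray, cfg: DetectConfig | None = None,
                 channel: str = "") -> list[Spot]:
    """Full single-channel detection: enhance, run both operators, merge.

    The union of contour and Hough detections is deduplicated by greedy
    distance non-maximum suppression at ``merge_dist_px``: contour-derived
    geometry is kept when both operators agree (method becomes ``merged``),
    and no two returned spots lie closer than ``merge_dist_px``.
    """
    cfg = cfg or DetectConfig()
    raw = np.asarray(image, dtype=np.float64)
    enh = enhance(raw, cfg.equalization)
    contour = detect_spots_contour(enh, cfg, intensity_image=raw, channel=channel)
    hough = detect_spots_hough(enh, cfg, intensity_image=raw, channel=channel)

    kept: list[Spot] = []
    for s in contour:  # contour first: its sub-pixel geometry is preferred
        if all((s.x_px - k.x_px) ** 2 + (s.y_px - k.y_px) ** 2
               >= cfg.merge_dist_px ** 2 for k in kept):
            kept.append(s)
    # a Hough detection near a contour spot is the same particle re-found
    # (ring fits land a few px off the centroid), so hough-only candidates
    # are admitted only when no contour evidence lies within 2*merge_dist
    gate2 = (2.0 * cfg.merge_dist_px) ** 2
    for s in hough:
        d2 = [(s.x_px - k.x_px) ** 2 + (s.y_px - k.y_px) ** 2 for k in kept]
        if d2 and min(d2) < gate2:
            k = kept[int(np.argmin(d2))]
            if min(d2) < cfg.merge_dist_px ** 2 and k.method == "contour":
                k.method = "merged"
            continue
        kept.append(s)
    kept.sort(key=lambda s: (s.y_px, s.x_px))
    return kept


def detect_field(fld: DualChannelField, cfg: DetectConfig | None = None,
                 ) -> tuple[list[Spot], list[Spot]]:
    """Detect spots independently in both channels of a field (exposures
    differ per channel, so no cross-channel intensity use is ever made)."""
    red = detect_spots(fld.red_image, cfg, channel="red")
    blue = detect_spots(fld.blue_image, cfg, channel="blue")
    return red, blue
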