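"""Count putative Semper (cone) cells inside ommatidium ROIs.

Under combined UV and white illumination the candidate cone-cell units
appear as grouped bright yellow-green components inside individual
ommatidia.  The procedure masks the pixels of an ROI whose hue and
saturation fall in a configured chromatic window and whose value (HSV
brightness) exceeds a high quantile of the in-window values, then counts
connected components above a minimum area.  In crown pancrustaceans the
canonical arrangement is a quartet; counts above four (or units touching
the ROI boundary) are flagged ambiguous rather than interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = ["ChromaWindow", "ConeCount", "chroma_peak_mask", "count_units"]


@dataclass(frozen=True)
class ChromaWindow:
    """Chromatic gate for peak isolation.

    Hue bounds are degrees in [0, 360) and may wrap around zero; the
    default band (70-150 degrees) covers the yellow-green fluorescence of
    the iridescent units.  ``q`` is the in-window value quantile a pixel
    must strictly exceed to count as a peak.
    """

    hue_lo: float = 70.0
    hue_hi: float = 150.0
    min_saturation: float = 0.3
    q: float = 0.95
    #: sigma (px) of the light Gaussian smoothing applied to the value
    #: channel before the quantile, so "peaks" are local intensity maxima
    #: rather than single noisy pixels; 0 disables
    value_smooth: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.q < 1.0:
            raise ValueError("q must be in [0, 1)")
        for hbound in (self.hue_lo, self.hue_hi):
            if not 0.0 <= hbound < 360.0:
                raise ValueError("hue bounds must be in [0, 360)")

    def hue_mask(self, hue_deg: np.ndarray) -> np.ndarray:
        if self.hue_lo <= self.hue_hi:
            return (hue_deg >= self.hue_lo) & (hue_deg <= self.hue_hi)
        return (hue_deg >= self.hue_lo) | (hue_deg <= self.hue_hi)  # wrap


@dataclass(frozen=True)
class ConeCount:
    """Counted candidate units in one ommatidium ROI."""

    roi_id: str
    n_units: int
    centroids: np.ndarray  # (n, 2) as (x, y)
    areas: np.ndarray
    ambiguous: bool


def _roi_mask(shape: tuple[int, int], roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi, float).reshape(-1, 2)
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(roi[:, 1], roi[:, 0], shape=shape)
    m[rr, cc] = True
    return m


def chroma_peak_mask(
    color_image: np.ndarray,
    roi: np.ndarray,
    window: ChromaWindow = ChromaWindow(),
) -> np.ndarray:
    """Mask of in-ROI pixels inside the chromatic window above its q-quantile.

    The quantile is computed over the in-ROI, in-window values only, and
    the comparison is strict, so at q -> 1 the mask empties rather than
    keeping the maximum.  An empty mask is a valid result.
    """
    img = np.asarray(color_image, float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image with 3 channels")
    roi_m = _roi_mask(img.shape[:2], roi)
    if roi_m.sum() < 10:
        raise ValueError("ROI smaller than 10 px rejected")
    hsv = rgb2hsv(img)
    hue = hsv[..., 0] * 360.0
    in_window = (
        roi_m & window.hue_mask(hue) & (hsv[..., 1] >= window.min_saturation)
    )
    if not in_window.any():
        return in_window
    values = hsv[..., 2]
    if window.value_smooth > 0:
        from scipy.ndimage import gaussian_filter

        values = gaussian_filter(values, window.value_smooth)
    cutoff = np.quantile(values[in_window], window.q)
    if window.q == 0.0:  # keep the whole in-window set, not all-but-minimum
        return in_window & (values >= cutoff)
    return in_window & (values > cutoff)


def count_units(
    mask: np.ndarray,
    roi: np.ndarray,
    min_area_px: int = 3,
    roi_id: str = "roi",
) -> ConeCount:
    """Connected components (8-connectivity) of the peak mask above min area.

    Flags the count ambiguous when it exceeds four (more units than the
    canonical quartet) or when any unit touches the ROI boundary.
    """
    mask = np.asarray(mask, bool)
    roi_m = _roi_mask(mask.shape, roi)
    boundary = roi_m & ~_erode(roi_m)
    labels = cc_label(mask, connectivity=2)
    centroids, areas = [], []
    touches = False
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid
        centroids.append((cx, cy))
        areas.append(region.area)
        if boundary[tuple(np.array(region.coords).T)].any():
            touches = True
    n = len(centroids)
    return ConeCount(
        roi_id=roi_id,
        n_units=n,
        centroids=np.array(centroids).reshape(-1, 2),
        areas=np.array(areas, dtype=int),
        ambiguous=bool(n > 4 or touches),
    )


def _erode(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    return binary_erosion(mask, np.ones((3, 3)))
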