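"""Isolate neural traces: tone balancing, dark thresholding, inversion, blur.

The procedure converts a fossil-plate photograph into a punctum-density
map: (1) rectify tonal imbalance by fitting a low-order multiplicative
field to the light background and dividing it out; (2) keep only pixels at
least ``k_frac`` black (blackness K = 1 - intensity, the K channel of a
neutral-gray CMYK decomposition), retaining the darkest puncta; (3) invert
to white profiles on black; (4) apply an isotropic Gaussian blur that
expands and runs together the puncta into a continuous density in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from cephalon.plate import DensityMap, TracePlate

__all__ = [
    "IsolationParams",
    "balance_tone",
    "threshold_dark",
    "invert_mask",
    "gaussian_density",
    "isolate_traces",
]


@dataclass(frozen=True)
class IsolationParams:
    """Parameters of the isolation chain.

    k_frac: blackness threshold fraction (default 0.87, i.e. 87 % black).
    sigma_px: Gaussian standard deviation in pixels.  The editing-software
        radius R = 10 px that the workflow emulates has no published
        radius-to-sigma mapping; sigma is declared directly and defaults
        to 10 px.
    tone_correction: polynomial order of the tonal field (0 disables).
    """

    k_frac: float = 0.87
    sigma_px: float = 10.0
    tone_correction: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.k_frac < 1.0:
            raise ValueError("k_frac must be in (0, 1)")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be > 0")
        if self.tone_correction < 0:
            raise ValueError("tone_correction order must be >= 0")


def _rescale(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi - lo < 1e-12:
        return np.clip(a, 0.0, 1.0)
    return (a - lo) / (hi - lo)


def _poly_design(shape: tuple[int, int], order: int) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    u = xx.ravel() / max(w - 1, 1) - 0.5
    v = yy.ravel() / max(h - 1, 1) - 0.5
    cols = [np.ones_like(u)]
    for total in range(1, order + 1):
        for i in range(total + 1):
            cols.append(u ** (total - i) * v**i)
    return np.stack(cols, axis=1)


def balance_tone(plate: TracePlate, tone_correction: int | None = 1) -> TracePlate:
    """Divide out a fitted low-order background field and rescale to [0, 1].

    The field is fitted by least squares to the background, taken as the
    pixels above the median intensity (traces are dark and sparse, so the
    median sits in the background).  ``tone_correction=None`` or 0 skips
    the fit and only min-max rescales.  A constant-intensity plate is
    returned unchanged with a warning.
    """
    px = plate.pixels
    if float(px.max()) - float(px.min()) < 1e-12:
        warnings.warn("constant-intensity plate: tone balancing skipped")
        return plate
    if not tone_correction:
        return plate.with_pixels(_rescale(px), "rescale")
    X = _poly_design(px.shape, int(tone_correction))
    flat = px.ravel()
    # pass 1 separates dark traces from background via the median; pass 2
    # refits on every background pixel so the value cut does not tilt the fit
    bg = flat >= np.median(flat)
    for _ in range(2):
        coef, *_ = np.linalg.lstsq(X[bg], flat[bg], rcond=None)
        ratio = flat / np.maximum(X @ coef, 1e-3)
        bg = ratio > 0.5
    field = np.maximum((X @ coef).reshape(px.shape), 1e-3)
    corrected = _rescale(flat.reshape(px.shape) / field)
    return plate.with_pixels(corrected, f"balance_tone(order={tone_correction})")


def threshold_dark(plate: TracePlate, k_frac: float = 0.87) -> np.ndarray:
    """Boolean mask of pixels at least ``k_frac`` black (K = 1 - intensity)."""
    if not 0.0 < k_frac <= 1.0:
        raise ValueError("k_frac must be in (0, 1]")
    return (1.0 - plate.pixels) >= k_frac


def invert_mask(mask: np.ndarray) -> TracePlate:
    """White (1.0) where the mask is true, black elsewhere."""
    return TracePlate(np.where(np.asarray(mask, bool), 1.0, 0.0), provenance="inverted-mask")


def gaussian_density(plate: TracePlate, sigma_px: float) -> DensityMap:
    """Normalised isotropic Gaussian blur with reflective boundaries."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    # truncation at 6 sigma keeps the discarded tail mass below 1e-8
    out = gaussian_filter(plate.pixels, sigma=sigma_px, mode="reflect", truncate=6.0)
    # convolution of values in [0,1] stays in [0,1] bar roundoff
    out = np.clip(out, 0.0, 1.0)
    return DensityMap(out, params={"sigma_px": sigma_px}, provenance=plate.provenance)


def isolate_traces(plate: TracePlate, params: IsolationParams = IsolationParams()) -> DensityMap:
    """Full chain: balance -> threshold -> invert -> blur, params recorded."""
    balanced = balance_tone(plate, params.tone_correction)
    mask = threshold_dark(balanced, params.k_frac)
    inverted = invert_mask(mask)
    dens = gaussian_density(inverted, params.sigma_px)
    return DensityMap(
        dens.pixels,
        params={
            "k_frac": params.k_frac,
            "sigma_px": params.sigma_px,
            "tone_correction": params.tone_correction,
        },
        provenance=f"{plate.provenance};isolate_traces",
    )
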