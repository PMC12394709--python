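"""Raster and landmark containers shared by every image stage.

A :class:`TracePlate` is the unit of all image processing: a 2-D grid of
intensities normalised to [0, 1] (0 = black, 1 = white) with optional
pixel-size metadata and a provenance string.  A :class:`DensityMap` is the
product of trace isolation: a blurred punctum-density raster on the same
grid.  A :class:`LandmarkSet` carries the manually annotated anatomy used
for registration: the antero-posterior midline, the outline of the
esophageal foramen, the ocellar-nerve points of the anterior sclerite, and
named regions of interest.

Coordinates are 0-based pixel centers, origin top-left, x rightward
(columns), y downward (rows).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "TracePlate",
    "DensityMap",
    "LandmarkSet",
    "read_plate",
    "write_plate",
]

#: ITU-R BT.709 luminance weights used to collapse RGB to grayscale.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


def _as_unit_float(pixels: np.ndarray) -> np.ndarray:
    """Convert an image array of any integer/float dtype to float64 in [0, 1]."""
    a = np.asarray(pixels)
    if a.ndim == 3:
        if a.shape[2] == 4:  # drop alpha
            a = a[:, :, :3]
        a = a.astype(np.float64) @ _LUMA if a.dtype.kind == "f" else (
            a.astype(np.float64) @ _LUMA
        )
        if np.issubdtype(np.asarray(pixels).dtype, np.integer):
            info = np.iinfo(np.asarray(pixels).dtype)
            a = a / info.max
        return np.clip(a, 0.0, 1.0)
    if np.issubdtype(a.dtype, np.integer):
        info = np.iinfo(a.dtype)
        return a.astype(np.float64) / info.max
    return np.clip(a.astype(np.float64), 0.0, 1.0)


@dataclass(frozen=True)
class TracePlate:
    """Grayscale fossil-plate raster with intensities in [0, 1]."""

    pixels: np.ndarray
    pixel_size: float | None = None  # mm per pixel, if known
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("plate must be a nonempty 2-D grid")
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise ValueError("plate intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, note: str = "") -> "TracePlate":
        prov = f"{self.provenance};{note}" if note else self.provenance
        return replace(self, pixels=pixels, provenance=prov)


@dataclass(frozen=True)
class DensityMap:
    """Punctum-density raster in [0, 1] produced by trace isolation."""

    pixels: np.ndarray
    params: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("density map must be a nonempty 2-D grid")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LandmarkSet:
    """Anatomical landmarks anchoring midline, registration and ROIs.

    ``midline`` is two distinct points on the antero-posterior axis;
    ``foramen_outline`` is a closed polyline (>= 3 vertices) around the
    esophageal foramen whose *first vertex* is the registration start
    vertex; ``ocellar_nerves`` are alignment points on the anterior
    sclerite; ``rois`` maps region names (``eyestalk_left`` etc.) to
    polygon vertex arrays.
    """

    midline: np.ndarray
    foramen_outline: np.ndarray
    ocellar_nerves: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    rois: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mid = np.asarray(self.midline, dtype=np.float64).reshape(2, 2)
        if np.allclose(mid[0], mid[1]):
            raise ValueError("midline points must be distinct")
        outline = np.asarray(self.foramen_outline, dtype=np.float64)
        if outline.ndim != 2 or outline.shape[0] < 3 or outline.shape[1] != 2:
            raise ValueError("foramen outline needs >= 3 (x, y) vertices")
        object.__setattr__(self, "midline", mid)
        object.__setattr__(self, "foramen_outline", outline)
        object.__setattr__(
            self,
            "ocellar_nerves",
            np.asarray(self.ocellar_nerves, dtype=np.float64).reshape(-1, 2),
        )
        object.__setattr__(
            self,
            "rois",
            {k: np.asarray(v, dtype=np.float64).reshape(-1, 2) for k, v in self.rois.items()},
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "midline": self.midline.tolist(),
            "foramen_outline": self.foramen_outline.tolist(),
            "ocellar_nerves": self.ocellar_nerves.tolist(),
            "rois": {k: v.tolist() for k, v in self.rois.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        d = json.loads(Path(path).read_text())
        return cls(
            midline=np.asarray(d["midline"]),
            foramen_outline=np.asarray(d["foramen_outline"]),
            ocellar_nerves=np.asarray(d.get("ocellar_nerves", [])).reshape(-1, 2),
            rois={k: np.asarray(v) for k, v in d.get("rois", {}).items()},
        )


def read_plate(path: str | Path, pixel_size: float | None = None) -> TracePlate:
    """Read a PNG/TIFF photograph, collapsing RGB to luminance grayscale."""
    raw = iio.imread(path)
    return TracePlate(_as_unit_float(raw), pixel_size=pixel_size, provenance=str(path))


def write_plate(pixels: np.ndarray, path: str | Path) -> None:
    """Write an intensity grid in [0, 1] as a 16-bit grayscale PNG/TIFF."""
    a = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(a * 65535.0).astype(np.uint16))
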