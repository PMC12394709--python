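"""Synthetic fossil plates and character matrices with known ground truth.

Every downstream stage of the pipeline is validated against data produced
here: plates bearing dark granular puncta arranged in an exactly
mirror-symmetric "cephalic nervous system" template, degraded by the
taphonomic distortions seen in compressed fossils (depth-asymmetric
erasure from axial rotation, lateral displacement, background speckle,
tonal gradients); and binary character matrices evolved on known trees
under the symmetric 2-state Mk process.

The template is an idealised stand-in for a stem-euarthropod cerebrum:
paired eyestalk neuropils with an optic-lobe chain, circumesophageal
cords, a medial synganglion ring around the esophageal foramen, and paired
ocellar nerves on the anterior sclerite.  Region shapes are placed on the
right of a vertical midline and mirrored, so the region set is invariant
under reflection by construction.

The axial-rotation model: each side of a rotated specimen exposes a
different preservation depth.  Here every
punctum is a mirror pair with a latent depth u ~ U(0,1); at rotation
asymmetry r the left copy is erased when u < r/2 and the right copy when
u > 1 - r/2, so the erased subsets are disjoint and at r = 1 the two sides
survive on exactly complementary depth ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from cephalon.plate import LandmarkSet, TracePlate
from cephalon.cladistics.matrix import MISSING, CharacterMatrix
from cephalon.cladistics.tree import Tree

__all__ = [
    "Shape",
    "SymmetricTemplate",
    "TaphonomyParams",
    "GroundTruth",
    "SimTreeModel",
    "make_template",
    "render_plate",
    "simulate_characters",
    "make_cone_fixture",
    "BACKGROUND_INTENSITY",
    "PUNCTUM_INTENSITY",
    "PUNCTUM_RADIUS",
]

#: background and punctum intensities place puncta safely below an
#: 87%-black threshold (intensity 0.13) before any tonal gradient
BACKGROUND_INTENSITY = 0.92
PUNCTUM_INTENSITY = 0.05
#: puncta are single points dilated to small disks, matching granular
#: deposits at plate magnification
PUNCTUM_RADIUS = 2


@dataclass(frozen=True)
class Shape:
    """Filled ellipse (optionally with a concentric hole) in plate coords."""

    label: str
    center: tuple[float, float]  # (x, y)
    semiaxes: tuple[float, float]  # (a along x, b along y) before rotation
    rotation: float = 0.0  # radians, counterclockwise
    hole_semiaxes: tuple[float, float] | None = None

    def mask(self, plate_size: tuple[int, int]) -> np.ndarray:
        h, w = plate_size
        m = np.zeros((h, w), dtype=bool)
        cx, cy = self.center
        a, b = self.semiaxes
        rr, cc = draw_ellipse(cy, cx, b, a, shape=(h, w), rotation=self.rotation)
        m[rr, cc] = True
        if self.hole_semiaxes is not None:
            ha, hb = self.hole_semiaxes
            rr, cc = draw_ellipse(cy, cx, hb, ha, shape=(h, w), rotation=self.rotation)
            m[rr, cc] = False
        return m

    def mirrored(self, axis_x: float) -> "Shape":
        cx, cy = self.center
        return replace(
            self,
            label=self.label.replace("_R", "_L") if "_R" in self.label else self.label + "_mirror",
            center=(2 * axis_x - cx, cy),
            rotation=-self.rotation,
        )


@dataclass(frozen=True)
class SymmetricTemplate:
    """Mirror-symmetric region set around a vertical midline."""

    shapes: tuple[Shape, ...]
    axis: np.ndarray  # two (x, y) points on the midline
    plate_size: tuple[int, int]  # (height, width)

    @property
    def axis_x(self) -> float:
        return float(self.axis[0][0])

    def region_mask(self, labels: tuple[str, ...] | None = None) -> np.ndarray:
        m = np.zeros(self.plate_size, dtype=bool)
        for s in self.shapes:
            if labels is None or s.label in labels:
                m |= s.mask(self.plate_size)
        return m

    def landmarks(self) -> LandmarkSet:
        """Annotation set derived from the template geometry.

        The foramen outline starts at its topmost vertex, which lies on the
        midline: a marked start vertex that is a fixed point of reflection.
        """
        h, w = self.plate_size
        ax = self.axis_x
        ring = next(s for s in self.shapes if s.label == "synganglion")
        cx, cy = ring.center
        ha, hb = ring.hole_semiaxes
        theta = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        # parametrised from the top point (on the midline), clockwise on screen
        outline = np.stack(
            [cx + (ha + 2) * np.sin(theta), cy - (hb + 2) * np.cos(theta)], axis=1
        )
        oc_r = next(s for s in self.shapes if s.label == "ocellar_R")
        oc_l = oc_r.mirrored(ax)
        ocellar = np.array([oc_l.center, (ax, oc_r.center[1] - 18), oc_r.center])
        eye_r = next(s for s in self.shapes if s.label == "eyestalk_R")
        ex, ey = eye_r.center
        ea = max(eye_r.semiaxes) + 8
        roi_r = np.array(
            [[ex - ea, ey - ea], [ex + ea, ey - ea], [ex + ea, ey + ea], [ex - ea, ey + ea]]
        )
        roi_l = roi_r.copy()
        roi_l[:, 0] = 2 * ax - roi_l[:, 0]
        sclerite = np.array([[ax - 60, 8], [ax + 60, 8], [ax + 60, 80], [ax - 60, 80]])
        return LandmarkSet(
            midline=np.array([[ax, 8.0], [ax, h - 8.0]]),
            foramen_outline=outline,
            ocellar_nerves=ocellar,
            rois={
                "eyestalk_right": roi_r,
                "eyestalk_left": roi_l,
                "anterior_sclerite": sclerite,
            },
        )


@dataclass(frozen=True)
class TaphonomyParams:
    """Degradations applied to a rendered plate; all rates nonnegative."""

    rotation_asymmetry: float = 0.0  # in [0, 1]; erased fraction per side is r/2
    lateral_shift: float = 0.0  # max |offset| in px applied rigidly per region
    speckle_rate: float = 0.0  # background dark puncta per px^2
    tone_gradient: float = 0.0  # amplitude of the multiplicative tonal field
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rotation_asymmetry <= 1.0:
            raise ValueError("rotation_asymmetry must be in [0, 1]")
        if self.lateral_shift < 0 or self.speckle_rate < 0 or self.tone_gradient < 0:
            raise ValueError("rates must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score recovery of a rendered plate."""

    template: SymmetricTemplate
    taphonomy: TaphonomyParams
    shifts: dict  # (region label, side) -> (dx, dy)
    puncta_full: dict  # side -> (n, 2) float array of (x, y), before erasure
    puncta: dict  # side -> (n, 2) after erasure and shifts
    speckle: np.ndarray  # (n, 2) background punctum coordinates


def make_template(layout_spec: dict | None = None, seed: int = 0) -> SymmetricTemplate:
    """Randomised but exactly mirror-symmetric cephalic template.

    ``layout_spec`` may override ``plate_size`` (height, width; width even),
    ``n_optic`` (circles in each eyestalk's optic-lobe chain) and ``jitter``
    (placement randomisation in px).  Deterministic given ``seed``.
    """
    spec = {"plate_size": (360, 440), "n_optic": 2, "jitter": 6.0}
    spec.update(layout_spec or {})
    h, w = spec["plate_size"]
    if h < 200 or w < 240:
        raise ValueError("plate too small to contain the requested regions")
    if w % 2:
        raise ValueError("plate width must be even for an exact pixel midline")
    rng = np.random.default_rng(seed)
    ax = (w - 1) / 2.0
    j = spec["jitter"]

    def jit(scale: float = 1.0) -> float:
        return float(rng.uniform(-j, j)) * scale

    sx, sy = w / 440.0, h / 360.0  # scale the reference layout to the plate
    right = [
        Shape(
            "eyestalk_R",
            (ax + (118 + jit()) * sx, (110 + jit()) * sy),
            (58 * sx, 42 * sy),
            rotation=-0.45 + 0.05 * jit(0.1),
        ),
        Shape(
            "cord_R",
            (ax + (52 + jit(0.5)) * sx, (262 + jit()) * sy),
            (32 * sx, 58 * sy),
            rotation=0.30,
        ),
        Shape("ocellar_R", (ax + 24 * sx, (58 + jit(0.5)) * sy), (16 * sx, 16 * sy)),
    ]
    for i in range(spec["n_optic"]):
        frac = (i + 1) / (spec["n_optic"] + 1)
        right.append(
            Shape(
                f"optic{i + 1}_R",
                (ax + (118 - 68 * frac + jit(0.5)) * sx, (110 + 42 * frac + jit(0.5)) * sy),
                (26 * sx, 26 * sy),
            )
        )
    medial = Shape(
        "synganglion",
        (ax, (205 + jit(0.5)) * sy),
        (64 * sx, 52 * sy),
        hole_semiaxes=(26 * sx, 20 * sy),
    )
    shapes = tuple(right) + tuple(s.mirrored(ax) for s in right) + (medial,)
    axis = np.array([[ax, 0.0], [ax, float(h - 1)]])
    return SymmetricTemplate(shapes=shapes, axis=axis, plate_size=(h, w))


def _paint_puncta(canvas: np.ndarray, coords: np.ndarray, value: float) -> None:
    h, w = canvas.shape
    for x, y in coords:
        rr, cc = draw_disk((y, x), PUNCTUM_RADIUS, shape=(h, w))
        canvas[rr, cc] = value


def _tone_field(shape: tuple[int, int], amp: float, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    u, v = xx / (w - 1) - 0.5, yy / (h - 1) - 0.5
    c = rng.uniform(-1, 1, size=5)
    f = c[0] * u + c[1] * v + c[2] * u * v + c[3] * (u**2 - 1 / 12) + c[4] * (v**2 - 1 / 12)
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)  # normalised to [0, 1]
    return 1.0 - amp * f


def render_plate(
    template: SymmetricTemplate,
    punctum_density: float = 0.02,
    taphonomy: TaphonomyParams = TaphonomyParams(),
) -> tuple[TracePlate, GroundTruth]:
    """Render a light plate with dark puncta in the template regions.

    Puncta are sampled as exact mirror pairs at ``punctum_density`` per px^2
    of region area, then degraded: depth-asymmetric erasure (rotation),
    per-region lateral shifts, background speckle, and a multiplicative
    tonal gradient.  The returned :class:`GroundTruth` records every punctum
    and transform.
    """
    if punctum_density <= 0:
        raise ValueError("punctum_density must be > 0")
    h, w = template.plate_size
    rng = np.random.default_rng(taphonomy.seed)
    ax = template.axis_x
    r = taphonomy.rotation_asymmetry

    # sample mirror-pair puncta on the right half-plane of the region union
    # (sampling the union, not shape-by-shape, keeps the density exact where
    # regions overlap); each punctum keeps the label of the first shape
    # containing it, for per-region lateral shifts
    label_map = np.full((h, w), -1, dtype=np.int32)
    for i, s in enumerate(reversed(template.shapes)):
        label_map[s.mask((h, w))] = len(template.shapes) - 1 - i
    union = label_map >= 0
    union[:, np.arange(w) <= ax] = False  # strictly-right pixels
    ys, xs = np.nonzero(union)
    n = rng.poisson(punctum_density * len(xs)) if len(xs) else 0
    pick = rng.integers(0, len(xs), size=n) if n else np.empty(0, dtype=int)
    right = np.stack([xs[pick].astype(float), ys[pick].astype(float)], axis=1) if n else np.empty((0, 2))
    labels_per_pt = np.array(
        [template.shapes[label_map[int(y), int(x)]].label for x, y in right],
        dtype=object,
    )
    left = right.copy()
    left[:, 0] = 2 * ax - left[:, 0]

    # depth-asymmetric erasure: disjoint subsets per side
    u = rng.uniform(size=len(right))
    keep_left = u >= r / 2.0
    keep_right = u <= 1.0 - r / 2.0

    # per-region rigid lateral shifts, recorded per (label, side)
    shifts: dict = {}
    shifted = {"left": left.copy(), "right": right.copy()}
    if taphonomy.lateral_shift > 0:
        for side in ("left", "right"):
            for lab in sorted({str(x) for x in labels_per_pt}):
                d = rng.uniform(-taphonomy.lateral_shift, taphonomy.lateral_shift, 2)
                shifts[(lab, side)] = (float(d[0]), float(d[1]))
                sel = labels_per_pt == lab
                shifted[side][sel] += d

    kept = {
        "left": shifted["left"][keep_left],
        "right": shifted["right"][keep_right],
    }

    n_speckle = rng.poisson(taphonomy.speckle_rate * h * w)
    speckle = np.stack(
        [rng.uniform(0, w - 1, n_speckle), rng.uniform(0, h - 1, n_speckle)], axis=1
    ) if n_speckle else np.empty((0, 2))

    canvas = np.full((h, w), BACKGROUND_INTENSITY)
    _paint_puncta(canvas, speckle, PUNCTUM_INTENSITY)
    _paint_puncta(canvas, kept["left"], PUNCTUM_INTENSITY)
    _paint_puncta(canvas, kept["right"], PUNCTUM_INTENSITY)
    if taphonomy.tone_gradient > 0:
        canvas = canvas * _tone_field((h, w), taphonomy.tone_gradient, rng)
    plate = TracePlate(np.clip(canvas, 0, 1), provenance=f"synthetic(seed={taphonomy.seed})")
    truth = GroundTruth(
        template=template,
        taphonomy=taphonomy,
        shifts=shifts,
        puncta_full={"left": left, "right": right},
        puncta=kept,
        speckle=speckle,
    )
    return plate, truth


# ---------------------------------------------------------------------------
# character simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimTreeModel:
    """Mk simulation settings: rooted tree with branch lengths in expected
    substitutions per character (total leaving rate 1)."""

    tree: Tree
    n_chars: int
    k_states: int = 2
    missing_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_states != 2:
            raise ValueError("only binary characters are supported")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must be in [0, 1)")
        if self.n_chars < 1:
            raise ValueError("n_chars must be positive")
        for u in self.tree.adj:
            for v, t in self.tree.adj[u].items():
                if t is None or t < 0:
                    raise ValueError("tree must have nonnegative branch lengths")


def simulate_characters(model: SimTreeModel) -> CharacterMatrix:
    """Evolve independent binary characters down the tree under Mk.

    Root states are drawn from the stationary (1/2, 1/2) distribution; along
    a branch of length t a state flips with probability (1 - e^(-2t))/2.
    Entries are replaced by the missing symbol at rate ``missing_frac``.
    """
    rng = np.random.default_rng(model.seed)
    tree = model.tree
    n = model.n_chars
    order = tree.postorder()  # (node, parent), children first
    states: dict[int, np.ndarray] = {}
    for u, p in reversed(order):  # preorder: parents before children
        if p is None:
            states[u] = rng.integers(0, 2, size=n, dtype=np.int8)
        else:
            t = tree.adj[u][p]
            flip = rng.random(n) < 0.5 * (1.0 - np.exp(-2.0 * t))
            states[u] = np.where(flip, 1 - states[p], states[p]).astype(np.int8)
    taxa = sorted(tree.names.values())
    leaf_of = {name: node for node, name in tree.names.items()}
    chars = np.stack([states[leaf_of[t]] for t in taxa])
    if model.missing_frac > 0:
        mask = rng.random(chars.shape) < model.missing_frac
        chars = np.where(mask, np.int8(MISSING), chars)
    return CharacterMatrix(list(taxa), chars)


# ---------------------------------------------------------------------------
# compound-eye (Semper cell) fixture
# ---------------------------------------------------------------------------


def make_cone_fixture(
    n_units: int = 4,
    seed: int = 0,
    size: tuple[int, int] = (96, 96),
    unit_radius: float = 7.0,
    snr: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RGB image of one ommatidium with bright yellow-green internal units.

    Returns (image, roi polygon, unit centers).  The background emulates
    the dull greenish matrix of the UV view — same chromatic band as the
    units but far dimmer — with Gaussian value noise scaled so the units'
    excess over background is ``snr`` times the noise sigma.  Peak
    isolation then reduces to the value quantile within the band.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    cy, cx = h / 2.0, w / 2.0
    ring_r = min(h, w) / 4.5
    phase = rng.uniform(0, 2 * np.pi)
    angles = phase + np.arange(n_units) * 2 * np.pi / max(n_units, 1)
    centers = np.stack(
        [cx + ring_r * np.cos(angles), cy + ring_r * np.sin(angles)], axis=1
    )
    base_v, unit_v = 0.35, 0.85
    noise_sigma = (unit_v - base_v) / snr
    hsv = np.zeros((h, w, 3))
    hsv[..., 0] = 95.0 / 360.0  # dull greenish matrix, inside the band
    hsv[..., 1] = 0.45
    hsv[..., 2] = base_v
    for x, y in centers:
        rr, cc = draw_disk((y, x), unit_radius, shape=(h, w))
        hsv[rr, cc, 0] = 110.0 / 360.0  # yellow-green
        hsv[rr, cc, 1] = 0.8
        hsv[rr, cc, 2] = unit_v
    hsv[..., 2] = np.clip(hsv[..., 2] + rng.normal(0, noise_sigma, (h, w)), 0, 1)
    from skimage.color import hsv2rgb

    image = hsv2rgb(hsv)
    margin = 4.0
    roi = np.array(
        [[margin, margin], [w - margin, margin], [w - margin, h - margin], [margin, h - margin]]
    )
    return image, roi, centers
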