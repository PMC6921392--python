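"""Synthetic X-ray angiography phantom with known layer decomposition.

Real coronary angiograms superimpose several moving layers: a static
anatomy layer (vertebrae, ribs, catheter), a large smooth structure moving
with respiration (diaphragm/lung), and a thin dark vessel tree that pulses
with the cardiac cycle while contrast agent flows in over the first frames.
This module composes exactly those layers so that every downstream stage
(morphological top-hat, low-rank/sparse decomposition, Hessian features,
segmentation metrics) can be tested against known ground truth:

    frame_i = clip( static - respiratory_i - vessel_i + noise_i , 0, 1 )

Vessels are rendered *dark* (absorption dips on a brighter background), the
standard X-ray polarity.  Vessel centerlines are cubic Bezier curves with
Gaussian cross-sectional profiles — smooth differentiable tubes that match
the tubular model underlying the Hessian vesselness descriptors.  The
respiratory layer is a translated anisotropic Gaussian dimming, a large
smooth structure that a sufficiently large grayscale closing removes.

Everything is deterministic under a fixed seed (bit-exact), and the
emitted ground truth stores the actual noise realisation so the sequence
can be recomposed exactly from its layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .sequence import ImageSequence, write_masks, write_sequence


class PhantomError(ValueError):
    """Invalid phantom configuration; the message names the field."""


@dataclass(frozen=True)
class VesselTreeSpec:
    """Geometry of the synthetic coronary tree.

    ``diameter_range`` is the full-width-at-half-maximum range of the
    Gaussian tube profiles in pixels; ``intensity_depth`` is the peak
    absorption (grayscale fraction in [0, 1]) at full contrast inflow.
    """

    n_branches: int = 5
    diameter_range: tuple[float, float] = (2.0, 4.0)
    intensity_depth: float = 0.35


@dataclass(frozen=True)
class PhantomConfig:
    frame_height: int = 128
    frame_width: int = 128
    n_frames: int = 30
    pixel_spacing_mm: float = 0.3
    vessel_tree: VesselTreeSpec = field(default_factory=VesselTreeSpec)
    #: frames over which vessel contrast ramps from 0 to full (agent inflow)
    contrast_inflow_frames: int = 8
    #: diaphragm translation, px.  At this frame scale (128 px spanning a
    #: ~15 cm field) 8 px is ~1 cm, a typical tidal-breathing excursion.
    respiratory_amplitude: float = 8.0
    respiratory_period: float = 20.0        # frames per breath
    respiratory_intensity: float = 0.12     # peak dimming of the breathing layer
    #: coronary displacement over the cardiac cycle, px (~7 mm here)
    cardiac_amplitude: float = 6.0
    cardiac_period: float = 8.0             # frames per heartbeat
    noise_sigma: float = 0.01               # additive Gaussian noise std
    include_catheter: bool = True           # thin static dark curve
    include_static_structures: bool = True  # vertebra/rib blobs and texture
    seed: int = 0

    def validate(self) -> None:
        tree = self.vessel_tree
        checks = [
            ("frame_height", self.frame_height >= 1),
            ("frame_width", self.frame_width >= 1),
            ("n_frames", self.n_frames >= 1),
            ("pixel_spacing_mm", self.pixel_spacing_mm > 0),
            ("contrast_inflow_frames", self.contrast_inflow_frames >= 1),
            ("respiratory_amplitude", self.respiratory_amplitude >= 0),
            ("respiratory_period", self.respiratory_period >= 1),
            ("respiratory_intensity", 0 <= self.respiratory_intensity <= 1),
            ("cardiac_amplitude", self.cardiac_amplitude >= 0),
            ("cardiac_period", self.cardiac_period >= 1),
            ("noise_sigma", self.noise_sigma >= 0),
            ("vessel_tree.n_branches", tree.n_branches >= 1),
            (
                "vessel_tree.diameter_range",
                0 < tree.diameter_range[0] <= tree.diameter_range[1],
            ),
            ("vessel_tree.intensity_depth", 0 <= tree.intensity_depth <= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise PhantomError(f"invalid phantom configuration field: {name}")


@dataclass
class GroundTruth:
    """Known layer decomposition of a generated phantom sequence.

    ``compose()`` rebuilds the emitted frames exactly from the stored
    layers and noise realisation.
    """

    vessel_mask: np.ndarray          # (n, h, w) bool
    static_layer: np.ndarray         # (h, w)
    respiratory_layer: np.ndarray    # (n, h, w)
    vessel_layer: np.ndarray         # (n, h, w) absorption, >= 0
    noise: np.ndarray                # (n, h, w)
    seed: int = 0

    def compose(self) -> np.ndarray:
        stack = (
            self.static_layer[None]
            - self.respiratory_layer
            - self.vessel_layer
            + self.noise
        )
        return np.clip(stack, 0.0, 1.0)


# ---------------------------------------------------------------------------
# geometry helpers

def _bezier(p0, p1, p2, p3, n: int) -> np.ndarray:
    """Sample a cubic Bezier curve at n points; returns (n, 2) xy array."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * p1
        + 3 * (1 - t) * t**2 * p2
        + t**3 * p3
    )


def _render_tube(
    points: np.ndarray, shape: tuple[int, int], diameter: float, depth: float
) -> np.ndarray:
    """Rasterize a tube with a Gaussian cross-section around a polyline.

    ``diameter`` is the FWHM of the profile; the profile is truncated at
    2 sigma and shifted so that absorption decays continuously to zero at
    the support boundary.
    """
    h, w = shape
    canvas = np.ones(shape, dtype=bool)
    ij = np.round(points[:, ::-1]).astype(int)  # (row, col)
    inside = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
    ij = ij[inside]
    if ij.size == 0 or depth == 0:
        return np.zeros(shape)
    canvas[ij[:, 0], ij[:, 1]] = False
    dist = ndimage.distance_transform_edt(canvas)
    sigma = diameter / 2.355  # FWHM -> Gaussian sigma
    cutoff = 2.0 * sigma
    edge = np.exp(-0.5 * (cutoff / sigma) ** 2)
    profile = (np.exp(-0.5 * (dist / sigma) ** 2) - edge) / (1.0 - edge)
    profile[dist > cutoff] = 0.0
    return depth * np.clip(profile, 0.0, None)


def _tree_branches(config: PhantomConfig) -> list[dict]:
    """Deterministically lay out the branch curves of the vessel tree.

    Returns one dict per branch with sampled centerline ``points`` (in
    frame coordinates, undisplaced), ``diameter`` and relative ``depth``.
    The trunk runs top-to-bottom; children split off at random arc
    positions with a random branching angle, tapering in diameter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_height, config.frame_width
    dmin, dmax = config.vessel_tree.diameter_range
    n_samples = max(64, 3 * max(h, w))

    p0 = np.array([rng.uniform(0.25, 0.45) * w, 0.05 * h])
    p3 = np.array([rng.uniform(0.40, 0.70) * w, rng.uniform(0.85, 0.95) * h])
    p1 = p0 + np.array([rng.uniform(-0.25, 0.25) * w, 0.3 * h])
    p2 = p3 + np.array([rng.uniform(-0.25, 0.25) * w, -0.3 * h])
    trunk = _bezier(p0, p1, p2, p3, n_samples)
    branches = [
        {"points": trunk, "diameter": dmax, "depth": 1.0}
    ]

    for _ in range(config.vessel_tree.n_branches - 1):
        parent = branches[rng.integers(0, len(branches))]
        pts = parent["points"]
        k = int(rng.uniform(0.25, 0.75) * (len(pts) - 2))
        start = pts[k]
        tangent = pts[k + 1] - pts[k - 1]
        tangent = tangent / (np.linalg.norm(tangent) + 1e-12)
        ang = np.deg2rad(rng.uniform(25, 60)) * rng.choice([-1.0, 1.0])
        rot = np.array(
            [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
        )
        direction = rot @ tangent
        length = rng.uniform(0.30, 0.55) * min(h, w)
        end = start + direction * length
        c1 = start + direction * (0.33 * length)
        c2 = end + rng.uniform(-0.12, 0.12, size=2) * min(h, w)
        hi = max(dmin, 0.85 * parent["diameter"])
        diameter = min(parent["diameter"], rng.uniform(dmin, hi + 1e-9))
        branches.append(
            {
                "points": _bezier(start, c1, c2, end, n_samples // 2),
                "diameter": diameter,
                "depth": rng.uniform(0.85, 1.0),
            }
        )
    return branches


def _cardiac_offset(config: PhantomConfig, frame_index: int) -> np.ndarray:
    phase = np.sin(2.0 * np.pi * frame_index / config.cardiac_period)
    direction = np.array([0.555, 0.832])  # fixed oblique axis, unit norm
    return config.cardiac_amplitude * phase * direction


def _vessel_respiratory_drift(config: PhantomConfig, frame_index: int) -> np.ndarray:
    """Vertical drift of the coronary tree with the breathing phase.

    The heart rides on the diaphragm, so the vessel tree shares the
    respiratory translation at reduced amplitude (half the diaphragm's).
    Superposing the two incommensurate phases keeps the tree from
    revisiting pixel-identical positions, as in real sequences.
    """
    phase = np.sin(2.0 * np.pi * frame_index / config.respiratory_period)
    return np.array([0.0, 0.5 * config.respiratory_amplitude * phase])


def _inflow_factor(config: PhantomConfig, frame_index: int) -> float:
    return min(1.0, frame_index / config.contrast_inflow_frames)


def generate_vessel_tree(
    config: PhantomConfig, frame_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Absorption image and support mask of the vessel tree at one frame.

    The tree is rigidly displaced by the cardiac phase
    ``sin(2*pi*frame_index/cardiac_period) * cardiac_amplitude`` and its
    absorption scaled by the inflow factor
    ``min(1, frame_index/contrast_inflow_frames)``.
    """
    config.validate()
    if not 0 <= frame_index < config.n_frames:
        raise PhantomError("frame_index out of range for n_frames")
    shape = (config.frame_height, config.frame_width)
    inflow = _inflow_factor(config, frame_index)
    depth0 = config.vessel_tree.intensity_depth
    if inflow == 0.0 or depth0 == 0.0:
        z = np.zeros(shape)
        return z, z.astype(bool)
    offset = _cardiac_offset(config, frame_index) + _vessel_respiratory_drift(
        config, frame_index
    )
    absorption = np.zeros(shape)
    for br in _tree_branches(config):
        tube = _render_tube(
            br["points"] + offset, shape, br["diameter"], depth0 * br["depth"] * inflow
        )
        absorption = np.maximum(absorption, tube)
    return absorption, absorption > 0


# ---------------------------------------------------------------------------
# static and respiratory layers

def _static_layer(config: PhantomConfig) -> np.ndarray:
    """Background anatomy: base level, vertebra blobs, rib bands, catheter."""
    rng = np.random.default_rng(config.seed + 1)
    h, w = config.frame_height, config.frame_width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    layer = np.full((h, w), 0.80)

    if config.include_static_structures:
        # vertebral column: a stack of soft rectangles slightly off-centre
        col_x = 0.62 * w
        n_vert = max(2, h // 28)
        for k in range(n_vert):
            cy = (k + 0.5) * h / n_vert
            block = (np.abs(xx - col_x) < 0.09 * w) & (
                np.abs(yy - cy) < 0.38 * h / n_vert
            )
            layer -= 0.13 * ndimage.gaussian_filter(block.astype(float), 1.5)

        # two broad rib-like diagonal bands with soft but high-contrast edges
        for sgn, off in ((1.0, 0.25), (-1.0, 0.65)):
            band = np.abs((yy - off * h) - sgn * 0.2 * (xx - 0.5 * w)) < 0.035 * h
            layer += 0.07 * ndimage.gaussian_filter(band.astype(float), 1.5)

        # faint fixed-pattern texture so the layer is not piecewise flat
        layer += 0.015 * ndimage.gaussian_filter(rng.standard_normal((h, w)), 4.0)

    if config.include_catheter:
        # catheter: a thin static dark curve entering from the top left
        p0 = np.array([0.08 * w, 0.0])
        p3 = np.array([0.16 * w, 0.98 * h])
        p1 = np.array([0.02 * w, 0.35 * h])
        p2 = np.array([0.22 * w, 0.65 * h])
        cath = _bezier(p0, p1, p2, p3, 3 * max(h, w))
        layer -= _render_tube(cath, (h, w), diameter=2.5, depth=0.28)

    return np.clip(layer, 0.0, 1.0)


def _respiratory_layer(config: PhantomConfig, frame_index: int) -> np.ndarray:
    """Large anisotropic Gaussian dimming translating with the breath phase."""
    h, w = config.frame_height, config.frame_width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    shift = config.respiratory_amplitude * np.sin(
        2.0 * np.pi * frame_index / config.respiratory_period
    )
    cy = 0.85 * h + shift
    cx = 0.35 * w
    sy = 0.30 * h
    sx = 0.55 * w
    return config.respiratory_intensity * np.exp(
        -0.5 * (((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2)
    )


# ---------------------------------------------------------------------------

def generate_sequence(config: PhantomConfig) -> tuple[ImageSequence, GroundTruth]:
    """Compose the phantom sequence and its ground-truth decomposition.

    Frames lie in [0, 1]; vessels are dark intensity dips.  Identical
    config and seed give bit-identical output.
    """
    config.validate()
    h, w, n = config.frame_height, config.frame_width, config.n_frames
    static = _static_layer(config)
    resp = np.stack([_respiratory_layer(config, i) for i in range(n)])
    vessels = np.zeros((n, h, w))
    masks = np.zeros((n, h, w), dtype=bool)
    for i in range(n):
        vessels[i], masks[i] = generate_vessel_tree(config, i)
    noise_rng = np.random.default_rng(config.seed + 7919)
    noise = (
        config.noise_sigma * noise_rng.standard_normal((n, h, w))
        if config.noise_sigma > 0
        else np.zeros((n, h, w))
    )
    gt = GroundTruth(
        vessel_mask=masks,
        static_layer=static,
        respiratory_layer=resp,
        vessel_layer=vessels,
        noise=noise,
        seed=config.seed,
    )
    seq = ImageSequence(
        gt.compose(),
        pixel_spacing_mm=config.pixel_spacing_mm,
        meta={"phantom_seed": config.seed},
    )
    return seq, gt


def save_phantom(
    seq: ImageSequence,
    gt: GroundTruth,
    config: PhantomConfig,
    directory: str | Path,
) -> None:
    """Persist a phantom: frames as TIFF, masks as PNGs, manifest as text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_sequence(seq, directory / "frames.tif", dtype="float32")
    write_masks(gt.vessel_mask, directory / "masks", prefix="vessel")
    lines = []
    for key, value in vars(config).items():
        if isinstance(value, VesselTreeSpec):
            for k2, v2 in vars(value).items():
                lines.append(f"vessel_tree.{k2}: {v2}")
        else:
            lines.append(f"{key}: {value}")
    (directory / "manifest.txt").write_text("\n".join(lines) + "\n")


def with_overrides(config: PhantomConfig, **kwargs) -> PhantomConfig:
    """Frozen-dataclass convenience: a copy with fields replaced."""
    tree_keys = {k: v for k, v in kwargs.items() if hasattr(VesselTreeSpec, k)}
    rest = {k: v for k, v in kwargs.items() if k not in tree_keys}
    if tree_keys:
        rest["vessel_tree"] = replace(config.vessel_tree, **tree_keys)
    return replace(config, **rest)
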