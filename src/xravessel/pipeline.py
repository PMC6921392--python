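"""End-to-end vessel enhancement and segmentation pipeline.

Stage order: normalize -> circular-SE top-hat (DI) -> streaming inter-frame
low-rank/sparse pass (E) -> second top-hat (DI') -> per-frame intra pass
with the ones basis (V) -> multi-scale feature fusion (F) -> threshold
segmentation (SI) -> metrics (when ground-truth masks are available).

Polarity bookkeeping is centralized here.  The top-hat direction makes
vessels *positive* in DI, both sparse components inherit that sign, and
the feature stage therefore runs in bright-vessel mode.  The second
top-hat must again extract the thin structures from a vessels-positive
image, so it is applied to the negated component (a closing on ``-E`` is
an opening-based white top-hat on ``E``).  The low-dose simulation maps
the enhanced component back to the original dark-vessel convention before
recombining.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import evaluate_sequence
from .features import FeatureConfig, fuse_multiscale, threshold_segment
from .morphology import make_circular_se, remove_layer_by_closing
from .rpca import RpcaConfig, inter_frame_rpca, intra_frame_rpca
from .sequence import ImageSequence, read_sequence, write_masks, write_sequence

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    input_path: str | None = None
    truth_masks_path: str | None = None
    output_dir: str | None = None
    pixel_spacing_mm: float = 0.3
    rpca: RpcaConfig = field(default_factory=RpcaConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    subtract_direction: str = "close_minus_frame"
    second_close_input: str = "E"  # or "DI"
    #: gray-level scale on which the decomposition operates.  The
    #: empirical regularizer rule 2.1/max(M1, M2) and the feature
    #: thresholds are both calibrated for 8-bit-like gray values; on a
    #: [0, 1] scale the same rule would over-shrink the sparse component.
    processing_scale: float = 255.0
    enable_second_close: bool = True
    enable_intra: bool = True
    save_intermediates: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.pixel_spacing_mm > 0:
            raise PipelineError("pixel_spacing_mm must be positive")
        if not self.processing_scale > 0:
            raise PipelineError("processing_scale must be positive")
        if self.second_close_input not in ("E", "DI"):
            raise PipelineError(
                f"second_close_input must be 'E' or 'DI', got "
                f"{self.second_close_input!r}"
            )
        self.rpca.validate()
        self.features.validate()

    # -- plain-text round trip --------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["features"]["sigma_list"] = list(self.features.sigma_list)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "rpca" in d and isinstance(d["rpca"], dict):
            d["rpca"] = RpcaConfig(**d["rpca"])
        if "features" in d and isinstance(d["features"], dict):
            f = dict(d["features"])
            if "sigma_list" in f:
                f["sigma_list"] = tuple(f["sigma_list"])
            d["features"] = FeatureConfig(**f)
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class PipelineResult:
    """Every intermediate of one run, vessels-positive convention.

    ``V`` is the enhanced vascular sequence, ``F`` the fused feature
    responses, ``SI`` the binary segmentations; ``metrics`` is the
    per-frame table when ground truth was supplied.
    """

    config: PipelineConfig
    original: ImageSequence
    DI: ImageSequence
    B: ImageSequence
    E: ImageSequence
    DIprime: ImageSequence
    V: ImageSequence
    F: np.ndarray
    SI: np.ndarray
    metrics: object = None  # pandas DataFrame when ground truth was given

    def vessels_positive(self) -> bool:
        return self.config.subtract_direction == "close_minus_frame"


def _stage_stats(name: str, frames: np.ndarray, t0: float) -> None:
    logger.info(
        "stage %-12s %6.2fs  min %+.4f  max %+.4f  mean %+.4f",
        name,
        time.perf_counter() - t0,
        float(frames.min()),
        float(frames.max()),
        float(frames.mean()),
    )


def run_on_sequence(
    seq: ImageSequence,
    config: PipelineConfig | None = None,
    truth_masks: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full enhancement + segmentation pipeline on a sequence."""
    config = config or PipelineConfig()
    config.validate()
    sign = 1.0 if config.subtract_direction == "close_minus_frame" else -1.0

    t0 = time.perf_counter()
    norm = seq.normalized()
    se = make_circular_se(seq.pixel_spacing_mm)
    logger.info("structuring element: %s", se)

    DI = remove_layer_by_closing(norm, se, config.subtract_direction)
    _stage_stats("top-hat", DI.frames, t0)

    # internal work is always vessels-positive, on the gray-level scale
    DI_pos = DI.copy_with(sign * config.processing_scale * DI.frames)

    t0 = time.perf_counter()
    B, E, _ = inter_frame_rpca(DI_pos, config.rpca)
    if config.rpca.clip_negative:
        E = E.copy_with(np.clip(E.frames, 0.0, None))
    _stage_stats("inter-rpca", E.frames, t0)

    t0 = time.perf_counter()
    if config.enable_second_close:
        source = E if config.second_close_input == "E" else DI_pos
        # closing of the negated frames == opening-based white top-hat,
        # i.e. the same thin-structure extraction in positive polarity
        DIprime = remove_layer_by_closing(
            source.copy_with(-source.frames), se, "close_minus_frame"
        )
    else:
        DIprime = E
    _stage_stats("2nd top-hat", DIprime.frames, t0)

    t0 = time.perf_counter()
    if config.enable_intra:
        V = intra_frame_rpca(DIprime, config.rpca)
        if config.rpca.clip_negative:
            V = V.copy_with(np.clip(V.frames, 0.0, None))
    else:
        V = DIprime
    _stage_stats("intra-rpca", V.frames, t0)

    t0 = time.perf_counter()
    # V is already on the gray-level scale the descriptors expect
    feat_cfg = dataclasses.replace(
        config.features, polarity="bright_vessels", intensity_scale=1.0
    )
    F = np.empty_like(V.frames)
    SI = np.empty(V.frames.shape, dtype=bool)
    for i, frame in enumerate(V.frames):
        maps = fuse_multiscale(frame, feat_cfg)
        F[i] = maps.fused
        SI[i] = threshold_segment(maps.fused, feat_cfg.threshold)
    _stage_stats("features", F, t0)

    # emitted sequences go back to the input's [0, 1] scale and polarity
    back = sign / config.processing_scale
    result = PipelineResult(
        config=config,
        original=norm,
        DI=DI,
        B=B.copy_with(back * B.frames),
        E=E.copy_with(back * E.frames),
        DIprime=DIprime.copy_with(back * DIprime.frames),
        V=V.copy_with(back * V.frames),
        F=F,
        SI=SI,
    )
    if truth_masks is not None:
        # CNR is polarity-invariant; score the vessels-positive component
        result.metrics = evaluate_sequence(
            V.frames, truth_masks, segmentations=SI
        )
    return result


def simulate_low_dose(
    original: ImageSequence,
    enhanced_V: ImageSequence,
    dose_fraction: float,
) -> ImageSequence:
    """Angiogram with a reduced effective contrast-agent dose.

    The enhanced vascular component is mapped back to the original's
    dark-vessel polarity and linearly subtracted:
    ``out = original - (1 - dose_fraction) * (-V_positive)``.  A dose
    fraction of 1 returns the original exactly; 0 removes the full
    estimated vessel signal.
    """
    if original.frames.shape != enhanced_V.frames.shape:
        raise PipelineError("original and enhanced sequences differ in shape")
    if not 0.0 <= dose_fraction <= 1.0:
        raise PipelineError("dose_fraction must lie in [0, 1]")
    if dose_fraction == 1.0:
        return original.copy_with(original.frames.copy())
    filled = original.frames + (1.0 - dose_fraction) * enhanced_V.frames
    return original.copy_with(np.clip(filled, 0.0, 1.0))


def _write_manifest(config: PipelineConfig, out: Path) -> None:
    import numpy
    import scipy
    import skimage

    manifest = (
        f"xravessel: {__version__}\n"
        f"numpy: {numpy.__version__}\n"
        f"scipy: {scipy.__version__}\n"
        f"scikit-image: {skimage.__version__}\n"
        f"seed: {config.seed}\n"
    )
    (out / "manifest.txt").write_text(manifest)
    (out / "config.yaml").write_text(config.to_yaml())


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: read input, run, persist outputs."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    if config.input_path is None:
        raise PipelineError("config.input_path is required")
    seq = read_sequence(config.input_path, config.pixel_spacing_mm)
    truth = None
    if config.truth_masks_path is not None:
        from .sequence import read_masks

        truth = read_masks(config.truth_masks_path)
    result = run_on_sequence(seq, config, truth_masks=truth)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sequence(result.V, out / "V.tif")
        write_masks(result.SI, out / "SI", prefix="si")
        if config.save_intermediates:
            write_sequence(result.DI, out / "DI.tif")
            write_sequence(result.B, out / "B.tif")
            write_sequence(result.E, out / "E.tif")
            write_sequence(result.DIprime, out / "DIprime.tif")
            write_sequence(result.original.copy_with(result.F), out / "F.tif")
        if result.metrics is not None:
            result.metrics.to_csv(out / "metrics.csv")
        _write_manifest(config, out)
    return result
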