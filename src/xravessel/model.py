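"""Model/results facade over the enhancement pipeline.

:class:`VesselSegmentationModel` is constructed from the data (an image
sequence, optionally with ground-truth masks) plus configuration, and
``fit()`` runs the decomposition and segmentation, returning a
:class:`VesselSegmentationResults` that carries the estimated components,
per-frame diagnostics and a ``summary()`` table.  This mirrors the
model/fit/results convention of statistical modelling packages: the
low-rank basis, coefficients and sparse components *are* the fitted
quantities of the per-frame convex objective.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .pipeline import (
    PipelineConfig,
    PipelineResult,
    run_on_sequence,
    simulate_low_dose,
)
from .sequence import ImageSequence


class VesselSegmentationModel:
    """Vessel enhancement/segmentation model for an angiographic sequence.

    Parameters
    ----------
    sequence : ImageSequence or ndarray (n, h, w)
        The grayscale frame stack (dark vessels, X-ray polarity).
    truth_masks : ndarray of bool, optional
        Per-frame ground-truth vessel masks; enables metrics.
    config : PipelineConfig, optional
        Full pipeline configuration; keyword overrides are applied on top
        (e.g. ``seed=3``, ``pixel_spacing_mm=0.2``).
    """

    def __init__(
        self,
        sequence: ImageSequence | np.ndarray,
        truth_masks: np.ndarray | None = None,
        config: PipelineConfig | None = None,
        **overrides,
    ) -> None:
        config = config or PipelineConfig()
        if overrides:
            config = replace(config, **overrides)
        if not isinstance(sequence, ImageSequence):
            sequence = ImageSequence(
                np.asarray(sequence), pixel_spacing_mm=config.pixel_spacing_mm
            )
        self.sequence = sequence
        self.truth_masks = truth_masks
        self.config = config

    @classmethod
    def from_file(cls, path, truth_masks=None, **overrides):
        from .sequence import read_sequence

        config = PipelineConfig(**overrides) if overrides else PipelineConfig()
        seq = read_sequence(path, config.pixel_spacing_mm)
        return cls(seq, truth_masks=truth_masks, config=config)

    def fit(self) -> "VesselSegmentationResults":
        result = run_on_sequence(
            self.sequence, self.config, truth_masks=self.truth_masks
        )
        return VesselSegmentationResults(self, result)


class VesselSegmentationResults:
    """Fitted components and diagnostics of one pipeline run."""

    def __init__(self, model: VesselSegmentationModel, result: PipelineResult):
        self.model = model
        self._result = result

    # -- estimated components ---------------------------------------------
    @property
    def enhanced(self) -> ImageSequence:
        """Enhanced vascular sequence V (vessels positive)."""
        return self._result.V

    @property
    def segmentation(self) -> np.ndarray:
        """Binary vessel masks SI, one per frame."""
        return self._result.SI

    @property
    def features(self) -> np.ndarray:
        """Fused multi-scale feature responses F."""
        return self._result.F

    @property
    def background(self) -> ImageSequence:
        """Low-rank (quasi-static) component B of the inter-frame pass."""
        return self._result.B

    @property
    def sparse(self) -> ImageSequence:
        """Sparse component E of the inter-frame pass."""
        return self._result.E

    @property
    def intermediates(self) -> PipelineResult:
        return self._result

    @property
    def metrics(self) -> pd.DataFrame | None:
        """Per-frame CNR and segmentation metrics (needs ground truth)."""
        return self._result.metrics

    # -- downstream operations --------------------------------------------
    def simulate_low_dose(self, dose_fraction: float) -> ImageSequence:
        """Original sequence with vessel contrast scaled to dose_fraction."""
        return simulate_low_dose(
            self._result.original, self._result.V, dose_fraction
        )

    def plot_frame(self, i: int, ax=None):
        """QC montage of one frame: original, enhanced V, response F, mask SI."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(1, 4, figsize=(12, 3))
        panels = [
            (self._result.original.frames[i], "original", "gray"),
            (self._result.V.frames[i], "enhanced V", "gray"),
            (self._result.F[i], "fused response F", "magma"),
            (self._result.SI[i], "segmentation SI", "gray"),
        ]
        for a, (img, title, cmap) in zip(np.ravel(ax), panels):
            a.imshow(img, cmap=cmap)
            a.set_title(title, fontsize=9)
            a.axis("off")
        return ax

    def diagnostics(self) -> pd.DataFrame:
        """Per-stage intensity statistics of the fitted components."""
        rows = []
        stages = {
            "original": self._result.original.frames,
            "DI": self._result.DI.frames,
            "B": self._result.B.frames,
            "E": self._result.E.frames,
            "DI'": self._result.DIprime.frames,
            "V": self._result.V.frames,
            "F": self._result.F,
        }
        for name, frames in stages.items():
            rows.append(
                {
                    "stage": name,
                    "min": float(frames.min()),
                    "max": float(frames.max()),
                    "mean": float(frames.mean()),
                    "nonzero_frac": float(np.mean(frames != 0)),
                }
            )
        return pd.DataFrame(rows).set_index("stage")

    def summary(self) -> str:
        cfg = self.model.config
        n, (h, w) = len(self.model.sequence), self.model.sequence.frame_shape
        lines = [
            "Vessel segmentation results",
            "=" * 64,
            f"frames: {n}  size: {h}x{w}  "
            f"pixel spacing: {self.model.sequence.pixel_spacing_mm} mm",
            f"rank bound r={cfg.rpca.rank_r}, r'={cfg.rpca.rank_r_prime}; "
            f"seed={cfg.rpca.seed}",
            f"feature scales: {list(cfg.features.sigma_list)}  "
            f"weights: ({cfg.features.alpha1}, {cfg.features.alpha2})",
            "",
            "Stage diagnostics:",
            self.diagnostics().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.metrics is not None:
            lines += [
                "",
                "Per-frame metrics (last rows aggregate mean/std):",
                self.metrics.tail(4).to_string(
                    float_format=lambda v: f"{v:.4f}"
                ),
            ]
        return "\n".join(lines)
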