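"""Contrast-to-noise ratio and pixelwise segmentation metrics.

Enhancement quality is measured as CNR = |mu_F - mu_B| / sigma_B, the mean
intensity gap between the vessel region and a background region in units
of the background's standard deviation (sample, n-1).  Two background
definitions are used: *global* — everything outside the vessel mask — and
*local* — a ring around the vessel boundary (default: the 7-pixel-wide
outer neighborhood), which is more sensitive to halo artefacts hugging
the vessels.

Segmentation quality is precision, sensitivity and F1 from pixel counts:
pre = TP/(TP+FP), sen = TP/(TP+FN), F1 their harmonic mean.  Empty
denominators return 0 with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .morphology import disk_mask


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class MaskSet:
    """Vessel mask plus its global and local background masks."""

    vessel: np.ndarray
    global_background: np.ndarray
    local_background: np.ndarray

    def __post_init__(self) -> None:
        v, g, l = self.vessel, self.global_background, self.local_background
        if not (v.shape == g.shape == l.shape):
            raise EvaluationError("mask shapes differ")
        if np.any(v & g) or np.any(v & l):
            raise EvaluationError("vessel mask overlaps a background mask")
        if np.any(l & ~g):
            raise EvaluationError("local background not contained in global")


def make_local_mask(vessel_mask: np.ndarray, width: int = 7) -> np.ndarray:
    """Outer ring around the vessel boundary: dilate by a disk of radius
    ``width`` and subtract the mask.  Clipped at frame borders."""
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        raise EvaluationError("empty vessel mask: local background undefined")
    footprint = disk_mask(2 * width + 1)
    dilated = ndimage.binary_dilation(vessel_mask, structure=footprint)
    return dilated & ~vessel_mask


def make_mask_set(vessel_mask: np.ndarray, local_width: int = 7) -> MaskSet:
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    return MaskSet(
        vessel=vessel_mask,
        global_background=~vessel_mask,
        local_background=make_local_mask(vessel_mask, local_width),
    )


def cnr(
    image: np.ndarray, vessel_mask: np.ndarray, background_mask: np.ndarray
) -> float:
    """|mean(vessel) - mean(background)| / std(background), sample std."""
    image = np.asarray(image, dtype=np.float64)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not vessel_mask.any() or not background_mask.any():
        raise EvaluationError("CNR requires non-empty vessel and background masks")
    fg = image[vessel_mask]
    bg = image[background_mask]
    sigma_b = bg.std(ddof=1) if bg.size > 1 else 0.0
    if sigma_b <= 0:
        raise EvaluationError("degenerate background: sigma_B = 0")
    return float(abs(fg.mean() - bg.mean()) / sigma_b)


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    fn: int
    precision: float
    sensitivity: float
    f1: float
    cnr_global: float | None = None
    cnr_local: float | None = None


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: empty denominator, returning 0", stacklevel=3)
        return 0.0
    return num / den


def segmentation_metrics(SI: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Pixelwise precision / sensitivity / F1 of a binary segmentation."""
    SI = np.asarray(SI, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if SI.shape != truth.shape:
        raise EvaluationError(
            f"segmentation shape {SI.shape} != truth shape {truth.shape}"
        )
    tp = int(np.sum(SI & truth))
    fp = int(np.sum(SI & ~truth))
    fn = int(np.sum(~SI & truth))
    pre = _ratio(tp, tp + fp, "precision")
    sen = _ratio(tp, tp + fn, "sensitivity")
    f1 = 2 * pre * sen / (pre + sen) if pre + sen > 0 else 0.0
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, precision=pre, sensitivity=sen, f1=f1
    )


def evaluate_sequence(
    images: np.ndarray,
    truth_masks: np.ndarray,
    segmentations: np.ndarray | None = None,
    local_width: int = 7,
) -> pd.DataFrame:
    """Per-frame metrics table with a mean +/- std aggregate row.

    ``images`` are the enhanced frames whose contrast is being scored
    against the ground-truth vessel masks; ``segmentations``, when given,
    adds precision / sensitivity / F1 columns.  Frames whose mask is
    empty (e.g. before contrast inflow) have NaN CNR entries.
    """
    images = np.asarray(images, dtype=np.float64)
    truth_masks = np.asarray(truth_masks, dtype=bool)
    rows = []
    for i in range(images.shape[0]):
        row: dict = {"frame": i}
        mask = truth_masks[i]
        if mask.any():
            ms = make_mask_set(mask, local_width)
            try:
                row["cnr_global"] = cnr(images[i], ms.vessel, ms.global_background)
                row["cnr_local"] = cnr(images[i], ms.vessel, ms.local_background)
            except EvaluationError:
                row["cnr_global"] = np.nan
                row["cnr_local"] = np.nan
        else:
            row["cnr_global"] = np.nan
            row["cnr_local"] = np.nan
        if segmentations is not None:
            rep = segmentation_metrics(segmentations[i], mask)
            row.update(
                precision=rep.precision, sensitivity=rep.sensitivity, f1=rep.f1
            )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("frame")
    agg = pd.DataFrame(
        {"mean": df.mean(), "std": df.std()}
    ).T
    agg.index.name = "frame"
    return pd.concat([df, agg])
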