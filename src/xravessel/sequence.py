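"""Image-sequence container and file I/O.

An :class:`ImageSequence` is an ordered stack of equally sized grayscale
frames together with the physical pixel spacing.  It is the carrier for
every intermediate product of the enhancement pipeline (the raw angiogram
``I``, the respiratory estimate ``R``, the difference sequences ``DI`` and
``DI'``, the sparse vascular components ``E`` and ``V``).

Frames are stored as a single ``float64`` array of shape ``(n_frames,
height, width)``.  On disk a sequence is a multi-page TIFF or a directory
of PNG/TIFF frames (lexicographic order); intensities are rescaled to
``[0, 1]`` on read according to the source bit depth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


class SequenceError(ValueError):
    """Raised for unreadable, inconsistent or empty image sequences."""


@dataclass
class ImageSequence:
    """Stack of equally sized grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Frame stack.  Stored as float64.
    pixel_spacing_mm : float
        Physical size of a pixel in millimetres (isotropic).
    """

    frames: np.ndarray
    pixel_spacing_mm: float = 0.3
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise SequenceError(
                f"frames must be a (n, h, w) stack, got shape {arr.shape}"
            )
        if arr.shape[0] == 0:
            raise SequenceError("empty sequence")
        if not np.all(np.isfinite(arr)):
            raise SequenceError("frames contain non-finite values")
        self.frames = arr

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def copy_with(self, frames: np.ndarray) -> "ImageSequence":
        """New sequence with the same spacing/metadata but different frames."""
        return ImageSequence(
            frames=np.asarray(frames, dtype=np.float64),
            pixel_spacing_mm=self.pixel_spacing_mm,
            meta=dict(self.meta),
        )

    def normalized(self) -> "ImageSequence":
        """Affinely rescale the whole stack to span [0, 1].

        A single global (per-sequence) scaling is used so that inter-frame
        contrast-agent inflow is preserved.  A constant stack maps to zeros.
        """
        lo = float(self.frames.min())
        hi = float(self.frames.max())
        if hi - lo <= 0:
            return self.copy_with(np.zeros_like(self.frames))
        return self.copy_with((self.frames - lo) / (hi - lo))


_EXTENSIONS = (".png", ".tif", ".tiff")


def _to_grayscale(arr: np.ndarray, path: str) -> np.ndarray:
    """Collapse an RGB(A) frame to luminance; pass grayscale through."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        return rgb @ np.array([0.2126, 0.7152, 0.0722])
    raise SequenceError(f"{path}: cannot interpret shape {arr.shape} as grayscale")


def _scale_to_unit(arr: np.ndarray) -> np.ndarray:
    """Map integer images to [0, 1] by their dtype range; floats pass through."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    return arr.astype(np.float64)


def read_sequence(path: str | Path, pixel_spacing_mm: float = 0.3) -> ImageSequence:
    """Read a sequence from a multi-page TIFF, a frame directory, or DICOM.

    Directories are read in lexicographic filename order.  Integer pixel
    types are scaled to [0, 1] by their dtype maximum (e.g. 16-bit TIFF by
    1/65535); float frames are taken as-is.
    """
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"input not found: {path}")

    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _EXTENSIONS
        )
        if not files:
            raise SequenceError(f"no image frames found in directory {path}")
        frames = []
        for f in files:
            try:
                arr = iio.imread(f)
            except Exception as exc:  # corrupt frame: name the file
                raise SequenceError(f"cannot read frame {f}: {exc}") from exc
            frames.append(_scale_to_unit(_to_grayscale(arr, str(f))))
        shapes = {fr.shape for fr in frames}
        if len(shapes) > 1:
            offending = [
                str(f) for f, fr in zip(files, frames) if fr.shape != frames[0].shape
            ]
            raise SequenceError(
                "frames have mixed sizes; offending files: " + ", ".join(offending)
            )
        stack = np.stack(frames)
    elif path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
        stack = _scale_to_unit(np.asarray(raw))
        if stack.ndim == 2:
            stack = stack[None]
    elif path.suffix.lower() in (".dcm", ".dicom"):
        stack = _read_dicom(path)
    else:
        raise SequenceError(f"unsupported input format: {path}")
    return ImageSequence(stack, pixel_spacing_mm=pixel_spacing_mm)


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional reader
        raise SequenceError("pydicom is required to read DICOM input") from exc
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 2:
        arr = arr[None]
    denom = float(2 ** int(ds.BitsStored) - 1) if "BitsStored" in ds else float(arr.max() or 1)
    return arr.astype(np.float64) / denom


def write_sequence(
    seq: ImageSequence, path: str | Path, dtype: str = "float32"
) -> None:
    """Write a sequence as a multi-page TIFF (float32 or uint8)."""
    path = Path(path)
    os.makedirs(path.parent, exist_ok=True)
    if dtype == "float32":
        data = seq.frames.astype(np.float32)
    elif dtype == "uint8":
        data = np.clip(np.round(seq.frames * 255.0), 0, 255).astype(np.uint8)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}; use 'float32' or 'uint8'")
    tifffile.imwrite(path, data, photometric="minisblack")


def write_masks(masks: np.ndarray, directory: str | Path, prefix: str = "mask") -> list:
    """Write a binary mask stack as per-frame PNGs; returns the paths."""
    directory = Path(directory)
    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, m in enumerate(np.asarray(masks, dtype=bool)):
        p = directory / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, (m.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def read_masks(directory: str | Path) -> np.ndarray:
    """Read a per-frame PNG mask directory back into a boolean stack."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise SequenceError(f"no PNG masks in {directory}")
    return np.stack([np.asarray(iio.imread(f)) > 127 for f in files])
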