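"""Raster I/O and dataset-directory scanning.

Retinal segmentation benchmarks ship as directories of fundus photographs
with per-image manual vessel tracings (and, for DRIVE, circular
field-of-view masks).  This module reads those rasters, binarizes mask
files, writes prediction maps back out, and enumerates a dataset directory
into (image, truth, optional FOV) triples keyed by a shared filename stem.

Expected layouts::

    drive_like / stare_like     flat
    ------------------------    --------------------
    root/images/<stem>.*        root/<stem>_img.*
    root/truth/<stem>.*         root/<stem>_truth.*
    root/fov/<stem>.*           root/<stem>_fov.*

``stare_like`` is ``drive_like`` without a ``fov/`` directory; in both
layouts the FOV is optional per image (absent means the whole frame).
Coordinates are row-major, origin top-left, 0-based; masks share the image
grid exactly.  GIF truths (the DRIVE dialect) are decoded via their first
frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "SamplePair",
    "DatasetPairingError",
    "ImageFormatError",
    "read_image",
    "read_mask",
    "write_mask",
    "scan_dataset",
]

_RASTER_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".gif", ".ppm", ".pgm")


class DatasetPairingError(ValueError):
    """An image lacks a matching ground-truth file (or vice versa)."""


class ImageFormatError(ValueError):
    """The file exists but cannot be decoded as a raster image."""


@dataclass
class SamplePair:
    """One dataset sample: RGB image, binary truth, optional binary FOV."""

    image: np.ndarray  # H×W×3 uint8
    truth: np.ndarray  # H×W uint8 in {0, 1}
    fov: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.truth.shape:
            raise ValueError(
                f"sample {self.id!r}: image {self.image.shape[:2]} and "
                f"truth {self.truth.shape} dimensions disagree"
            )
        if self.fov is not None and self.fov.shape != self.truth.shape:
            raise ValueError(
                f"sample {self.id!r}: fov {self.fov.shape} and "
                f"truth {self.truth.shape} dimensions disagree"
            )

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


def _decode(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = iio.imread(path, index=0) if path.suffix.lower() == ".gif" else iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ImageFormatError(f"cannot decode {path}: {exc}") from exc
    return np.asarray(arr)


def read_image(path: str | Path) -> np.ndarray:
    """Read a raster as H×W×3 uint8; grayscale sources are replicated to 3 channels."""
    arr = _decode(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(f"{path}: unsupported raster shape {arr.shape}")
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        scale = info.max if info else 1.0
        arr = np.clip(np.asarray(arr, dtype=np.float64) / scale * 255.0, 0, 255)
        arr = arr.round().astype(np.uint8)
    return arr


def read_mask(path: str | Path, threshold: int = 128) -> np.ndarray:
    """Read a raster and binarize: pixel >= threshold -> 1 else 0 (H×W uint8)."""
    arr = _decode(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr >= threshold).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask (as {0, 255}) or probability map (scaled, round-half-up).

    Probabilities in [0, 1] are scaled by 255 and rounded half away from
    zero, so 0.5 -> 128.  Round-trips through :func:`read_mask` losslessly
    for binary input.
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    if np.issubdtype(m.dtype, np.floating):
        if m.min() < 0 or m.max() > 1:
            raise ValueError("probability maps must lie in [0, 1]")
        out = np.floor(m * 255.0 + 0.5).astype(np.uint8)
    else:
        if not np.isin(m, (0, 1)).all():
            raise ValueError("integer masks must be binary")
        out = (m * 255).astype(np.uint8)
    iio.imwrite(Path(path), out)


def _stem_index(folder: Path, strip: str = "") -> dict[str, Path]:
    index: dict[str, Path] = {}
    if not folder.is_dir():
        return index
    for f in sorted(folder.iterdir()):
        if f.suffix.lower() in _RASTER_SUFFIXES:
            stem = f.stem
            if strip and stem.endswith(strip):
                stem = stem[: -len(strip)]
            index[stem] = f
    return index


def scan_dataset(root: str | Path, layout: str = "drive_like") -> list[SamplePair]:
    """Enumerate a dataset directory into SamplePairs, ordered by stem.

    Raises :class:`DatasetPairingError` listing every orphan when images and
    truths do not pair one-to-one.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"no such dataset directory: {root}")
    if layout in ("drive_like", "stare_like"):
        images = _stem_index(root / "images")
        truths = _stem_index(root / "truth")
        fovs = _stem_index(root / "fov")
    elif layout == "flat":
        images = {k[:-4]: v for k, v in _stem_index(root).items() if k.endswith("_img")}
        truths = {k[:-6]: v for k, v in _stem_index(root).items() if k.endswith("_truth")}
        fovs = {k[:-4]: v for k, v in _stem_index(root).items() if k.endswith("_fov")}
    else:
        raise ValueError(f"unknown layout {layout!r}")

    orphans = sorted(set(images) ^ set(truths))
    if orphans:
        raise DatasetPairingError(
            f"unpaired image/truth stems in {root}: {', '.join(orphans)}"
        )
    pairs = []
    for stem in sorted(images):
        pairs.append(
            SamplePair(
                image=read_image(images[stem]),
                truth=read_mask(truths[stem]),
                fov=read_mask(fovs[stem]) if stem in fovs else None,
                id=stem,
            )
        )
    extra_fov = sorted(set(fovs) - set(images))
    if extra_fov:
        warnings.warn(f"FOV masks without matching images ignored: {', '.join(extra_fov)}")
    return pairs
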