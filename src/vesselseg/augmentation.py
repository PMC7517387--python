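"""Paired image/mask augmentation: rotate, mirror, shift, crop.

Training sets of twenty-odd fundus images are far too small for a deep
segmentation network, so the set is expanded geometrically.  Four transforms
are applied, each stage expanding the set and every transform applied
identically to the image, the truth mask and the FOV mask: rotation at fixed
angular intervals (30° by default, the identity orientation included),
mirroring, a random shift of 20–50 px toward one of the four corners, and
random fixed-size crops (four 512×512 patches by default).

Images are interpolated bilinearly; masks use nearest-neighbor so they stay
binary.  Regions moved in from outside the frame are zero-filled.  Every
output carries a provenance id of the form
``<source>/rot<deg>/mir<axis>/shift<dr>,<dc>/crop<k>``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_datasets import SamplePair

__all__ = [
    "AugmentPlan",
    "rotations",
    "mirror",
    "random_shift",
    "random_crops",
    "augment_dataset",
]


@dataclass(frozen=True)
class AugmentPlan:
    """Multiplicities and bounds for the four-stage augmentation pipeline."""

    rotation_step_deg: float = 30.0
    shift_min_px: int = 20
    shift_max_px: int = 50
    n_shifts: int = 1
    n_crops: int = 4
    crop_size: int = 512
    seed: int = 0
    do_rotate: bool = True
    do_mirror: bool = True
    do_shift: bool = True
    do_crop: bool = True
    mirror_axis: str = "horizontal"

    def __post_init__(self) -> None:
        if not 0 < self.rotation_step_deg <= 360:
            raise ValueError("rotation step must be in (0, 360]")
        if self.shift_min_px > self.shift_max_px:
            raise ValueError("shift_min_px must be <= shift_max_px")
        if self.shift_min_px < 0:
            raise ValueError("shifts must be non-negative")
        if self.n_crops < 1 or self.crop_size < 1 or self.n_shifts < 1:
            raise ValueError("multiplicities and crop size must be positive")
        if self.mirror_axis not in ("horizontal", "vertical"):
            raise ValueError("mirror_axis must be 'horizontal' or 'vertical'")


def _rotate_pair(pair: SamplePair, angle: float, tag: str) -> SamplePair:
    if angle % 360 == 0:
        return SamplePair(pair.image.copy(), pair.truth.copy(),
                          None if pair.fov is None else pair.fov.copy(),
                          id=f"{pair.id}/{tag}")
    img = ndimage.rotate(pair.image, angle, axes=(0, 1), reshape=False,
                         order=1, mode="constant", cval=0)
    truth = ndimage.rotate(pair.truth, angle, reshape=False, order=0,
                           mode="constant", cval=0)
    fov = None
    if pair.fov is not None:
        fov = ndimage.rotate(pair.fov, angle, reshape=False, order=0,
                             mode="constant", cval=0)
    return SamplePair(np.clip(img, 0, 255).astype(np.uint8),
                      truth.astype(np.uint8), fov, id=f"{pair.id}/{tag}")


def rotations(pair: SamplePair, step_deg: float = 30.0) -> list[SamplePair]:
    """All ⌊360/step⌋ orientations at multiples of ``step_deg`` (0° included)."""
    if step_deg <= 0:
        raise ValueError("rotation step must be positive")
    n = int(360 // step_deg)
    return [_rotate_pair(pair, k * step_deg, f"rot{int(round(k * step_deg)):03d}")
            for k in range(max(n, 1))]


def mirror(pair: SamplePair, axis: str = "horizontal") -> SamplePair:
    """Flip image and masks about the given axis; an involution."""
    if axis == "horizontal":
        flip = lambda a: a[:, ::-1].copy()  # noqa: E731
    elif axis == "vertical":
        flip = lambda a: a[::-1].copy()  # noqa: E731
    else:
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    return SamplePair(flip(pair.image), flip(pair.truth),
                      None if pair.fov is None else flip(pair.fov),
                      id=f"{pair.id}/mir{axis[0]}")


def _shift_array(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(a)
    H, W = a.shape[:2]
    src_r = slice(max(0, -dr), min(H, H - dr))
    dst_r = slice(max(0, dr), min(H, H + dr))
    src_c = slice(max(0, -dc), min(W, W - dc))
    dst_c = slice(max(0, dc), min(W, W + dc))
    out[dst_r, dst_c] = a[src_r, src_c]
    return out


def random_shift(
    pair: SamplePair, plan: AugmentPlan, rng: np.random.Generator
) -> SamplePair:
    """Shift toward a uniformly drawn corner by independent per-axis magnitudes.

    Corner directions are the four sign combinations of (row, col); the
    magnitude on each axis is a uniform integer in
    [shift_min_px, shift_max_px].  Vacated pixels are zero-filled and the
    same displacement is applied to image, truth and FOV.
    """
    H, W = pair.truth.shape
    if plan.shift_max_px >= min(H, W):
        raise ValueError(f"shift bound {plan.shift_max_px} >= image dimension {min(H, W)}")
    sr, sc = rng.choice([-1, 1]), rng.choice([-1, 1])
    dr = int(sr) * int(rng.integers(plan.shift_min_px, plan.shift_max_px + 1))
    dc = int(sc) * int(rng.integers(plan.shift_min_px, plan.shift_max_px + 1))
    return SamplePair(
        _shift_array(pair.image, dr, dc),
        _shift_array(pair.truth, dr, dc),
        None if pair.fov is None else _shift_array(pair.fov, dr, dc),
        id=f"{pair.id}/shift{dr:+d},{dc:+d}",
    )


def random_crops(
    pair: SamplePair, plan: AugmentPlan, rng: np.random.Generator
) -> list[SamplePair]:
    """``n_crops`` random ``crop_size``² patches, identical offsets on image and masks.

    Images smaller than the crop are zero-padded at the bottom/right first;
    every patch is a contiguous sub-array of the (padded) input.
    """
    cs = plan.crop_size
    H, W = pair.truth.shape
    ph, pw = max(H, cs), max(W, cs)

    def pad(a: np.ndarray) -> np.ndarray:
        if (ph, pw) == (H, W):
            return a
        widths = ((0, ph - H), (0, pw - W)) + ((0, 0),) * (a.ndim - 2)
        return np.pad(a, widths)

    img, truth = pad(pair.image), pad(pair.truth)
    fov = None if pair.fov is None else pad(pair.fov)
    out = []
    for k in range(plan.n_crops):
        r = int(rng.integers(0, ph - cs + 1))
        c = int(rng.integers(0, pw - cs + 1))
        out.append(SamplePair(
            img[r : r + cs, c : c + cs].copy(),
            truth[r : r + cs, c : c + cs].copy(),
            None if fov is None else fov[r : r + cs, c : c + cs].copy(),
            id=f"{pair.id}/crop{k}",
        ))
    return out


def augment_dataset(pairs: list[SamplePair], plan: AugmentPlan) -> list[SamplePair]:
    """Run the rotate → mirror → shift → crop pipeline over a dataset.

    Each enabled stage expands the set (rotation ×⌊360/step⌋, mirroring ×2,
    shifting ×n_shifts, cropping ×n_crops); with every stage disabled the
    input is returned unchanged.  Deterministic given ``plan.seed``; the
    transform chain is recorded in each output id.
    """
    if not pairs:
        raise ValueError("empty input dataset")
    if not (plan.do_rotate or plan.do_mirror or plan.do_shift or plan.do_crop):
        return list(pairs)
    rng = np.random.default_rng(plan.seed)
    current = list(pairs)
    if plan.do_rotate:
        current = [r for p in current for r in rotations(p, plan.rotation_step_deg)]
    if plan.do_mirror:
        current = [x for p in current for x in (p, mirror(p, plan.mirror_axis))]
    if plan.do_shift:
        current = [random_shift(p, plan, rng) for p in current for _ in range(plan.n_shifts)]
    if plan.do_crop:
        current = [c for p in current for c in random_crops(p, plan, rng)]
    return current
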