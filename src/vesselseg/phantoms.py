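"""Synthetic fundus-style vessel phantoms with exact ground truth.

Real benchmark fundus photographs cannot ship with a library, so every stage
of the pipeline is exercised on phantoms that emulate the statistics the
method cares about: dark curvilinear vessel trees (widths of roughly 1–8 px,
tapering toward the periphery) on a smooth, vignetted background, with
additive Gaussian noise and 8-bit quantization, a circular field of view,
and a vessel pixel fraction near 12% of the frame — the prevalence of
manually traced vessels in standard retinal datasets.  Vessels are drawn
*darker* than the background, as they appear in the green channel of a
fundus photograph.

The ground-truth mask is the exact rasterization of the vessel tree (a pixel
is vessel iff its center lies within half the local width of the tree
centerline), captured before blurring, noise or quantization, so it is a
true oracle for the segmentation task.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io_datasets import SamplePair, write_mask
import imageio.v3 as iio

__all__ = ["PhantomSpec", "rasterize_tube", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise parameters of one phantom image.

    vessel_contrast is the background-minus-vessel intensity gap on the
    normalized [0, 1] scale, before noise; noise_sigma is the Gaussian noise
    standard deviation on the same scale.  target_vessel_fraction is the
    desired vessel share of *all* frame pixels; trees are added until it is
    reached (or a tree budget runs out, with a warning).
    """

    size: int = 128
    n_trees: int = 3
    branch_depth: int = 3
    width_range: tuple[float, float] = (1.0, 8.0)
    vessel_contrast: float = 0.25
    noise_sigma: float = 0.05
    vignette_strength: float = 0.3
    target_vessel_fraction: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if not 0 < self.width_range[0] <= self.width_range[1]:
            raise ValueError("width range must be positive and ordered")
        if not 0.0 < self.target_vessel_fraction < 0.5:
            raise ValueError("target_vessel_fraction must be in (0, 0.5)")
        if self.n_trees < 1 or self.branch_depth < 0:
            raise ValueError("n_trees >= 1 and branch_depth >= 0 required")


def rasterize_tube(
    shape: tuple[int, int], points: np.ndarray, widths: np.ndarray
) -> np.ndarray:
    """Exact binary raster of a variable-width polyline tube.

    A pixel (center at integer coordinates) is on iff its distance to some
    segment of the polyline is at most half the local width, the width being
    carried by the segment's start point.  Vectorized per segment over the
    segment's bounding box.
    """
    H, W = shape
    mask = np.zeros((H, W), dtype=bool)
    pts = np.asarray(points, dtype=np.float64)
    wid = np.broadcast_to(np.asarray(widths, dtype=np.float64), (len(pts),))
    if len(pts) == 1:
        segs = [(pts[0], pts[0], wid[0])]
    else:
        segs = [(pts[i], pts[i + 1], wid[i]) for i in range(len(pts) - 1)]
    for a, b, w in segs:
        r = w / 2.0
        lo = np.floor(np.minimum(a, b) - r).astype(int)
        hi = np.ceil(np.maximum(a, b) + r).astype(int)
        r0, c0 = np.maximum(lo, 0)
        r1, c1 = np.minimum(hi + 1, (H, W))
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        p = np.stack([yy, xx], axis=-1).astype(np.float64)
        d = b - a
        denom = float(d @ d)
        if denom == 0:
            dist = np.linalg.norm(p - a, axis=-1)
        else:
            t = np.clip(((p - a) @ d) / denom, 0.0, 1.0)
            proj = a + t[..., None] * d
            dist = np.linalg.norm(p - proj, axis=-1)
        mask[r0:r1, c0:c1] |= dist <= r
    return mask


def _grow_tree(
    rng: np.random.Generator,
    size: int,
    start: np.ndarray,
    heading: float,
    width: float,
    depth: int,
    min_width: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random-walk branch with tapering width; returns (points, widths) polylines."""
    step = max(size / 40.0, 2.0)
    n_steps = rng.integers(size // 8, size // 3)
    pts = [start.copy()]
    widths = [width]
    pos, ang, w = start.copy(), heading, width
    for _ in range(n_steps):
        ang += rng.normal(0.0, 0.25)  # gentle curvature
        pos = pos + step * np.array([np.sin(ang), np.cos(ang)])
        w = max(w * float(rng.uniform(0.93, 0.995)), min_width)
        pts.append(pos.copy())
        widths.append(w)
        if not (-size * 0.1 <= pos[0] <= size * 1.1 and -size * 0.1 <= pos[1] <= size * 1.1):
            break
    branches = [(np.array(pts), np.array(widths))]
    if depth > 0 and len(pts) > 3:
        k = rng.integers(1, 3)  # one or two children
        for _ in range(k):
            i = int(rng.integers(len(pts) // 3, len(pts) - 1))
            child_ang = ang + float(rng.choice([-1, 1])) * float(rng.uniform(0.4, 1.0))
            child_w = max(widths[i] * 0.7, min_width)
            branches += _grow_tree(rng, size, np.array(pts[i]), child_ang,
                                   child_w, depth - 1, min_width)
    return branches


def generate_phantom(spec: PhantomSpec) -> SamplePair:
    """Deterministically generate one phantom SamplePair from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    wmin, wmax = spec.width_range
    scale = n / 512.0  # width range is quoted at full fundus resolution
    wmin_px = max(wmin * max(scale, 0.25), 1.0)
    wmax_px = max(wmax * max(scale, 0.25), wmin_px)

    # field of view: centered disk, as in a fundus photograph
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = cx = (n - 1) / 2.0
    rad = np.hypot(yy - cy, xx - cx)
    fov = (rad <= 0.48 * n).astype(np.uint8)

    truth = np.zeros((n, n), dtype=bool)
    fovb = fov.astype(bool)
    target = spec.target_vessel_fraction
    max_trees = max(spec.n_trees, 60)
    trees = 0
    while trees < max_trees and (trees < spec.n_trees or (truth & fovb).mean() < target):
        ang0 = float(rng.uniform(0, 2 * np.pi))
        start = np.array([cy, cx]) + 0.44 * n * np.array([np.sin(ang0), np.cos(ang0)])
        heading = ang0 + np.pi + float(rng.normal(0, 0.4))  # point inward
        width = float(rng.uniform(0.6 * wmax_px, wmax_px))
        for pts, wid in _grow_tree(rng, n, start, heading, width,
                                   spec.branch_depth, wmin_px):
            truth |= rasterize_tube((n, n), pts, wid)
        trees += 1
    truth &= fovb
    achieved = float(truth.mean())
    if achieved < target * 0.5:
        warnings.warn(
            f"phantom seed {spec.seed}: achieved vessel fraction {achieved:.3f} "
            f"below target {target:.3f} within the tree budget"
        )

    # background: base level + smooth low-frequency field + radial vignette
    base = 0.62 + 0.05 * float(rng.uniform(-1, 1))
    lowfreq = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)), sigma=n / 6.0)
    lowfreq *= 0.08 / max(np.abs(lowfreq).max(), 1e-9)
    vignette = 1.0 - spec.vignette_strength * (rad / (0.5 * n)) ** 2
    background = (base + lowfreq) * vignette

    vessel_soft = ndimage.gaussian_filter(truth.astype(np.float64), sigma=0.6)
    vessel_soft /= max(vessel_soft.max(), 1e-9)
    img = background - spec.vessel_contrast * vessel_soft
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, (n, n))
    img = np.clip(img, 0.0, 1.0)
    img8 = np.round(img * 255.0).astype(np.uint8)
    rgb = np.stack([img8, img8, img8], axis=-1)
    return SamplePair(image=rgb, truth=truth.astype(np.uint8), fov=fov,
                      id=f"phantom{spec.seed:05d}")


def generate_dataset(
    spec: PhantomSpec, n_train: int, n_test: int, out_dir: str | Path
) -> dict:
    """Write a drive_like directory tree of phantoms and a JSON manifest.

    Sample ``i`` uses seed ``spec.seed + i`` (train first, then test), so any
    sample can be regenerated from the manifest alone.  Returns the manifest.
    """
    if n_train < 0 or n_test < 0:
        raise ValueError("n_train and n_test must be >= 0")
    out = Path(out_dir)
    manifest: dict = {"spec": {**asdict(spec), "width_range": list(spec.width_range)},
                      "splits": {}}
    i = 0
    for split, count in (("train", n_train), ("test", n_test)):
        root = out / split
        for sub in ("images", "truth", "fov"):
            (root / sub).mkdir(parents=True, exist_ok=True)
        seeds = []
        for _ in range(count):
            s = replace(spec, seed=spec.seed + i)
            pair = generate_phantom(s)
            iio.imwrite(root / "images" / f"{pair.id}.png", pair.image)
            write_mask(pair.truth, root / "truth" / f"{pair.id}.png")
            write_mask(pair.fov, root / "fov" / f"{pair.id}.png")
            seeds.append({"id": pair.id, "seed": s.seed})
            i += 1
        manifest["splits"][split] = seeds
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
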