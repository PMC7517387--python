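"""Green-channel extraction and contrast-limited adaptive histogram equalization.

Fundus photographs have low vessel/background contrast, and of the three RGB
channels the green one carries the most of it, so segmentation pipelines
conventionally work on the green channel alone.  CLAHE then equalizes the
histogram of each tile of a regular grid (8×8 tiles by default), but first
clips every histogram at a threshold

    T_clip = n_tile/L + α·(n_tile − n_tile/L)

where ``n_tile`` is the pixel count per tile, ``L`` the number of gray levels
(256) and ``α`` a normalized clipping coefficient (0.05 by default; α = 1
disables clipping).  The clipped excess is spread uniformly over the bins,
which bounds noise amplification in flat regions, and the per-tile
equalization mappings are blended bilinearly at each pixel so tile seams are
invisible.

Redistribution rule (single pass): with total excess N_tol = Σ max(h − T_clip, 0),
per-bin increment N_ace = N_tol/L and limit T_lim = T_clip − N_ace,

    h'(x) = T_clip           if h(x) > T_lim
            h(x) + N_ace     otherwise

Bins between T_lim and T_clip end at T_clip, slightly above h + N_ace; the
total count is conserved up to that slack, and no bin exceeds T_clip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClaheParams",
    "TileHistogram",
    "green_channel",
    "clip_threshold",
    "clip_and_redistribute",
    "tile_mapping",
    "clahe",
]


@dataclass(frozen=True)
class ClaheParams:
    """Tile grid, clipping coefficient and gray-level count for CLAHE."""

    grid_rows: int = 8
    grid_cols: int = 8
    clip_alpha: float = 0.05
    gray_levels: int = 256

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one tile per axis")
        if not 0.0 <= self.clip_alpha <= 1.0:
            raise ValueError("clip_alpha must be in [0, 1]")
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")


@dataclass
class TileHistogram:
    """Gray-level counts of one tile; float so redistribution stays exact."""

    counts: np.ndarray
    tile_origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 1:
            raise ValueError("histogram counts must be 1-D")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")


def green_channel(image: np.ndarray) -> np.ndarray:
    """Channel 1 (R=0, G=1, B=2) of an H×W×3 image, as uint8."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 image, got shape {img.shape}")
    return img[:, :, 1].astype(np.uint8)


def clip_threshold(n_tile: int, params: ClaheParams = ClaheParams()) -> float:
    """Clip threshold T_clip = n_tile/L + α·(n_tile − n_tile/L)."""
    if n_tile < 1:
        raise ValueError("n_tile must be >= 1")
    floor = n_tile / params.gray_levels
    return floor + params.clip_alpha * (n_tile - floor)


def clip_and_redistribute(
    hist: TileHistogram, params: ClaheParams = ClaheParams()
) -> TileHistogram:
    """Clip a tile histogram at T_clip and spread the excess uniformly."""
    h = hist.counts
    n_tile = int(round(h.sum()))
    if n_tile < 1:
        return TileHistogram(h.copy(), hist.tile_origin)
    t_clip = clip_threshold(n_tile, params)
    n_tol = np.maximum(h - t_clip, 0.0).sum()
    n_ace = n_tol / params.gray_levels
    t_lim = t_clip - n_ace
    out = np.where(h > t_lim, t_clip, h + n_ace)
    return TileHistogram(out, hist.tile_origin)


def tile_mapping(hist: TileHistogram, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """Equalization lookup table (length L) from a clipped tile histogram.

    The mapping is the normalized cumulative distribution scaled to
    [0, L−1]; it is monotone non-decreasing by construction.  A degenerate
    tile whose raw histogram occupies a single gray level maps identically,
    which makes the whole transform idempotent on constant images.
    """
    raw = hist.counts
    L = params.gray_levels
    if np.count_nonzero(raw) <= 1:
        return np.arange(L, dtype=np.float64)
    clipped = clip_and_redistribute(hist, params).counts
    cdf = np.cumsum(clipped)
    total = cdf[-1]
    if total <= 0:
        return np.arange(L, dtype=np.float64)
    return np.floor(cdf / total * (L - 1) + 0.5)


def _as_levels(image: np.ndarray, L: int) -> tuple[np.ndarray, str]:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img.astype(np.intp), "uint8"
    if np.issubdtype(img.dtype, np.floating):
        if img.min() < 0 or img.max() > 1:
            raise ValueError("float gray images must lie in [0, 1]")
        return np.clip(np.round(img * (L - 1)), 0, L - 1).astype(np.intp), "float"
    raise ValueError(f"unsupported gray image dtype {img.dtype}")


def clahe(image: np.ndarray, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Accepts uint8 (levels 0..255) or float-in-[0,1] gray images and returns
    the same dtype/domain.  Images whose sides are not divisible by the tile
    grid are reflect-padded to the next multiple, processed, and cropped
    back.  Pixel values are reconstructed by bilinear interpolation between
    the mappings of the four surrounding tile centers, with clamped
    (duplicated) mappings beyond the border tiles.
    """
    levels, domain = _as_levels(image, params.gray_levels)
    H, W = levels.shape
    gr, gc = params.grid_rows, params.grid_cols
    if H < gr or W < gc:
        raise ValueError(f"image {H}×{W} smaller than the {gr}×{gc} tile grid")
    th = -(-H // gr)  # tile height after padding
    tw = -(-W // gc)
    Hp, Wp = th * gr, tw * gc
    if (Hp, Wp) != (H, W):
        padded = np.pad(levels, ((0, Hp - H), (0, Wp - W)), mode="reflect")
    else:
        padded = levels
    L = params.gray_levels

    maps = np.empty((gr, gc, L), dtype=np.float64)
    for i in range(gr):
        for j in range(gc):
            tile = padded[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            hist = TileHistogram(np.bincount(tile.ravel(), minlength=L)[:L],
                                 (i * th, j * tw))
            maps[i, j] = tile_mapping(hist, params)

    # bilinear blend between the four nearest tile-center mappings
    rows = np.arange(Hp, dtype=np.float64)
    cols = np.arange(Wp, dtype=np.float64)
    fr = (rows - (th - 1) / 2.0) / th  # fractional tile coordinate
    fc = (cols - (tw - 1) / 2.0) / tw
    r0 = np.clip(np.floor(fr).astype(int), 0, gr - 1)
    r1 = np.clip(r0 + 1, 0, gr - 1)
    wr = np.clip(fr - np.floor(fr), 0.0, 1.0)
    wr[fr < 0] = 0.0
    wr[fr > gr - 1] = 1.0
    c0 = np.clip(np.floor(fc).astype(int), 0, gc - 1)
    c1 = np.clip(c0 + 1, 0, gc - 1)
    wc = np.clip(fc - np.floor(fc), 0.0, 1.0)
    wc[fc < 0] = 0.0
    wc[fc > gc - 1] = 1.0

    R0 = r0[:, None]
    R1 = r1[:, None]
    C0 = c0[None, :]
    C1 = c1[None, :]
    WR = wr[:, None]
    WC = wc[None, :]
    v00 = maps[R0, C0, padded]
    v01 = maps[R0, C1, padded]
    v10 = maps[R1, C0, padded]
    v11 = maps[R1, C1, padded]
    out = ((1 - WR) * (1 - WC) * v00 + (1 - WR) * WC * v01
           + WR * (1 - WC) * v10 + WR * WC * v11)
    out = out[:H, :W]
    if domain == "uint8":
        return np.clip(np.round(out), 0, L - 1).astype(np.uint8)
    return np.clip(out / (L - 1), 0.0, 1.0)
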