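"""Contrast preprocessing that suppresses FOA imaging artifacts.

The fiber-optic-array micrograph carries two nuisances that defeat plain
smoothing: a periodic core/gap lattice at roughly the cell-contour
spatial scale, and a smooth illumination field that is darker at the
center than at the edges. Both are local-contrast problems, so the
pipeline here is local histogram equalization:

1. convert the input to L*a*b* and rescale the L channel to [0, 1],
2. run contrast-limited adaptive histogram equalization (CLAHE) on L —
   per-tile histograms clipped at a contrast limit, excess mass spread
   uniformly over the bins, per-tile CDF mappings blended bilinearly,
3. convert back to RGB and finally to a single gray channel for the
   scan-window detector.

A per-pixel moving-template equalizer (classic AHE: the center pixel of
a sliding window takes the window-equalized value) is provided as the
slow, exact reference that CLAHE approximates.

All images use the [0, 1] working scale; :class:`GrayImage` records the
original bit depth for round trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

from .errors import ParameterError

__all__ = [
    "GrayImage",
    "ClaheParams",
    "EqualizationTemplate",
    "to_grayscale",
    "rgb_to_lab",
    "lab_to_rgb",
    "clahe",
    "moving_window_equalize",
    "preprocess_pipeline",
    "mean_filter_demo",
]

#: BT.601 luma weights used for every RGB -> gray reduction.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class GrayImage:
    """Single-channel image on the [0, 1] working scale."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ParameterError("GrayImage requires a 2-D raster")
        if self.pixels.size and (
            self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9
        ):
            raise ParameterError("GrayImage values must lie in [0, 1]")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.pixels, dtype=dtype)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_uint8(self) -> np.ndarray:
        return np.round(self.pixels * 255.0).astype(np.uint8)


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE tuning: tile grid, clip limit, histogram bins.

    ``clip_limit`` is the per-bin ceiling expressed as a fraction of the
    tile pixel count, on the conventional 0.01-1 scale: 1 disables
    clipping (plain tile-wise equalization), small values cap the local
    contrast gain. The defaults — a 25x25 tile grid and a clip limit of
    0.1 — are the ones effective on FOA yeast micrographs.
    """

    num_tiles: tuple[int, int] = (25, 25)
    clip_limit: float = 0.1
    n_bins: int = 256
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        tr, tc = self.num_tiles
        if tr < 1 or tc < 1:
            raise ParameterError("num_tiles must be at least (1, 1)")
        if not (0.01 <= self.clip_limit <= 1.0):
            raise ParameterError("clip_limit must lie in [0.01, 1]")
        if self.n_bins < 1:
            raise ParameterError("n_bins must be positive")
        if self.distribution != "uniform":
            raise ParameterError("only the uniform distribution is supported")


@dataclass(frozen=True)
class EqualizationTemplate:
    """Sliding window of the per-pixel (moving-template) equalizer.

    Dimensions must be odd so the center pixel c(x0, y0) — the one that
    receives the window-equalized value — is well defined.
    """

    height: int = 25
    width: int = 25
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ParameterError("window dimensions must be positive")
        if self.height % 2 == 0 or self.width % 2 == 0:
            raise ParameterError("window dimensions must be odd")
        if self.n_bins < 1:
            raise ParameterError("n_bins must be positive")


def _as_float01(img) -> np.ndarray:
    a = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if a.dtype == np.uint8:
        a = a.astype(np.float64) / 255.0
    elif a.dtype == np.uint16:
        a = a.astype(np.float64) / 65535.0
    else:
        a = a.astype(np.float64)
    return a


def to_grayscale(rgb) -> GrayImage:
    """Reduce a 3-channel image to gray with fixed BT.601 luma weights.

    8-bit input is rounded back to 8 bits after the weighted sum (the
    gray image a camera pipeline would store) and then rescaled to
    [0, 1]; floating input keeps full precision.
    """
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ParameterError("to_grayscale expects an H x W x 3 raster")
    was_uint8 = arr.dtype == np.uint8
    a = _as_float01(arr)
    gray = a @ np.asarray(LUMA_WEIGHTS)
    if was_uint8:
        gray = np.round(gray * 255.0) / 255.0
    return GrayImage(np.clip(gray, 0.0, 1.0))


def rgb_to_lab(rgb) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """sRGB (D65) to L*a*b*; returns the three channel rasters."""
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ParameterError("rgb_to_lab expects an H x W x 3 raster")
    a = _as_float01(arr)
    if a.min() < -1e-9 or a.max() > 1 + 1e-9:
        raise ParameterError("RGB values must lie in [0, 1] (or be 8/16-bit)")
    lab = _skcolor.rgb2lab(a)
    return lab[..., 0], lab[..., 1], lab[..., 2]


def lab_to_rgb(L, a, b) -> np.ndarray:
    """L*a*b* back to sRGB on the [0, 1] scale, gamut-clipped."""
    lab = np.stack([np.asarray(L, float), np.asarray(a, float),
                    np.asarray(b, float)], axis=-1)
    if lab[..., 0].min() < -1e-6 or lab[..., 0].max() > 100 + 1e-6:
        raise ParameterError("L* must lie in [0, 100]")
    return np.clip(_skcolor.lab2rgb(lab), 0.0, 1.0)


def _tile_edges(n: int, tiles: int) -> np.ndarray:
    # Evenly sized integer partition of n rows/cols into `tiles` tiles.
    return np.round(np.linspace(0, n, tiles + 1)).astype(int)


def _clipped_cdf(binned_tile: np.ndarray, n_bins: int, clip_limit: float) -> np.ndarray:
    n = binned_tile.size
    hist = np.bincount(binned_tile.ravel(), minlength=n_bins).astype(np.float64)
    ceiling = clip_limit * n
    excess = np.maximum(hist - ceiling, 0.0).sum()
    hist = np.minimum(hist, ceiling) + excess / n_bins
    return np.cumsum(hist) / n


def clahe(img, params: ClaheParams = ClaheParams()) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    The image is partitioned into ``num_tiles`` contextual regions; each
    region's histogram is clipped at ``clip_limit`` times its pixel
    count, the clipped excess is redistributed uniformly over the bins
    (one pass), and the region's CDF becomes its gray-level mapping.
    Every pixel is then mapped by bilinear interpolation between the four
    surrounding tile mappings; pixels beyond the outermost tile centers
    fall back to the nearest tile mapping. Output values lie in (0, 1]
    and are monotone non-decreasing in the input within any fixed blend
    of tiles.
    """
    a = _as_float01(img)
    if a.ndim != 2:
        raise ParameterError("clahe expects a 2-D raster")
    rows, cols = a.shape
    tr, tc = params.num_tiles
    if rows < tr or cols < tc:
        raise ParameterError(
            f"image {rows}x{cols} smaller than the {tr}x{tc} tile grid"
        )
    n_bins = params.n_bins
    binned = np.minimum((a * n_bins).astype(np.int64), n_bins - 1)
    binned = np.maximum(binned, 0)

    r_edges = _tile_edges(rows, tr)
    c_edges = _tile_edges(cols, tc)
    maps = np.empty((tr, tc, n_bins), dtype=np.float64)
    for i in range(tr):
        for j in range(tc):
            tile = binned[r_edges[i]: r_edges[i + 1], c_edges[j]: c_edges[j + 1]]
            maps[i, j] = _clipped_cdf(tile, n_bins, params.clip_limit)

    # Tile centers in pixel coordinates; pixels interpolate between the
    # two bracketing centers per axis, clamped at the borders.
    r_centers = (r_edges[:-1] + r_edges[1:] - 1) / 2.0
    c_centers = (c_edges[:-1] + c_edges[1:] - 1) / 2.0

    def _axis_blend(n: int, centers: np.ndarray):
        pos = np.arange(n, dtype=np.float64)
        hi = np.searchsorted(centers, pos)
        lo = np.clip(hi - 1, 0, len(centers) - 1)
        hi = np.clip(hi, 0, len(centers) - 1)
        span = centers[hi] - centers[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(span > 0, (pos - centers[lo]) / np.where(span == 0, 1, span), 0.0)
        return lo, hi, np.clip(w, 0.0, 1.0)

    rlo, rhi, wr = _axis_blend(rows, r_centers)
    clo, chi, wc = _axis_blend(cols, c_centers)

    RL, RH = rlo[:, None], rhi[:, None]
    CL, CH = clo[None, :], chi[None, :]
    WR, WC = wr[:, None], wc[None, :]
    out = (
        (1 - WR) * (1 - WC) * maps[RL, CL, binned]
        + (1 - WR) * WC * maps[RL, CH, binned]
        + WR * (1 - WC) * maps[RH, CL, binned]
        + WR * WC * maps[RH, CH, binned]
    )
    return GrayImage(np.clip(out, 0.0, 1.0))


def moving_window_equalize(
    img, template: EqualizationTemplate = EqualizationTemplate()
) -> GrayImage:
    """Per-pixel adaptive histogram equalization (the moving-template form).

    For every pixel, the histogram of its surrounding ``height x width``
    window (edge-replicated at the borders) is equalized over the full
    gray range and the transformed value is assigned to the window's
    center pixel. This is the exact-but-slow reference that tiled CLAHE
    with ``clip_limit=1`` approximates; quadratic in the window area, so
    intended for small images and tests.
    """
    a = _as_float01(img)
    if a.ndim != 2:
        raise ParameterError("moving_window_equalize expects a 2-D raster")
    h, w = template.height, template.width
    n_bins = template.n_bins
    binned = np.minimum((a * n_bins).astype(np.int64), n_bins - 1)
    binned = np.maximum(binned, 0)
    pad = np.pad(binned, ((h // 2, h // 2), (w // 2, w // 2)), mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(pad, (h, w))
    # g(x0,y0) = CDF of the window histogram evaluated at the center bin.
    out = (windows <= binned[..., None, None]).mean(axis=(2, 3))
    return GrayImage(out)


def preprocess_pipeline(
    rgb,
    params: ClaheParams = ClaheParams(),
    return_intermediates: bool = False,
):
    """Full artifact-suppression pipeline on a color micrograph.

    Steps: RGB -> L*a*b*; L scaled to [0, 1]; CLAHE on L; L rescaled;
    back to RGB; finally the BT.601 gray reduction used by the
    scan-window detector. Gray input may be passed as replicated RGB;
    on the neutral axis the pipeline collapses to CLAHE on the gray
    channel up to quantization.

    Returns the final :class:`GrayImage`, plus a dict of intermediates
    (``lab_l``, ``clahe_l``, ``rgb_out``) when ``return_intermediates``.
    """
    arr = np.asarray(rgb)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    L, A, B = rgb_to_lab(arr)
    L01 = np.clip(L / 100.0, 0.0, 1.0)
    Lc = clahe(L01, params).pixels
    rgb_out = lab_to_rgb(Lc * 100.0, A, B)
    gray = to_grayscale(rgb_out)
    if return_intermediates:
        return gray, {"lab_l": L01, "clahe_l": Lc, "rgb_out": rgb_out}
    return gray


def mean_filter_demo(img, radius: int = 5) -> GrayImage:
    """Plain mean filter, kept only to demonstrate why smoothing fails.

    Averaging at the fiber-gap scale blurs cell contours and core gaps
    alike; it is not part of the pipeline.
    """
    from scipy import ndimage

    a = _as_float01(img)
    size = 2 * int(radius) + 1
    return GrayImage(np.clip(ndimage.uniform_filter(a, size=size), 0.0, 1.0))
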