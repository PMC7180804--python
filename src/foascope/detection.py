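"""Hexagonal scan-window scoring and peak retention for yeast cells.

After preprocessing, live cells present a bright interior surrounded by
a dark rim, while dead (stained) cells are uniformly darker than the
background. Detection therefore slides a fixed hexagonal window — shaped
like the fiber-core packing — over the image and computes two region
statistics at every position:

* live score: mean gray over the hexagon interior minus mean gray over
  its edge ring (large at a live-cell center),
* dead score: mean gray over the whole hexagon (small at a dead cell).

Candidate cells are local score extrema passing a threshold, thinned by
greedy non-maximum suppression with an explicit radius. Region sums are
normalized to means so thresholds do not depend on the window size.

Coordinates follow the package convention: row-major, 0-based, ``x`` is
the column and ``y`` the row; window offsets are (dy, dx) relative to
the window center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .preprocess import GrayImage, _as_float01

__all__ = [
    "ScanWindowMask",
    "ScoreMap",
    "DetectionSet",
    "make_hex_window",
    "score_live",
    "score_dead",
    "select_peaks",
    "detect_cells",
    "detections_to_mask",
]


@dataclass(frozen=True)
class ScanWindowMask:
    """Rasterized flat-topped regular hexagon split into edge ring and interior.

    ``edge_ring`` holds the (dy, dx) offsets within ``ring_thickness`` of
    the hexagon boundary, ``interior`` the remaining hexagon pixels; the
    two sets are disjoint and their union is the full hexagon raster.
    The mask is symmetric under 180-degree rotation.
    """

    circumradius_px: float
    ring_thickness: int
    edge_ring: np.ndarray = field(repr=False)
    interior: np.ndarray = field(repr=False)

    @property
    def all_offsets(self) -> np.ndarray:
        return np.concatenate([self.edge_ring, self.interior], axis=0)

    @property
    def half_extent(self) -> tuple[int, int]:
        """(max |dy|, max |dx|) over all offsets."""
        offs = self.all_offsets
        return int(np.abs(offs[:, 0]).max()), int(np.abs(offs[:, 1]).max())


def _hex_inner_distance(dy: np.ndarray, dx: np.ndarray, R: float) -> np.ndarray:
    # Distance from a point to the boundary of a flat-topped regular
    # hexagon of circumradius R centered at the origin; positive inside.
    # The three edge-line families give the support function
    # h = max(|y|, |sqrt(3) x + y| / 2, |sqrt(3) x - y| / 2); the apothem
    # is sqrt(3) R / 2.
    s3 = math.sqrt(3.0)
    h = np.maximum.reduce([
        np.abs(dy),
        np.abs(s3 * dx + dy) / 2.0,
        np.abs(s3 * dx - dy) / 2.0,
    ])
    return s3 * R / 2.0 - h


def make_hex_window(circumradius_px: float, ring_thickness: int = 2) -> ScanWindowMask:
    """Build the hexagonal scan window.

    Offsets are exactly the pixels whose centers lie inside (or on the
    boundary of) a flat-topped regular hexagon of the given circumradius;
    the edge ring is the band within ``ring_thickness`` of the boundary.
    """
    if circumradius_px < 2:
        raise ParameterError("circumradius must be at least 2 px")
    if ring_thickness < 1 or int(ring_thickness) != ring_thickness:
        raise ParameterError("ring_thickness must be a positive integer")
    K = int(math.ceil(circumradius_px))
    dy, dx = np.meshgrid(np.arange(-K, K + 1), np.arange(-K, K + 1), indexing="ij")
    d = _hex_inner_distance(dy.astype(float), dx.astype(float), circumradius_px)
    inside = d >= 0
    ring = inside & (d < ring_thickness)
    interior = inside & (d >= ring_thickness)
    if not interior.any():
        raise ParameterError(
            "circumradius too small for the requested ring thickness: "
            "empty interior"
        )
    ring_offs = np.column_stack([dy[ring], dx[ring]])
    int_offs = np.column_stack([dy[interior], dx[interior]])
    return ScanWindowMask(
        circumradius_px=float(circumradius_px),
        ring_thickness=int(ring_thickness),
        edge_ring=ring_offs,
        interior=int_offs,
    )


@dataclass
class ScoreMap:
    """Per-pixel detector response; NaN where the window does not fit."""

    scores: np.ndarray
    mode: str
    window: ScanWindowMask

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.scores)


def _region_mean(a: np.ndarray, offsets: np.ndarray, extent) -> np.ndarray:
    ky, kx = extent
    kernel = np.zeros((2 * ky + 1, 2 * kx + 1))
    kernel[offsets[:, 0] + ky, offsets[:, 1] + kx] = 1.0 / len(offsets)
    return ndimage.correlate(a, kernel, mode="constant", cval=0.0)


def _invalidate_border(s: np.ndarray, extent) -> np.ndarray:
    ky, kx = extent
    out = s.copy()
    out[:ky, :] = np.nan
    out[s.shape[0] - ky:, :] = np.nan
    out[:, :kx] = np.nan
    out[:, s.shape[1] - kx:] = np.nan
    return out


def _check_fits(a: np.ndarray, w: ScanWindowMask) -> None:
    ky, kx = w.half_extent
    if a.shape[0] < 2 * ky + 1 or a.shape[1] < 2 * kx + 1:
        raise ParameterError("scan window larger than the image")


def score_live(img, w: ScanWindowMask) -> ScoreMap:
    """Interior-minus-ring contrast map; live cells are maxima.

    ``score = mean(interior) - mean(edge ring)``: large where a bright
    cell interior sits inside a dark rim. Invariant under adding a
    constant to the whole image. Border positions where the window
    does not fit are NaN.
    """
    a = _as_float01(img)
    _check_fits(a, w)
    ext = w.half_extent
    s = _region_mean(a, w.interior, ext) - _region_mean(a, w.edge_ring, ext)
    return ScoreMap(_invalidate_border(s, ext), "live", w)


def score_dead(img, w: ScanWindowMask) -> ScoreMap:
    """Mean gray over the whole hexagon; dead (stained) cells are minima."""
    a = _as_float01(img)
    _check_fits(a, w)
    ext = w.half_extent
    s = _region_mean(a, w.all_offsets, ext)
    return ScoreMap(_invalidate_border(s, ext), "dead", w)


@dataclass
class DetectionSet:
    """Retained cell candidates: positions, scores and class labels."""

    x: np.ndarray
    y: np.ndarray
    score: np.ndarray
    label: np.ndarray

    @classmethod
    def empty(cls) -> "DetectionSet":
        z = np.empty(0)
        return cls(z.copy(), z.copy(), z.copy(), np.empty(0, dtype=object))

    @classmethod
    def from_records(cls, records, label: str | None = None) -> "DetectionSet":
        if not records:
            return cls.empty()
        x, y, s = (np.asarray(v, float) for v in zip(*[(r[0], r[1], r[2]) for r in records]))
        labels = np.array(
            [label if label is not None else r[3] for r in records], dtype=object
        )
        return cls(x, y, s, labels)

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "y": self.y, "score": self.score, "label": self.label}
        )

    def subset(self, mask: np.ndarray) -> "DetectionSet":
        return DetectionSet(self.x[mask], self.y[mask], self.score[mask],
                            self.label[mask])


def select_peaks(
    smap: ScoreMap,
    polarity: str,
    threshold: float,
    nms_radius_px: float,
) -> DetectionSet:
    """Retain thresholded local extrema, thinned by greedy NMS.

    Local extrema of the stated polarity that strictly exceed (``max``)
    or fall strictly below (``min``) the threshold are visited from most
    extreme to least; a candidate within ``nms_radius_px`` (Euclidean)
    of an already retained one is suppressed. Ties are broken by lower
    row, then lower column, so the result is deterministic. Retained
    detections are pairwise at least ``nms_radius_px`` apart.
    """
    if polarity not in ("max", "min"):
        raise ParameterError("polarity must be 'max' or 'min'")
    if nms_radius_px <= 0:
        raise ParameterError("nms_radius_px must be positive")
    s = smap.scores if polarity == "max" else -smap.scores
    th = threshold if polarity == "max" else -threshold
    filled = np.where(np.isnan(s), -np.inf, s)
    is_peak = filled == ndimage.maximum_filter(filled, size=3, mode="constant",
                                               cval=-np.inf)
    cand = is_peak & ~np.isnan(s) & (filled > th)
    ys, xs = np.nonzero(cand)
    if len(ys) == 0:
        return DetectionSet.empty()
    vals = filled[ys, xs]
    order = np.lexsort((xs, ys, -vals))
    kept_y: list[int] = []
    kept_x: list[int] = []
    kept_s: list[float] = []
    r2 = nms_radius_px**2
    for idx in order:
        cy, cx = int(ys[idx]), int(xs[idx])
        ok = True
        for py, px in zip(kept_y, kept_x):
            if (cy - py) ** 2 + (cx - px) ** 2 < r2:
                ok = False
                break
        if ok:
            kept_y.append(cy)
            kept_x.append(cx)
            kept_s.append(float(smap.scores[cy, cx]))
    return DetectionSet(
        x=np.array(kept_x, float),
        y=np.array(kept_y, float),
        score=np.array(kept_s, float),
        label=np.array([smap.mode] * len(kept_x), dtype=object),
    )


def detect_cells(
    img,
    window: ScanWindowMask,
    live_threshold: float,
    dead_threshold: float,
    nms_radius: float,
    return_masks: bool = False,
):
    """Run both scan windows and return (live, dead) detection sets.

    Live candidates are score-map maxima above ``live_threshold``; dead
    candidates are mean-gray minima below ``dead_threshold``. When a
    live and a dead detection fall within ``nms_radius`` of each other
    the one with the larger margin beyond its own threshold survives
    (both margins are in mean-gray units, so they are comparable).
    With ``return_masks`` the binary candidate rasters (one marked pixel
    per retained detection) are returned as well.
    """
    a = _as_float01(img)
    live = select_peaks(score_live(a, window), "max", live_threshold, nms_radius)
    dead = select_peaks(score_dead(a, window), "min", dead_threshold, nms_radius)

    if len(live) and len(dead):
        live_margin = live.score - live_threshold
        dead_margin = dead_threshold - dead.score
        entries = (
            [("live", i, live_margin[i], live.y[i], live.x[i]) for i in range(len(live))]
            + [("dead", i, dead_margin[i], dead.y[i], dead.x[i]) for i in range(len(dead))]
        )
        entries.sort(key=lambda e: (-e[2], e[3], e[4]))
        kept: list[tuple[str, int]] = []
        kept_pos: list[tuple[str, float, float]] = []
        r2 = nms_radius**2
        for lab, i, _, cy, cx in entries:
            conflict = any(
                plab != lab and (cy - py) ** 2 + (cx - px) ** 2 < r2
                for plab, py, px in kept_pos
            )
            if not conflict:
                kept.append((lab, i))
                kept_pos.append((lab, cy, cx))
        live_keep = np.zeros(len(live), bool)
        dead_keep = np.zeros(len(dead), bool)
        for lab, i in kept:
            (live_keep if lab == "live" else dead_keep)[i] = True
        live = live.subset(live_keep)
        dead = dead.subset(dead_keep)

    if return_masks:
        shape = a.shape
        return live, dead, (
            detections_to_mask(live, shape),
            detections_to_mask(dead, shape),
        )
    return live, dead


def detections_to_mask(det: DetectionSet, shape, dot_radius: int = 1) -> np.ndarray:
    """Paint detections as small disks into a binary candidate raster.

    The default 1-px dot radius yields 5-pixel particles, comfortably
    above the 2-pixel minimum of the particle counter.
    """
    mask = np.zeros(shape, dtype=bool)
    rows, cols = shape
    rr = int(dot_radius)
    for cx, cy in zip(det.x, det.y):
        cy_i, cx_i = int(round(cy)), int(round(cx))
        for dy in range(-rr, rr + 1):
            for dx in range(-rr, rr + 1):
                if dy * dy + dx * dx <= rr * rr:
                    py, px = cy_i + dy, cx_i + dx
                    if 0 <= py < rows and 0 <= px < cols:
                        mask[py, px] = True
    return mask
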