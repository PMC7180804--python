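"""Counting, ground-truth matching, identification rates, cross-validation.

Detected candidates are counted with the minimum-size particle rule of
an ImageJ-style "Analyze Particles" pass (connected components of at
least 2 px, no upper bound), matched one-to-one to ground-truth cells of
the same viability label, and summarized as identification percentages
with cell clusters excluded from the denominator — the same protocol as
comparing automated counts against a manual count. k-fold
cross-validation selects the detection thresholds on training folds and
reports held-out identification and false-detection rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .detection import DetectionSet, make_hex_window, score_dead, score_live, select_peaks
from .errors import ParameterError, UndefinedRateError
from .preprocess import ClaheParams, clahe
from .synthetic import CellGT, SyntheticScene

__all__ = [
    "CountResult",
    "MatchResult",
    "CVResult",
    "count_particles",
    "match_detections",
    "identification_rate",
    "flag_clusters",
    "kfold_evaluate",
    "evaluate_scene",
    "run_default_benchmark",
]


@dataclass
class CountResult:
    """Particle counts and centroids from one binary candidate mask."""

    count: int
    centroids: list[tuple[float, float]]  # (y, x)


@dataclass
class MatchResult:
    """One-to-one detection/ground-truth correspondence for one class."""

    matched: list[tuple[int, int]]  # (detection index, gt index)
    misses: list[int]  # unmatched gt indices
    false_detections: list[int]  # unmatched detection indices
    excluded: list[int]  # cluster gt indices left out of the denominator

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def n_gt_counted(self) -> int:
        return len(self.matched) + len(self.misses)


@dataclass
class CVResult:
    """Per-fold and fold-mean identification/false-detection percentages."""

    live_rates: list[float]
    dead_rates: list[float]
    live_false_rates: list[float]
    dead_false_rates: list[float]
    live_thresholds: list[float]
    dead_thresholds: list[float]
    fold_assignment: list[list[int]] = field(default_factory=list)

    @property
    def mean_live_rate(self) -> float:
        return float(np.mean(self.live_rates))

    @property
    def mean_dead_rate(self) -> float:
        return float(np.mean(self.dead_rates))

    @property
    def mean_live_false_rate(self) -> float:
        return float(np.mean(self.live_false_rates))

    @property
    def mean_dead_false_rate(self) -> float:
        return float(np.mean(self.dead_false_rates))


def run_default_benchmark(
    n_scenes: int = 20, seed: int = 0, k: int = 5,
    config: PipelineConfig | None = None,
) -> CVResult:
    """Render the standard synthetic benchmark and cross-validate on it.

    ``n_scenes`` scenes are generated under the package's default study
    conditions (no deliberate clusters, low noise) with seeds
    ``seed + i``, then scored by :func:`kfold_evaluate` with the fold
    shuffle seeded by ``seed``. Unless a config is given, the CLAHE
    tile grid is rescaled to the scene size so one tile keeps the same
    extent in cell diameters as on full-resolution device micrographs
    (see :func:`foascope.config.tile_grid_for_shape`).
    """
    from .config import tile_grid_for_shape
    from .synthetic import DEFAULT_POPULATION, DEFAULT_SHAPE, default_scene

    scenes = [default_scene(seed=seed + i) for i in range(n_scenes)]
    if config is None:
        lo, hi = DEFAULT_POPULATION.radius_px_range
        tr, tc = tile_grid_for_shape(DEFAULT_SHAPE, cell_diameter_px=lo + hi)
        config = PipelineConfig(num_tiles_rows=tr, num_tiles_cols=tc)
    return kfold_evaluate(scenes, k=k, seed=seed, config=config)


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def count_particles(
    mask: np.ndarray, min_area_px: int = 2, connectivity: int = 8
) -> CountResult:
    """Count connected foreground components of at least ``min_area_px``.

    The minimum-size rule discards isolated noise specks: a bright blob
    of two or more pixels counts as a cell, with no upper size limit.
    Connectivity is 4 or 8 (8 by default, the usual particle-analysis
    convention); each counted component contributes its centroid.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ParameterError("count_particles expects a 2-D raster")
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ParameterError("mask must be binary (bool or 0/1)")
        arr = arr.astype(bool)
    if connectivity not in _STRUCTURES:
        raise ParameterError("connectivity must be 4 or 8")
    if min_area_px < 1:
        raise ParameterError("min_area_px must be positive")
    labels, n = ndimage.label(arr, structure=_STRUCTURES[connectivity])
    if n == 0:
        return CountResult(0, [])
    areas = np.bincount(labels.ravel())[1:]
    keep = np.nonzero(areas >= min_area_px)[0] + 1
    centroids = ndimage.center_of_mass(arr, labels, keep.tolist())
    return CountResult(len(keep), [(float(cy), float(cx)) for cy, cx in centroids])


def flag_clusters(gt: list[CellGT], min_sep_px: float) -> set[int]:
    """Indices of ground-truth cells with any neighbor closer than ``min_sep_px``.

    Symmetric and label-blind: both members of a close pair are flagged.
    These cells form visual clusters the scan-window detector is not
    asked to resolve, so they are excluded from rate denominators.
    """
    if min_sep_px <= 0:
        raise ParameterError("min_sep_px must be positive")
    flagged: set[int] = set()
    for i in range(len(gt)):
        for j in range(i + 1, len(gt)):
            if math.hypot(gt[i].x - gt[j].x, gt[i].y - gt[j].y) < min_sep_px:
                flagged.add(i)
                flagged.add(j)
    return flagged


def match_detections(
    det: DetectionSet,
    gt: list[CellGT],
    max_dist_px: float,
    label: str | None = None,
    exclude_clusters: bool = True,
    cluster_sep_px: float | None = None,
) -> MatchResult:
    """Greedy one-to-one matching of detections to ground truth.

    Same-label pairs within ``max_dist_px`` are matched in order of
    increasing distance, each detection and each ground-truth cell used
    at most once. Leftover detections are false detections — except
    those that sit within ``max_dist_px`` of an excluded cluster cell,
    which are ignored outright (the cluster protocol removes those cells
    from both numerator and denominator). Leftover ground truth are
    misses. When ``label`` is given only that class of ground truth is
    considered.
    """
    if max_dist_px <= 0:
        raise ParameterError("max_dist_px must be positive")
    gt_idx = [
        i for i, c in enumerate(gt) if label is None or c.label == label
    ]
    excluded: list[int] = []
    if exclude_clusters:
        if cluster_sep_px is not None:
            flagged = flag_clusters(gt, cluster_sep_px)
        else:
            flagged = {i for i, c in enumerate(gt) if c.cluster_member}
        excluded = [i for i in gt_idx if i in flagged]
        gt_idx = [i for i in gt_idx if i not in flagged]

    pairs = []
    for d in range(len(det)):
        if label is not None and det.label[d] != label:
            continue
        for gi in gt_idx:
            dist = math.hypot(det.x[d] - gt[gi].x, det.y[d] - gt[gi].y)
            if dist <= max_dist_px:
                pairs.append((dist, d, gi))
    pairs.sort()
    used_det: set[int] = set()
    used_gt: set[int] = set()
    matched: list[tuple[int, int]] = []
    for dist, d, gi in pairs:
        if d in used_det or gi in used_gt:
            continue
        matched.append((d, gi))
        used_det.add(d)
        used_gt.add(gi)

    det_indices = [
        d for d in range(len(det))
        if (label is None or det.label[d] == label) and d not in used_det
    ]
    # A detection on an excluded cluster cell is neither a hit nor a miss.
    false_dets = []
    for d in det_indices:
        near_cluster = any(
            math.hypot(det.x[d] - gt[e].x, det.y[d] - gt[e].y) <= max_dist_px
            for e in excluded
        )
        if not near_cluster:
            false_dets.append(d)
    misses = [gi for gi in gt_idx if gi not in used_gt]
    return MatchResult(matched, misses, false_dets, excluded)


def identification_rate(n_detected_matched: int, n_gt: int) -> float:
    """Identification percentage, 100 * matched / ground truth, to one decimal.

    This is the figure used when comparing automated counts against a
    manual count of the same image set.
    """
    if n_gt <= 0:
        raise UndefinedRateError("identification rate undefined for zero cells")
    if not (0 <= n_detected_matched <= n_gt):
        raise ParameterError("matched count must lie between 0 and the gt count")
    return round(100.0 * n_detected_matched / n_gt, 1)


def _scene_maps(scene: SyntheticScene, cfg: PipelineConfig):
    params = ClaheParams(num_tiles=cfg.num_tiles, clip_limit=cfg.clip_limit,
                         n_bins=cfg.n_bins)
    pre = clahe(scene.image_float, params)
    window = make_hex_window(cfg.window_circumradius_px, cfg.ring_thickness_px)
    return score_live(pre, window), score_dead(pre, window)


def _rates_from_peaks(
    det: DetectionSet, scene: SyntheticScene, label: str, cfg: PipelineConfig
) -> tuple[float, float]:
    res = match_detections(
        det, scene.gt, cfg.match_max_dist_px, label=label,
        cluster_sep_px=cfg.cluster_separation_px,
    )
    n_gt = res.n_gt_counted
    if n_gt == 0:
        return 100.0, 0.0
    rate = 100.0 * res.n_matched / n_gt
    false_rate = 100.0 * len(res.false_detections) / n_gt
    return rate, false_rate


def evaluate_scene(
    scene: SyntheticScene,
    cfg: PipelineConfig | None = None,
    live_threshold: float | None = None,
    dead_threshold: float | None = None,
) -> dict:
    """Preprocess, detect and score one scene against its ground truth."""
    cfg = cfg or PipelineConfig()
    live_th = cfg.live_threshold if live_threshold is None else live_threshold
    dead_th = cfg.dead_threshold if dead_threshold is None else dead_threshold
    live_map, dead_map = _scene_maps(scene, cfg)
    live = select_peaks(live_map, "max", live_th, cfg.nms_radius_px)
    dead = select_peaks(dead_map, "min", dead_th, cfg.nms_radius_px)
    live_rate, live_false = _rates_from_peaks(live, scene, "live", cfg)
    dead_rate, dead_false = _rates_from_peaks(dead, scene, "dead", cfg)
    return {
        "live_rate": live_rate,
        "dead_rate": dead_rate,
        "live_false_rate": live_false,
        "dead_false_rate": dead_false,
        "n_live_detected": len(live),
        "n_dead_detected": len(dead),
    }


def _threshold_objective(rates: list[tuple[float, float]]) -> float:
    # mean identification rate minus mean false-detection rate
    return float(np.mean([r - f for r, f in rates]))


def kfold_evaluate(
    scenes: list[SyntheticScene],
    k: int = 5,
    live_grid: np.ndarray | None = None,
    dead_grid: np.ndarray | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> CVResult:
    """k-fold cross-validated identification rates with per-fold thresholds.

    Scenes are shuffled (seeded) into ``k`` folds. For each fold the
    live and dead score thresholds — the only free parameters of the
    detector — are chosen on the other k-1 folds by maximizing the mean
    identification rate minus the mean false-detection rate over the
    candidate grid, then the held-out fold is scored with the chosen
    pair. Score maps are computed once per scene; because greedy NMS
    retains, at a stricter threshold, exactly the surviving detections
    that still pass it, peaks are extracted once at the loosest grid
    value and filtered per candidate threshold.
    """
    if len(scenes) < k:
        raise ParameterError("need at least as many scenes as folds")
    if k < 2:
        raise ParameterError("k must be at least 2")
    cfg = config or PipelineConfig()
    live_grid = np.asarray(
        live_grid if live_grid is not None else np.arange(0.05, 0.51, 0.05)
    )
    dead_grid = np.asarray(
        dead_grid if dead_grid is not None else np.arange(0.10, 0.61, 0.05)
    )

    # Per-scene cache: peaks at the loosest thresholds, then per-grid rates.
    live_rates = np.empty((len(scenes), len(live_grid), 2))
    dead_rates = np.empty((len(scenes), len(dead_grid), 2))
    for si, scene in enumerate(scenes):
        live_map, dead_map = _scene_maps(scene, cfg)
        live_all = select_peaks(live_map, "max", float(live_grid.min()),
                                cfg.nms_radius_px)
        dead_all = select_peaks(dead_map, "min", float(dead_grid.max()),
                                cfg.nms_radius_px)
        for ti, th in enumerate(live_grid):
            det = live_all.subset(live_all.score > th)
            live_rates[si, ti] = _rates_from_peaks(det, scene, "live", cfg)
        for ti, th in enumerate(dead_grid):
            det = dead_all.subset(dead_all.score < th)
            dead_rates[si, ti] = _rates_from_peaks(det, scene, "dead", cfg)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scenes))
    folds = [sorted(order[i::k].tolist()) for i in range(k)]

    result = CVResult([], [], [], [], [], [], fold_assignment=folds)
    for fold in folds:
        train = [i for i in range(len(scenes)) if i not in fold]
        live_obj = [
            _threshold_objective([tuple(live_rates[si, ti]) for si in train])
            for ti in range(len(live_grid))
        ]
        dead_obj = [
            _threshold_objective([tuple(dead_rates[si, ti]) for si in train])
            for ti in range(len(dead_grid))
        ]
        li = int(np.argmax(live_obj))
        di = int(np.argmax(dead_obj))
        result.live_thresholds.append(float(live_grid[li]))
        result.dead_thresholds.append(float(dead_grid[di]))
        result.live_rates.append(float(np.mean([live_rates[si, li, 0] for si in fold])))
        result.live_false_rates.append(
            float(np.mean([live_rates[si, li, 1] for si in fold]))
        )
        result.dead_rates.append(float(np.mean([dead_rates[si, di, 0] for si in fold])))
        result.dead_false_rates.append(
            float(np.mean([dead_rates[si, di, 1] for si in fold]))
        )
    return result
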