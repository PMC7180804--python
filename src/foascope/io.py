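"""Image and table I/O plus the end-to-end pipeline runner.

Images are 8- or 16-bit PNG or TIFF with 1 or 3 channels; 8-bit data
round-trips losslessly. Detections and counts are CSV with documented
headers (`x,y,score,label` and per-scene count rows); every run writes a
log recording the full configuration and seed so it can be reproduced
exactly.
"""

from __future__ import annotations

import csv
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from . import __version__
from .config import PipelineConfig, dump_config
from .detection import detect_cells, detections_to_mask, make_hex_window
from .errors import ImageIOError, ParameterError
from .preprocess import ClaheParams, preprocess_pipeline
from .quantify import count_particles, identification_rate, match_detections
from .synthetic import CellGT, SyntheticScene

__all__ = [
    "read_image",
    "write_image",
    "read_gt_csv",
    "write_gt_csv",
    "write_scene",
    "read_scene",
    "run_pipeline",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster onto the [0, 1] working scale.

    Returns a 2-D array for single-channel input or H x W x 3 for RGB;
    palette images are expanded to RGB on read. 16-bit data is scaled by
    1/65535.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"{path}: no such file")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            with Image.open(path) as im:
                if im.mode == "P":
                    im = im.convert("RGB")
                arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - surface the loader's reason
        raise ImageIOError(f"{path}: unreadable image ({exc})")
    if arr.ndim == 3 and arr.shape[2] == 4:
        raise ImageIOError(f"{path}: 4-channel images are not supported")
    if arr.ndim == 3 and arr.shape[2] != 3:
        raise ImageIOError(f"{path}: expected 1 or 3 channels, got {arr.shape[2]}")
    if arr.ndim not in (2, 3):
        raise ImageIOError(f"{path}: expected a 2-D or 3-channel image")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    raise ImageIOError(f"{path}: unsupported bit depth {arr.dtype}")


def write_image(arr: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] raster (or uint8 array) as 8-bit PNG/TIFF."""
    path = Path(path)
    a = np.asarray(arr)
    if a.dtype != np.uint8:
        if a.min() < -1e-9 or a.max() > 1 + 1e-9:
            raise ParameterError("float image values must lie in [0, 1]")
        a = np.round(np.clip(a, 0, 1) * 255.0).astype(np.uint8)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(str(path), a)
        else:
            Image.fromarray(a).save(path)
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"{path}: cannot write image ({exc})")


_GT_HEADER = ["x", "y", "radius_px", "label", "cluster_member"]


def write_gt_csv(gt: list[CellGT], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_GT_HEADER)
        for c in gt:
            writer.writerow([c.x, c.y, c.radius_px, c.label, int(c.cluster_member)])


def read_gt_csv(path: str | Path) -> list[CellGT]:
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"{path}: no such file")
    cells = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _GT_HEADER:
            raise ImageIOError(f"{path}: expected header {','.join(_GT_HEADER)}")
        for row in reader:
            cells.append(
                CellGT(
                    x=float(row["x"]),
                    y=float(row["y"]),
                    radius_px=float(row["radius_px"]),
                    label=row["label"],
                    cluster_member=bool(int(row["cluster_member"])),
                )
            )
    return cells


def write_scene(scene: SyntheticScene, directory: str | Path, stem: str) -> None:
    """Write a scene as image + ground-truth CSV + parameter sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_image(scene.image, directory / f"{stem}.png")
    write_gt_csv(scene.gt, directory / f"{stem}.gt.csv")
    lines = [f"seed = {scene.seed}", f"noise_sigma = {scene.noise_sigma}"]
    for prefix, spec in (
        ("lattice", scene.lattice),
        ("illumination", scene.illumination),
        ("population", scene.population),
    ):
        for key, value in asdict(spec).items():
            lines.append(f"{prefix}.{key} = {value}")
    (directory / f"{stem}.cfg").write_text("\n".join(lines) + "\n")


def read_scene(directory: str | Path, stem: str):
    """Read back the (image, ground truth) pair written by :func:`write_scene`."""
    directory = Path(directory)
    img = read_image(directory / f"{stem}.png")
    gt = read_gt_csv(directory / f"{stem}.gt.csv")
    return img, gt


def run_pipeline(
    cfg: PipelineConfig,
    image_paths: list[str | Path],
    out_dir: str | Path,
    log=None,
) -> list[dict]:
    """Preprocess, detect, count — and score when ground truth is present.

    For each ``img.png`` a sibling ``img.gt.csv`` (if it exists) is used
    to compute per-class identification rates. Writes
    ``detections.csv``, ``counts.csv`` and ``run.log`` into ``out_dir``
    and returns one report dict per image.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = log or (lambda msg: print(msg, file=sys.stderr))
    params = ClaheParams(num_tiles=cfg.num_tiles, clip_limit=cfg.clip_limit,
                         n_bins=cfg.n_bins)
    window = make_hex_window(cfg.window_circumradius_px, cfg.ring_thickness_px)
    reports: list[dict] = []
    det_rows: list[list] = []
    count_rows: list[list] = []
    for path in image_paths:
        path = Path(path)
        log(f"[pipeline] {path.name}: preprocessing")
        arr = read_image(path)
        pre = preprocess_pipeline(arr, params)
        live, dead, (live_mask, dead_mask) = detect_cells(
            pre, window, cfg.live_threshold, cfg.dead_threshold,
            cfg.nms_radius_px, return_masks=True,
        )
        live_count = count_particles(live_mask, cfg.min_particle_area_px,
                                     cfg.connectivity)
        dead_count = count_particles(dead_mask, cfg.min_particle_area_px,
                                     cfg.connectivity)
        report = {
            "image": path.name,
            "n_live": live_count.count,
            "n_dead": dead_count.count,
        }
        for det in (live, dead):
            for i in range(len(det)):
                det_rows.append(
                    [path.name, det.x[i], det.y[i], det.score[i], det.label[i]]
                )
        gt_path = path.parent / (path.stem + ".gt.csv")
        if gt_path.exists():
            gt = read_gt_csv(gt_path)
            for label, det in (("live", live), ("dead", dead)):
                res = match_detections(
                    det, gt, cfg.match_max_dist_px, label=label,
                    cluster_sep_px=cfg.cluster_separation_px,
                )
                if res.n_gt_counted:
                    report[f"{label}_rate"] = identification_rate(
                        res.n_matched, res.n_gt_counted
                    )
                    report[f"{label}_false"] = len(res.false_detections)
        count_rows.append(
            [path.name, report["n_live"], report["n_dead"],
             report.get("live_rate", ""), report.get("dead_rate", "")]
        )
        reports.append(report)
        log(
            f"[pipeline] {path.name}: live={report['n_live']} "
            f"dead={report['n_dead']}"
        )

    with open(out_dir / "detections.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "x", "y", "score", "label"])
        writer.writerows(det_rows)
    with open(out_dir / "counts.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "n_live", "n_dead", "live_rate", "dead_rate"])
        writer.writerows(count_rows)
    (out_dir / "run.log").write_text(
        f"foascope {__version__}\n" + dump_config(cfg)
    )
    return reports
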