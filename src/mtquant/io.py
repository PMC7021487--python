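"""File I/O: TIFF stacks with JSON calibration sidecars, CSV results, YAML
configuration and run manifests.

A movie on disk is a multi-page TIFF plus an optional sidecar
``<stem>.json`` carrying ``pixel_size_um`` and ``frame_interval_min``;
missing calibration falls back to 1 µm/px and 1 min/frame with a logged
warning so uncalibrated data still flows through the pipeline (slopes then
come out in fraction per frame).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .prep import Movie

__all__ = [
    "read_movie",
    "write_movie",
    "read_image",
    "write_image",
    "write_results",
    "read_config",
    "write_manifest",
]

logger = logging.getLogger("mtquant")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_movie(path, pixel_size: Optional[float] = None,
               frame_interval: Optional[float] = None,
               cell_mask_path=None) -> Movie:
    """Load a multi-page TIFF as a timelapse Movie.

    Calibration comes from explicit arguments, else the JSON sidecar, else
    defaults (1 µm/px, 1 min/frame) with a warning.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        raise ValueError(
            f"{path} is a single page; a timelapse needs T >= 2 frames")
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a T×Y×X stack, got {stack.shape}")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um")
    if frame_interval is None:
        frame_interval = meta.get("frame_interval_min")
    if pixel_size is None:
        logger.warning("%s: no pixel size; defaulting to 1 µm/px", path)
        pixel_size = 1.0
    if frame_interval is None:
        logger.warning("%s: no frame interval; defaulting to 1 min/frame", path)
        frame_interval = 1.0

    cell_mask = None
    if cell_mask_path is not None:
        cell_mask = np.asarray(tifffile.imread(cell_mask_path)) > 0
    return Movie(stack=stack, pixel_size=float(pixel_size),
                 frame_interval=float(frame_interval), cell_mask=cell_mask)


def write_movie(movie: Movie, path) -> Path:
    """Write a 16-bit multi-page TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.clip(movie.stack, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, stack, photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps({
        "pixel_size_um": movie.pixel_size,
        "frame_interval_min": movie.frame_interval,
    }, indent=2))
    return path


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=float)


def write_image(image: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.clip(image, 0, 65535).astype(np.uint16),
                     photometric="minisblack")
    return path


def write_results(records: Sequence[dict], path,
                  sort_by: Sequence[str] = ("batch", "group", "cell")) -> Path:
    """Write result records as CSV with stable column and row order.

    Columns keep first-seen order; rows are sorted by whichever of
    ``sort_by`` columns are present, so identical runs give byte-identical
    files.  An empty record list writes a header-only file when columns can
    be inferred, else an empty file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(list(records))
    keys = [k for k in sort_by if k in df.columns]
    if keys:
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False)
    return path


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_manifest(out_dir, command: str, config: dict, seed: int) -> Path:
    """Record what produced an output directory: command, config, seed, version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "mtquant_version": __version__,
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=str))
    return p
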