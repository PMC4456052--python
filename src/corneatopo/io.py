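"""Reading and writing frame sequences, masks, ground truth and results.

Frames live in memory as float grids in [0, 1]; on disk they are 8- or 16-bit
grayscale TIFF stacks or PNG/TIFF directories (lexicographic frame order).
Integer pixel values are normalized by the dtype maximum — never by per-frame
min-max stretching, which would break palette comparability across frames.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .curvature import CurvatureProfile
from .segmentation import SegmentationResult
from .synthetic import GroundTruth

__all__ = [
    "read_sequence",
    "write_sequence",
    "write_frames_png",
    "write_ground_truth",
    "segmentation_to_csv",
    "profile_to_csv",
]

log = logging.getLogger("corneatopo")

_IMAGE_EXTS = {".png", ".tif", ".tiff"}


def _to_float(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if np.issubdtype(frames.dtype, np.integer):
        return frames.astype(float) / np.iinfo(frames.dtype).max
    return frames.astype(float)


def read_sequence(path: str | Path) -> np.ndarray:
    """Load a (n_frames, rows, cols) float sequence from a stack or directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in directory {path}")
        frames = []
        for f in files:
            try:
                frames.append(_to_float(iio.imread(f)))
            except Exception as exc:
                raise ValueError(f"unreadable frame {f}") from exc
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        seq = np.stack(frames)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        try:
            seq = _to_float(tifffile.imread(path))
        except Exception as exc:
            raise ValueError(f"unreadable TIFF stack {path}") from exc
        if seq.ndim == 2:
            seq = seq[None]
    elif path.suffix.lower() in {".avi", ".mp4"}:
        raise ValueError(
            f"{path.suffix} containers are not supported in this build; "
            "convert to a TIFF stack or PNG directory first"
        )
    else:
        raise ValueError(f"unsupported input {path}")
    log.info("read sequence: %d frames of shape %s", len(seq), seq.shape[1:])
    return seq


def write_sequence(frames: np.ndarray, path: str | Path, bit_depth: int = 16) -> None:
    """Write a float sequence as an 8/16-bit grayscale TIFF stack."""
    frames = np.clip(np.asarray(frames, dtype=float), 0.0, 1.0)
    if bit_depth == 16:
        data = np.round(frames * np.iinfo(np.uint16).max).astype(np.uint16)
    elif bit_depth == 8:
        data = np.round(frames * 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def write_frames_png(frames: np.ndarray, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write each frame (gray or RGB float) as an 8-bit PNG."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(np.asarray(frames)):
        data = np.round(np.clip(frame, 0, 1) * 255).astype(np.uint8)
        p = out_dir / f"{prefix}_{t:04d}.png"
        iio.imwrite(p, data)
        paths.append(p)
    return paths


def write_ground_truth(gt: GroundTruth, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Ground truth as CSV (column, upper_row, lower_row, radius_mm) + JSON sidecar."""
    n = len(gt.upper_rows)
    pd.DataFrame(
        {
            "column": np.arange(n),
            "upper_row": gt.upper_rows,
            "lower_row": gt.lower_rows,
            "radius_mm": gt.radius_mm,
        }
    ).to_csv(csv_path, index=False)
    if json_path is not None:
        sidecar = {
            "cct_px": gt.cct_px,
            "apex_positions": list(gt.apex_positions) if gt.apex_positions else None,
            "stage": gt.stage,
            "displacement_px": gt.displacement_px,
        }
        with open(json_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)


def segmentation_to_csv(seg: SegmentationResult, path: str | Path) -> None:
    n = len(seg.upper_rows)
    pd.DataFrame(
        {
            "column": np.arange(n),
            "upper_row": seg.upper_rows,
            "center_row": seg.center.fitted_rows,
            "lower_row": seg.lower_rows,
            "low_confidence": seg.quality_flags.astype(int),
        }
    ).to_csv(path, index=False)


def profile_to_csv(prof: CurvatureProfile, path: str | Path) -> None:
    n = len(prof.radius_mm)
    pd.DataFrame(
        {
            "column": np.arange(n),
            "radius_mm": prof.radius_mm,
            "valid": prof.valid_cols.astype(int),
        }
    ).to_csv(path, index=False)
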