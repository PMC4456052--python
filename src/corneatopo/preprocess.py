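"""Artifact removal: closing + connected-component area filtering.

Eyelashes and tear-film debris appear as thin bright strokes outside (or
touching) the corneal band.  Because every such impurity is much smaller than
the cornea, a size prior suffices: binarize, bridge illumination gaps in the
band with a morphological closing (10 rows x 60 columns, long axis horizontal
to match the near-horizontal band), then keep only connected components whose
area is at least a fixed fraction (default 1/3) of the largest component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing as _closing

from .config import PreprocessConfig

__all__ = ["BinaryMask", "binarize", "close_gaps", "keep_large", "apply_mask", "cornea_mask"]


@dataclass
class BinaryMask:
    """Boolean foreground mask plus the provenance of the steps that made it."""

    data: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)

    def __array__(self, dtype=None, copy=None):
        arr = self.data.astype(dtype) if dtype is not None else self.data
        return np.array(arr, copy=True) if copy else arr

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def binarize(frame: np.ndarray, config: PreprocessConfig | None = None) -> BinaryMask:
    """Global Otsu threshold; raises on a blank (uniform) frame."""
    config = config or PreprocessConfig()
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0.0:
        raise ValueError("empty frame: no intensity variation to threshold")
    if config.binarization != "otsu":
        raise ValueError(f"unknown binarization method {config.binarization!r}")
    thr = threshold_otsu(frame)
    mask = frame > thr
    if not mask.any():
        raise ValueError("empty frame: no foreground above threshold")
    return BinaryMask(mask, ["binarize:otsu"])


def _rect_footprint(rows: int, cols: int) -> list:
    # separable decomposition of the rectangle: much faster, same result
    return [(np.ones((rows, 1), dtype=bool), 1), (np.ones((1, cols), dtype=bool), 1)]


def close_gaps(mask: BinaryMask, config: PreprocessConfig | None = None) -> BinaryMask:
    """Morphological closing with the rectangular structuring element."""
    config = config or PreprocessConfig()
    closed = _closing(mask.data, footprint=_rect_footprint(config.se_rows, config.se_cols))
    # closing never removes foreground
    closed |= mask.data
    return BinaryMask(closed, mask.provenance + [f"close:{config.se_rows}x{config.se_cols}"])


def keep_large(mask: BinaryMask, ratio: float = 1.0 / 3.0) -> BinaryMask:
    """Keep 8-connected components with area >= ratio * largest area."""
    labels = label(mask.data, connectivity=2)
    if labels.max() == 0:
        raise ValueError("mask has no components")
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= ratio * areas.max()) + 1
    out = np.isin(labels, keep)
    return BinaryMask(out, mask.provenance + [f"keep_large:{ratio:.4g}"])


def apply_mask(frame: np.ndarray, mask: BinaryMask) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.shape != mask.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs mask {mask.shape}")
    return frame * mask.data


def cornea_mask(frame: np.ndarray, config: PreprocessConfig | None = None) -> BinaryMask:
    """Full artifact-removal chain: binarize -> close -> area filter.

    With ``grayscale_closing`` the closing is applied to the intensity image
    before thresholding instead of to the binary mask.
    """
    config = config or PreprocessConfig()
    if config.grayscale_closing:
        frame = _closing(
            np.asarray(frame, dtype=float),
            footprint=_rect_footprint(config.se_rows, config.se_cols),
        )
        mask = binarize(frame, config)
    else:
        mask = close_gaps(binarize(frame, config), config)
    return keep_large(mask, config.area_ratio)
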