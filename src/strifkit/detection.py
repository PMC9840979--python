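"""Locating restrained flies and fixing their analysis regions.

Flies are glued to the slide, so detection runs once on the first frame and
the resulting square regions of interest (ROIs) are held fixed for the whole
recording.  Detection is the classical blob pipeline: grayscale conversion,
Otsu thresholding (flies are darker than the background by default),
morphological opening/closing, 8-connected components, and an area filter.
The ROI is a square centred on the blob centroid with side equal to the
larger of the blob's height and width, clipped at the frame edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, opening

__all__ = [
    "Roi",
    "FlyDetection",
    "DetectionError",
    "to_grayscale",
    "binarize",
    "clean_mask",
    "detect_flies",
    "detections_to_frame",
]

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


class DetectionError(RuntimeError):
    """No usable fly blobs were found."""


@dataclass(frozen=True)
class Roi:
    """Square pixel region: top-left corner and side length."""

    top: int
    left: int
    side: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.top, self.top + self.side), slice(self.left, self.left + self.side)

    def contains(self, row: float, col: float) -> bool:
        return (
            self.top <= row < self.top + self.side
            and self.left <= col < self.left + self.side
        )

    def intersects(self, other: "Roi") -> bool:
        return not (
            self.top + self.side <= other.top
            or other.top + other.side <= self.top
            or self.left + self.side <= other.left
            or other.left + other.side <= self.left
        )


@dataclass
class FlyDetection:
    fly_id: int
    centroid: tuple[float, float]  # (row, col)
    blob_area: int
    blob_extent: tuple[int, int]  # (height, width)
    roi: Roi
    clipped: bool = False  # ROI shrunk at a frame edge


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Fixed-luma grayscale as float64; grayscale input passes through."""
    if frame.ndim == 2:
        return frame.astype(np.float64)
    if frame.ndim == 3 and frame.shape[-1] == 3:
        return frame.astype(np.float64) @ _LUMA
    raise ValueError(f"expected (H, W) or (H, W, 3) frame, got {frame.shape}")


def binarize(frame: np.ndarray, dark_flies: bool = True) -> np.ndarray:
    """Otsu-threshold a frame into a foreground (fly) mask.

    ``dark_flies`` selects which side of the threshold is foreground.  A
    uniform frame has no Otsu threshold; it yields an empty mask with a
    warning.
    """
    gray = to_grayscale(frame)
    if np.ptp(gray) == 0:
        warnings.warn("uniform frame: no contrast, returning empty mask", stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    thr = threshold_otsu(gray)
    return gray < thr if dark_flies else gray > thr


def clean_mask(mask: np.ndarray, kernel_radius: int = 1) -> np.ndarray:
    """Morphological opening then closing with a disk structuring element."""
    if kernel_radius <= 0:
        return mask.astype(bool)
    selem = disk(kernel_radius)
    return closing(opening(mask.astype(bool), selem), selem).astype(bool)


def _raster_order(regions):
    """Arena raster order: group centroids into row bands, then sort by
    column.  Banding (gap > median blob height) keeps the ordering stable
    against small within-row centroid scatter."""
    regions = sorted(regions, key=lambda r: r.centroid[0])
    gap = max(float(np.median([max(r.bbox[2] - r.bbox[0], 1) for r in regions])), 2.0)
    bands: list[list] = [[regions[0]]]
    for r in regions[1:]:
        if r.centroid[0] - bands[-1][-1].centroid[0] > gap:
            bands.append([r])
        else:
            bands[-1].append(r)
    out = []
    for band in bands:
        out.extend(sorted(band, key=lambda r: r.centroid[1]))
    return out


def detect_flies(
    frame: np.ndarray,
    min_area: int = 20,
    max_area: int = 2000,
    n_expected: int = 1,
    kernel_radius: int = 1,
    dark_flies: bool = True,
) -> list[FlyDetection]:
    """Detect fly blobs on one frame and attach fixed square ROIs.

    Components of the cleaned Otsu mask are filtered to
    ``[min_area, max_area]`` pixels, ordered by raster position of their
    centroids, and numbered ``0..k-1``.  If the surviving count differs from
    ``n_expected`` a warning is emitted (the caller decides whether to abort);
    zero survivors raise :class:`DetectionError`.
    """
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    mask = clean_mask(binarize(frame, dark_flies=dark_flies), kernel_radius)
    lab = label(mask, connectivity=2)  # 8-connectivity
    regions = [r for r in regionprops(lab) if min_area <= r.area <= max_area]
    if not regions:
        raise DetectionError(
            f"no blobs within area [{min_area}, {max_area}] "
            f"(raw components: {lab.max()})"
        )
    regions = _raster_order(regions)
    h, w = mask.shape
    detections: list[FlyDetection] = []
    for i, r in enumerate(regions):
        r0, c0, r1, c1 = r.bbox
        extent = (r1 - r0, c1 - c0)
        side = max(extent)
        cr, cc = r.centroid
        top = int(round(cr - side / 2))
        left = int(round(cc - side / 2))
        clipped = False
        # keep side length where possible by sliding inside the frame
        top = min(max(top, 0), max(h - side, 0))
        left = min(max(left, 0), max(w - side, 0))
        side_r = min(side, h - top, w - left)
        if side_r != side:
            clipped = True
        detections.append(
            FlyDetection(
                fly_id=i,
                centroid=(cr, cc),
                blob_area=int(r.area),
                blob_extent=extent,
                roi=Roi(top, left, side_r),
                clipped=clipped,
            )
        )
    if len(detections) != n_expected:
        warnings.warn(
            f"detected {len(detections)} flies, expected {n_expected}",
            stacklevel=2,
        )
    return detections


def detections_to_frame(detections: list[FlyDetection]) -> pd.DataFrame:
    """Tidy table of detections, joinable to arena metadata by fly_id."""
    return pd.DataFrame(
        {
            "fly_id": [d.fly_id for d in detections],
            "centroid_row": [d.centroid[0] for d in detections],
            "centroid_col": [d.centroid[1] for d in detections],
            "area": [d.blob_area for d in detections],
            "roi_top": [d.roi.top for d in detections],
            "roi_left": [d.roi.left for d in detections],
            "roi_side": [d.roi.side for d in detections],
        }
    )


def save_detections(detections: list[FlyDetection], path: str | Path) -> None:
    detections_to_frame(detections).to_csv(path, index=False)
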