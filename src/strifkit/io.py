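"""Reading and writing videos, frame directories and metadata tables.

Frame-image sequences (numbered PNG/TIFF files in a directory) are the
canonical on-disk format; container videos (AVI/MP4) are read through
imageio when a suitable backend is available.  Metadata CSVs map arena
position (the raster-order fly index) to genotype/condition.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_frames",
    "write_frame_dir",
    "read_metadata",
]

_FRAME_EXTS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


def _numeric_key(p: Path):
    m = re.search(r"(\d+)(?=\D*$)", p.stem)
    return (int(m.group(1)) if m else 0, p.name)


def read_frames(path: str | Path) -> np.ndarray:
    """Load a video as a (T, H, W[, 3]) uint8 stack.

    ``path`` may be a directory of numbered frame images (sorted by the last
    number in each file name) or a container video readable by imageio.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS),
            key=_numeric_key,
        )
        if not files:
            raise FileNotFoundError(f"no frame images in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            frames = np.stack(list(iio.imiter(path)))
        except Exception as exc:  # no backend for this container
            raise RuntimeError(
                f"cannot read {path.name}: no imageio backend available; "
                "convert to a PNG frame directory instead"
            ) from exc
    if frames.ndim == 4 and frames.shape[-1] == 4:  # drop alpha
        frames = frames[..., :3]
    return frames.astype(np.uint8, copy=False)


def write_frame_dir(frames: np.ndarray, out_dir: str | Path, prefix: str = "frame") -> Path:
    """Write a frame stack as numbered PNGs; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(frames.shape[0] - 1)))
    for t in range(frames.shape[0]):
        iio.imwrite(out / f"{prefix}_{t:0{width}d}.png", frames[t])
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Arena metadata CSV: requires ``position`` (unique int) and
    ``genotype`` columns; extra columns pass through."""
    df = pd.read_csv(path)
    required = {"position", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    if df["position"].duplicated().any():
        raise ValueError("metadata positions must be unique")
    return df
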