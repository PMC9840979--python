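"""Motion-energy traces for restrained flies.

The motion signal is deliberately simple: the mean absolute pixel difference
between consecutive grayscale frames inside a fly's fixed ROI
(intensity units per pixel per frame), so ROI size does not bias between
flies.  The same statistic computed outside all ROIs gives a background
trace used for noise floors and for detecting the onset of optogenetic
illumination (a global RGB jump, the "flash").

Salt-and-pepper sensor noise is removed at the image level with a per-pixel
temporal median-of-three (a corrupted pixel is almost never corrupted in two
consecutive frames), before any differencing.  A second, trace-level defence
(:func:`denoise_trace`) applies a temporal median filter and a minimum-
difference floor that zeroes sub-threshold residuals.

STRIF-speed is the average of stride-2 ("alternating frame") pixel
differences over the fly's active epochs.  Stride-2 differencing is blind to
strictly period-2 motion (frames t and t-2 are identical); this aliasing is
inherent to the definition and covered by a test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .detection import Roi, to_grayscale

__all__ = [
    "MotionTrace",
    "temporal_median3",
    "frames_to_gray",
    "frame_difference_trace",
    "background_trace",
    "denoise_trace",
    "strif_speed",
    "SpeedResult",
    "detect_flash",
    "compute_traces",
    "traces_to_frame",
]


@dataclass
class MotionTrace:
    """Per-fly motion time series.

    ``activity[k]`` is the ROI mean |frame k+1 - frame k|; length is
    ``n_frames - 1``.  ``background`` is the same statistic outside all ROIs.
    """

    fly_id: int
    fps: float
    activity: np.ndarray
    background: np.ndarray
    n_frames: int
    flash_frame: int | None = None

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if len(self.activity) != self.n_frames - 1:
            raise ValueError("activity length must be n_frames - 1")
        if (self.activity < 0).any() or (self.background < 0).any():
            raise ValueError("motion values must be non-negative")
        if self.flash_frame is not None and not (
            1 <= self.flash_frame <= self.n_frames - 1
        ):
            raise ValueError("flash_frame out of range")

    @property
    def times(self) -> np.ndarray:
        """Time (s) of each activity sample: the later frame of the pair."""
        return (np.arange(len(self.activity)) + 1) / self.fps


def frames_to_gray(frames: np.ndarray) -> np.ndarray:
    """Luma-grayscale a (T, H, W[, 3]) stack to uint8."""
    if frames.ndim == 3:
        return frames.astype(np.uint8, copy=False)
    gray = frames.astype(np.float32) @ np.array([0.299, 0.587, 0.114], dtype=np.float32)
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def temporal_median3(gray: np.ndarray) -> np.ndarray:
    """Per-pixel median over frames (t-1, t, t+1); first/last frames copied.

    Removes temporally isolated impulse (salt-and-pepper) noise without
    touching sustained intensity changes.  Fully vectorised.
    """
    if gray.shape[0] < 3:
        return gray.copy()
    a, b, c = gray[:-2], gray[1:-1], gray[2:]
    out = gray.copy()
    # median of three without sorting
    out[1:-1] = np.maximum(np.minimum(a, b), np.minimum(np.maximum(a, b), c))
    return out


def frame_difference_trace(
    frames: np.ndarray, roi: Roi, stride: int = 1
) -> np.ndarray:
    """Mean absolute grayscale difference inside ``roi`` between frames
    ``t`` and ``t - stride``; length ``T - stride``."""
    if frames.shape[0] < stride + 1:
        raise ValueError(f"need at least {stride + 1} frames")
    ys, xs = roi.slices
    sub = frames[:, ys, xs]
    if sub.ndim == 4:
        sub = frames_to_gray(sub)
    sub = sub.astype(np.int16, copy=False)
    d = np.abs(sub[stride:] - sub[:-stride])
    return d.mean(axis=(1, 2)).astype(float)


def background_trace(
    frames: np.ndarray, rois: list[Roi], chunk: int = 1000, return_n: bool = False
):
    """Mean absolute grayscale difference outside all ROIs, per frame pair.

    With ``return_n`` also returns the number of background pixels (needed to
    rescale impulse-noise floors to ROI size)."""
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    gray = frames if frames.ndim == 3 else frames_to_gray(frames)
    h, w = gray.shape[1:3]
    mask = np.ones((h, w), dtype=bool)
    for r in rois:
        ys, xs = r.slices
        mask[ys, xs] = False
    n_bg = int(mask.sum())
    if n_bg == 0:
        out = np.zeros(gray.shape[0] - 1)
        return (out, 0) if return_n else out
    out = np.empty(gray.shape[0] - 1)
    for s in range(0, gray.shape[0] - 1, chunk):
        e = min(s + chunk, gray.shape[0] - 1)
        block = gray[s : e + 1].astype(np.int16)
        d = np.abs(block[1:] - block[:-1])
        out[s:e] = d[:, mask].mean(axis=1)
    return (out, n_bg) if return_n else out


def denoise_trace(
    raw: np.ndarray, median_window: int = 5, min_diff_floor: float = 0.0
) -> np.ndarray:
    """Temporal median filter then minimum-difference floor.

    Values at or below ``min_diff_floor`` are set to zero; edge samples use
    shrunken (nearest-extended) windows.
    """
    if median_window < 3 or median_window % 2 == 0:
        raise ValueError("median_window must be odd and >= 3")
    if min_diff_floor < 0:
        raise ValueError("min_diff_floor must be >= 0")
    out = median_filter(np.asarray(raw, dtype=float), size=median_window, mode="nearest")
    out[out <= min_diff_floor] = 0.0
    return out


@dataclass(frozen=True)
class SpeedResult:
    value: float
    has_activity: bool


def strif_speed(
    frames: np.ndarray,
    roi: Roi,
    ethogram,
    whole_assay: bool = False,
) -> SpeedResult:
    """Average stride-2 pixel difference over active epochs (STRIF-speed).

    The stride-2 series value at index k compares frames k+2 and k and is
    assigned to the time of frame k+2.  With ``whole_assay`` the average runs
    over the entire recording instead of active epochs only.
    """
    series = frame_difference_trace(frames, roi, stride=2)
    fps = ethogram.fps if hasattr(ethogram, "fps") else None
    if whole_assay:
        return SpeedResult(float(series.mean()), True)
    times = (np.arange(len(series)) + 2) / (fps or 1.0)
    support = np.zeros(len(series), dtype=bool)
    from .ethogram import ACTIVE  # local import to avoid a cycle

    for ep in ethogram.epochs:
        if ep.state == ACTIVE:
            support |= (times >= ep.start) & (times < ep.end)
    if not support.any():
        return SpeedResult(0.0, False)
    return SpeedResult(float(series[support].mean()), True)


def detect_flash(
    frames: np.ndarray,
    rois: list[Roi] | None = None,
    sd_multiple: float = 5.0,
    window: int = 15,
    min_jump: float = 5.0,
) -> int | None:
    """First frame at which any colour channel's background mean jumps.

    The per-channel mean over the background region (outside all ROIs) is
    tracked; a flash is the first frame whose step exceeds
    ``max(sd_multiple x rolling SD of the preceding window, min_jump)``.
    ``min_jump`` guards against a zero SD on clean footage.  Returns the frame
    index, or None.  A flash already on in frame 0 is undetectable by
    differencing and is reported as None.
    """
    if frames.ndim == 3:
        chan = frames[..., None]
    else:
        chan = frames
    h, w = chan.shape[1:3]
    mask = np.ones((h, w), dtype=bool)
    for r in rois or []:
        ys, xs = r.slices
        mask[ys, xs] = False
    if not mask.any():
        mask[:] = True
    means = chan[:, mask, :].mean(axis=1)  # (T, C)
    steps = np.abs(np.diff(means, axis=0))  # step into frame t+1
    for t in range(steps.shape[0]):
        s = max(0, t - window + 1)
        sd = means[s : t + 1].std(axis=0, ddof=0) if t >= 1 else np.zeros(means.shape[1])
        thresh = np.maximum(sd_multiple * sd, min_jump)
        if (steps[t] > thresh).any():
            return t + 1
    return None


def compute_traces(
    frames: np.ndarray,
    detections,
    fps: float,
    median_window: int = 5,
    floor_quantile: float = 0.99,
    min_diff_floor: float | None = None,
    prefilter: bool = True,
    detect_flash_onset: bool = True,
    flash_frame: int | None = None,
) -> list[MotionTrace]:
    """Full trace computation for one video.

    Grayscales the stack, optionally applies the temporal median-of-three
    prefilter, computes per-fly ROI activity and the shared background trace,
    denoises each activity trace (median filter + floor), and detects the
    flash onset on the raw frames.  Samples within ``median_window`` frames
    of the flash are zeroed: the global intensity jump is illumination, not
    fly motion.

    The minimum-difference floor defaults to the ``floor_quantile`` quantile
    of the median-filtered background trace rescaled by
    ``n_background_pixels / n_roi_pixels``.  The rescaling matters for
    impulse (salt-and-pepper) noise: one corrupted pixel shifts a region's
    mean difference in inverse proportion to the region's area, so a floor
    measured on the large background region must be amplified before it is
    applied to a small ROI.
    """
    gray = frames_to_gray(frames)
    rois = [d.roi for d in detections]
    if detect_flash_onset and flash_frame is None:
        flash_frame = detect_flash(frames, rois)
    if prefilter:
        gray = temporal_median3(gray)
    bg_raw, n_bg = background_trace(gray, rois, return_n=True)
    bg = median_filter(bg_raw, size=median_window, mode="nearest")
    floor_base = float(np.quantile(bg, floor_quantile)) * n_bg
    traces = []
    n_frames = gray.shape[0]
    for det in detections:
        raw = frame_difference_trace(gray, det.roi)
        floor = (
            min_diff_floor
            if min_diff_floor is not None
            else floor_base / max(det.roi.side**2, 1)
        )
        act = denoise_trace(raw, median_window=median_window, min_diff_floor=floor)
        if flash_frame is not None:
            lo = max(0, flash_frame - 1 - median_window)
            hi = min(len(act), flash_frame - 1 + median_window + 1)
            act[lo:hi] = 0.0
        traces.append(
            MotionTrace(
                fly_id=det.fly_id,
                fps=fps,
                activity=act,
                background=bg,
                n_frames=n_frames,
                flash_frame=flash_frame,
            )
        )
    return traces


def traces_to_frame(traces: list[MotionTrace]) -> pd.DataFrame:
    """Long-form table: one row per frame pair per fly."""
    parts = []
    for tr in traces:
        k = np.arange(1, len(tr.activity) + 1)
        parts.append(
            pd.DataFrame(
                {
                    "fly_id": tr.fly_id,
                    "frame": k,
                    "t_seconds": k / tr.fps,
                    "activity": tr.activity,
                    "background": tr.background,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
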