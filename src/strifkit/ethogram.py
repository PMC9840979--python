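"""Activity/immobility segmentation and struggle metrics.

The behavioral rule is asymmetric: a restrained fly counts as immobile only
after five or more seconds without supra-threshold motion, so maximal
quiescent runs shorter than ``min_immobility`` are absorbed into the
surrounding activity, while activity has no minimum duration.  Epochs tile
the assay without gaps and alternate state; epochs touching the assay edges
are kept (total time is conserved).

The primary struggle metric is the activity:inactivity ratio of total times
over a window; it is reported with an explicit undefined flag (not a capped
value) when the fly was never immobile.  For optogenetic assays the ethogram
is split at the illumination onset and the post-onset fragment is
re-evaluated against the immobility rule.

``walking_metrics`` applies the same state logic to centroid trajectories of
freely walking flies (speed threshold instead of motion threshold), yielding
comparable ratios plus a mean speed in mm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

ACTIVE = "active"
INACTIVE = "inactive"

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "EthogramEpoch",
    "Ethogram",
    "StrifMetrics",
    "classify_states",
    "segment_binary",
    "compute_metrics",
    "split_before_after",
    "duration_histogram",
    "walking_metrics",
    "WalkingMetrics",
    "metrics_to_frame",
]


@dataclass(frozen=True)
class EthogramEpoch:
    state: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Ethogram:
    """Ordered, gap-free, alternating state epochs over one assay."""

    fly_id: int
    epochs: list[EthogramEpoch]
    assay_duration: float
    fps: float | None = None

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("ethogram needs at least one epoch")
        if not math.isclose(self.epochs[0].start, 0.0, abs_tol=1e-9):
            raise ValueError("first epoch must start at 0")
        if not math.isclose(self.epochs[-1].end, self.assay_duration, rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("last epoch must end at assay_duration")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if not math.isclose(a.end, b.start, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError("epochs must tile without gaps or overlaps")
            if a.state == b.state:
                raise ValueError("adjacent epochs must alternate state")

    def total_time(self, state: str) -> float:
        return sum(e.duration for e in self.epochs if e.state == state)

    def binary(self, fps: float) -> np.ndarray:
        """Per-sample active flags at ``fps``, sample k covering frame pair k."""
        n = int(round(self.assay_duration * fps))
        times = (np.arange(n) + 1) / fps
        out = np.zeros(n, dtype=bool)
        for e in self.epochs:
            if e.state == ACTIVE:
                out |= (times > e.start) & (times <= e.end + 1e-9)
        return out


def _runs(binary: np.ndarray) -> list[tuple[bool, int, int]]:
    """Maximal runs as (value, start_index, stop_index) with stop exclusive."""
    if len(binary) == 0:
        return []
    change = np.flatnonzero(np.diff(binary.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(binary)]))
    return [(bool(binary[s]), int(s), int(e)) for s, e in zip(starts, stops)]


def segment_binary(
    active: np.ndarray, fps: float, min_immobility: float = 5.0, fly_id: int = 0
) -> Ethogram:
    """Build an ethogram from a per-sample active flag series.

    Sample k spans ``(k/fps, (k+1)/fps]``.  Quiescent runs shorter than
    ``min_immobility`` seconds are merged into the surrounding activity,
    unless the entire series is quiescent (a fully immobile assay stays one
    inactive epoch regardless of length).
    """
    active = np.asarray(active, dtype=bool)
    if active.size == 0:
        raise ValueError("empty series")
    if active.any():
        min_run = int(math.ceil(min_immobility * fps))
        merged = active.copy()
        for val, s, e in _runs(active):
            if not val and (e - s) < min_run:
                merged[s:e] = True
        active = merged
    epochs = [
        EthogramEpoch(ACTIVE if val else INACTIVE, s / fps, e / fps)
        for val, s, e in _runs(active)
    ]
    return Ethogram(
        fly_id=fly_id,
        epochs=epochs,
        assay_duration=len(active) / fps,
        fps=fps,
    )


def classify_states(
    trace, activity_threshold: float | None = None, min_immobility: float = 5.0
) -> Ethogram:
    """Segment a motion trace into activity/immobility epochs.

    Frames with activity strictly above ``activity_threshold`` are raw-active.
    The threshold defaults to the 99th percentile of the trace's denoised
    background series (a data-driven noise scale).  The assay duration is the
    trace span, ``(n_frames - 1) / fps``.
    """
    if min_immobility <= 0:
        raise ValueError("min_immobility must be > 0")
    act = np.asarray(trace.activity, dtype=float)
    if act.size == 0:
        raise ValueError("empty trace")
    if activity_threshold is None:
        activity_threshold = float(np.quantile(trace.background, 0.99))
    if activity_threshold < 0:
        raise ValueError("activity_threshold must be >= 0")
    return segment_binary(
        act > activity_threshold, trace.fps, min_immobility, fly_id=trace.fly_id
    )


@dataclass
class StrifMetrics:
    """Struggle metrics for one fly over one window."""

    fly_id: int
    window: str  # {"full", "before_flash", "after_flash"}
    window_span: tuple[float, float]
    total_active: float
    total_inactive: float
    ratio: float  # nan when undefined
    ratio_defined: bool
    n_active_epochs: int
    n_inactive_epochs: int
    mean_active_duration: float
    mean_inactive_duration: float
    strif_speed: float = float("nan")

    @property
    def window_duration(self) -> float:
        return self.window_span[1] - self.window_span[0]


def _window_epochs(
    ethogram: Ethogram, t0: float, t1: float
) -> list[EthogramEpoch]:
    """Epochs truncated to [t0, t1]; states preserved, adjacency coalesced."""
    out: list[EthogramEpoch] = []
    for e in ethogram.epochs:
        a, b = max(e.start, t0), min(e.end, t1)
        if b - a <= 1e-12:
            continue
        if out and out[-1].state == e.state:
            out[-1] = EthogramEpoch(e.state, out[-1].start, b)
        else:
            out.append(EthogramEpoch(e.state, a, b))
    return out


def _metrics_from_epochs(
    epochs: list[EthogramEpoch],
    fly_id: int,
    window: str,
    span: tuple[float, float],
    speed: float = float("nan"),
) -> StrifMetrics:
    act = [e for e in epochs if e.state == ACTIVE]
    ina = [e for e in epochs if e.state == INACTIVE]
    total_active = sum(e.duration for e in act)
    total_inactive = sum(e.duration for e in ina)
    defined = total_inactive > 0
    return StrifMetrics(
        fly_id=fly_id,
        window=window,
        window_span=span,
        total_active=total_active,
        total_inactive=total_inactive,
        ratio=(total_active / total_inactive) if defined else float("nan"),
        ratio_defined=defined,
        n_active_epochs=len(act),
        n_inactive_epochs=len(ina),
        mean_active_duration=(total_active / len(act)) if act else 0.0,
        mean_inactive_duration=(total_inactive / len(ina)) if ina else 0.0,
        strif_speed=speed,
    )


def compute_metrics(
    ethogram: Ethogram,
    window: tuple[float, float] | None = None,
    label: str = "full",
    speed: float = float("nan"),
) -> StrifMetrics:
    """Struggle metrics over a window (default: whole assay).

    Epochs straddling the window edges are truncated at the edge; total
    active + inactive time equals the window length exactly.
    """
    t0, t1 = window if window is not None else (0.0, ethogram.assay_duration)
    t0 = max(t0, 0.0)
    t1 = min(t1, ethogram.assay_duration)
    if t1 - t0 <= 0:
        raise ValueError("zero-length window")
    eps = _window_epochs(ethogram, t0, t1)
    return _metrics_from_epochs(eps, ethogram.fly_id, label, (t0, t1), speed)


def _reapply_immobility_rule(
    epochs: list[EthogramEpoch], min_immobility: float
) -> list[EthogramEpoch]:
    """Merge inactive epochs shorter than the rule into surrounding activity."""
    if all(e.state == INACTIVE for e in epochs):
        return list(epochs)
    kept: list[EthogramEpoch] = []
    for e in epochs:
        state = e.state
        if state == INACTIVE and e.duration < min_immobility:
            state = ACTIVE
        if kept and kept[-1].state == state:
            kept[-1] = EthogramEpoch(state, kept[-1].start, e.end)
        else:
            kept.append(EthogramEpoch(state, e.start, e.end))
    return kept


def split_before_after(
    ethogram: Ethogram,
    flash_time: float,
    min_immobility: float = 5.0,
    speed_before: float = float("nan"),
    speed_after: float = float("nan"),
) -> tuple[StrifMetrics, StrifMetrics]:
    """Windowed metrics before and after an optogenetic light onset.

    The epoch containing ``flash_time`` is split there; the post-onset
    fragment (and the whole after-window) is re-evaluated against the
    immobility rule, since a truncated quiescent fragment may no longer
    qualify as immobility.
    """
    if not 0 < flash_time < ethogram.assay_duration:
        raise ValueError("flash_time must lie strictly inside the assay")
    before = compute_metrics(
        ethogram, (0.0, flash_time), label="before_flash", speed=speed_before
    )
    after_eps = _window_epochs(ethogram, flash_time, ethogram.assay_duration)
    after_eps = _reapply_immobility_rule(after_eps, min_immobility)
    after = _metrics_from_epochs(
        after_eps,
        ethogram.fly_id,
        "after_flash",
        (flash_time, ethogram.assay_duration),
        speed=speed_after,
    )
    return before, after


def duration_histogram(
    ethograms: list[Ethogram], bin_width: float = 5.0
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pooled per-state probability distribution of epoch durations.

    Bins are half-open ``[k*bin_width, (k+1)*bin_width)``.  Returns
    ``{state: (bin_edges, probabilities)}`` with probabilities summing to 1.
    """
    if not ethograms:
        raise ValueError("need at least one ethogram")
    out = {}
    for state in (ACTIVE, INACTIVE):
        durs = np.array(
            [e.duration for eth in ethograms for e in eth.epochs if e.state == state]
        )
        if durs.size == 0:
            out[state] = (np.array([0.0, bin_width]), np.array([0.0]))
            continue
        n_bins = int(np.floor(durs.max() / bin_width)) + 1
        edges = np.arange(n_bins + 1) * bin_width
        counts, _ = np.histogram(durs, bins=edges)
        out[state] = (edges, counts / counts.sum())
    return out


@dataclass
class WalkingMetrics:
    """Open-field analog of StrifMetrics, plus mean speed in mm/s."""

    fly_id: int
    total_active: float
    total_inactive: float
    ratio: float
    ratio_defined: bool
    n_active_epochs: int
    n_inactive_epochs: int
    mean_speed: float


def walking_metrics(
    trajectory: pd.DataFrame,
    fps: float,
    immobility_speed_threshold: float = 0.5,
    min_immobility: float = 5.0,
    fly_id: int = 0,
    interpolate: bool = False,
) -> WalkingMetrics:
    """Activity metrics from a pre-tracked centroid trajectory.

    ``trajectory`` needs columns ``x`` and ``y`` in millimetres (and
    optionally ``t`` in seconds for gap checking).  Frame speed is centroid
    displacement times ``fps`` (mm/s); frames above
    ``immobility_speed_threshold`` are raw-active and the same immobility
    merge rule applies.
    """
    x = trajectory["x"].to_numpy(dtype=float)
    y = trajectory["y"].to_numpy(dtype=float)
    if "t" in trajectory:
        t = trajectory["t"].to_numpy(dtype=float)
        gaps = np.diff(t)
        if (gaps > 1.0 + 1e-9).any():
            if not interpolate:
                raise ValueError("trajectory has gaps > 1 s; enable interpolation")
            tt = np.arange(t[0], t[-1] + 0.5 / fps, 1.0 / fps)
            x = np.interp(tt, t, x)
            y = np.interp(tt, t, y)
    if len(x) < 2:
        raise ValueError("trajectory needs at least 2 samples")
    speeds = np.hypot(np.diff(x), np.diff(y)) * fps
    eth = segment_binary(
        speeds > immobility_speed_threshold, fps, min_immobility, fly_id=fly_id
    )
    m = compute_metrics(eth)
    return WalkingMetrics(
        fly_id=fly_id,
        total_active=m.total_active,
        total_inactive=m.total_inactive,
        ratio=m.ratio,
        ratio_defined=m.ratio_defined,
        n_active_epochs=m.n_active_epochs,
        n_inactive_epochs=m.n_inactive_epochs,
        mean_speed=float(speeds.mean()),
    )


def metrics_to_frame(metrics: list[StrifMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fly_id": [m.fly_id for m in metrics],
            "window": [m.window for m in metrics],
            "window_start": [m.window_span[0] for m in metrics],
            "window_end": [m.window_span[1] for m in metrics],
            "total_active": [m.total_active for m in metrics],
            "total_inactive": [m.total_inactive for m in metrics],
            "ratio": [m.ratio for m in metrics],
            "ratio_defined": [m.ratio_defined for m in metrics],
            "n_active_epochs": [m.n_active_epochs for m in metrics],
            "n_inactive_epochs": [m.n_inactive_epochs for m in metrics],
            "mean_active_duration": [m.mean_active_duration for m in metrics],
            "mean_inactive_duration": [m.mean_inactive_duration for m in metrics],
            "strif_speed": [m.strif_speed for m in metrics],
        }
    )
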