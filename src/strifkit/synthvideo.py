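"""Synthetic restrained-fly videos with known ground truth.

A restrained (thorax-glued) fly alternates between bouts of flailing — bursts
of high motor activity — and quiescence.  This module generates such
alternating state sequences (:class:`BehaviorProgram`), renders them as
multi-fly videos of dark blobs jittering on a light background
(:func:`render_video`), and optionally corrupts the frames with a global
illumination step ("flash", emulating optogenetic light onset) and
salt-and-pepper noise.  Every rendered video carries a ground-truth record so
the whole detection → motion → ethogram pipeline can be validated end to end
without real recordings.

Durations of active and inactive bouts are drawn from a shifted exponential:
``floor + Exponential(mean - floor)``, so the floor (default 1 s) is respected
and the expected duration equals the requested mean exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

ACTIVE = "active"
INACTIVE = "inactive"

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "Epoch",
    "BehaviorProgram",
    "RenderSpec",
    "GroundTruth",
    "sample_program",
    "render_video",
    "inject_noise",
    "expected_state_intervals",
    "compare_to_program",
    "default_positions",
]


@dataclass(frozen=True)
class Epoch:
    """One behavioral bout: state, duration in seconds, jitter amplitude (px)."""

    state: str
    duration: float
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.state not in (ACTIVE, INACTIVE):
            raise ValueError(f"unknown state {self.state!r}")
        if self.duration <= 0:
            raise ValueError("epoch duration must be > 0")
        if self.state == INACTIVE and self.amplitude != 0:
            raise ValueError("inactive epochs must have amplitude 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class BehaviorProgram:
    """Ground-truth alternating active/inactive sequence for one fly."""

    fly_id: int
    epochs: list[Epoch]
    total_duration: float

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("program needs at least one epoch")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if a.state == b.state:
                raise ValueError("adjacent epochs must alternate state")
        total = sum(e.duration for e in self.epochs)
        if not math.isclose(total, self.total_duration, rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError(
                f"epoch durations sum to {total}, expected {self.total_duration}"
            )

    def state_at(self, t: float) -> str:
        """State occupied at time ``t`` seconds (last epoch covers the end)."""
        acc = 0.0
        for e in self.epochs:
            acc += e.duration
            if t < acc:
                return e.state
        return self.epochs[-1].state

    def to_dict(self) -> dict:
        return {
            "fly_id": self.fly_id,
            "total_duration": self.total_duration,
            "epochs": [
                {"state": e.state, "duration": e.duration, "amplitude": e.amplitude}
                for e in self.epochs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BehaviorProgram":
        return cls(
            fly_id=d["fly_id"],
            epochs=[Epoch(e["state"], e["duration"], e["amplitude"]) for e in d["epochs"]],
            total_duration=d["total_duration"],
        )


def sample_program(
    duration: float,
    mean_active: float = 20.0,
    mean_inactive: float = 10.0,
    amplitude: float = 3.0,
    seed: int | None = None,
    floor: float = 1.0,
    start_state: str = ACTIVE,
    fly_id: int = 0,
) -> BehaviorProgram:
    """Sample an alternating active/inactive program.

    Bout durations are ``floor + Exponential(mean - floor)`` per state, so the
    expectation equals the requested mean; the last bout is truncated at
    ``duration``.  Reproducible for a given ``seed``.

    Parameters
    ----------
    duration : assay length in seconds.
    mean_active, mean_inactive : mean bout durations in seconds (> 0).
    amplitude : per-frame blob jitter during active bouts, pixels.
    floor : minimum bout duration in seconds (clipped to ``mean`` if larger).
    start_state : state of the first bout (flailing first by default; a glued
        fly typically struggles immediately after handling).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if mean_active <= 0 or mean_inactive <= 0:
        raise ValueError("mean durations must be > 0")
    if start_state not in (ACTIVE, INACTIVE):
        raise ValueError(f"unknown start_state {start_state!r}")
    rng = np.random.default_rng(seed)
    means = {ACTIVE: mean_active, INACTIVE: mean_inactive}
    other = {ACTIVE: INACTIVE, INACTIVE: ACTIVE}

    epochs: list[Epoch] = []
    state = start_state
    t = 0.0
    while t < duration:
        mean = means[state]
        lo = min(floor, mean)  # floor cannot exceed the requested mean
        d = lo + rng.exponential(mean - lo) if mean > lo else mean
        d = min(d, duration - t)
        if d > 0:
            amp = amplitude if state == ACTIVE else 0.0
            epochs.append(Epoch(state, d, amp))
            t += d
        state = other[state]
    return BehaviorProgram(fly_id=fly_id, epochs=epochs, total_duration=duration)


def default_positions(n_flies: int, frame_size: tuple[int, int], fly_radius: int) -> list[tuple[int, int]]:
    """Grid anchors (row, col) with pairwise separation > 4 x fly_radius."""
    h, w = frame_size
    ncols = int(math.ceil(math.sqrt(n_flies * w / h)))
    ncols = max(1, min(ncols, n_flies))
    nrows = int(math.ceil(n_flies / ncols))
    margin = 2 * fly_radius + 2
    rows = np.linspace(margin, h - margin, nrows)
    cols = np.linspace(margin, w - margin, ncols)
    pos = [(int(round(r)), int(round(c))) for r in rows for c in cols]
    return pos[:n_flies]


@dataclass
class RenderSpec:
    """Rendering geometry and photometry for a synthetic multi-fly video.

    Defaults mirror the real acquisition: 30 frames/s RGB, six flies per
    arena, dark flies on a light background.
    """

    frame_size: tuple[int, int] = (120, 160)
    fps: float = 30.0
    n_flies: int = 6
    fly_radius: int = 6
    fly_positions: list[tuple[int, int]] | None = None
    background_level: int = 200
    fly_level: int = 30
    flash_frame: int | None = None
    flash_color_shift: tuple[int, int, int] = (40, 0, 0)
    noise_fraction: float = 0.0
    seed: int = 0
    grayscale: bool = False

    def __post_init__(self) -> None:
        if self.fly_positions is None:
            self.fly_positions = default_positions(
                self.n_flies, self.frame_size, self.fly_radius
            )
        if len(self.fly_positions) != self.n_flies:
            raise ValueError("fly_positions length must equal n_flies")
        if not 0 <= self.noise_fraction < 0.05:
            raise ValueError("noise_fraction must be in [0, 0.05)")
        if abs(self.fly_level - self.background_level) < 50:
            raise ValueError("fly/background contrast must be >= 50 intensity units")
        min_sep = 4 * self.fly_radius
        pts = np.asarray(self.fly_positions, dtype=float)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.hypot(*(pts[i] - pts[j])) <= min_sep:
                    raise ValueError(
                        f"fly positions {i} and {j} closer than 4 x fly_radius"
                    )


@dataclass
class GroundTruth:
    """Everything needed to score a pipeline run against the simulation."""

    programs: list[BehaviorProgram]
    anchors: list[tuple[int, int]]
    fps: float
    flash_frame: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fps": self.fps,
            "flash_frame": self.flash_frame,
            "anchors": [list(a) for a in self.anchors],
            "programs": [p.to_dict() for p in self.programs],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            programs=[BehaviorProgram.from_dict(p) for p in d["programs"]],
            anchors=[tuple(a) for a in d["anchors"]],
            fps=d["fps"],
            flash_frame=d["flash_frame"],
        )


def _disk_mask(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def render_video(
    programs: Sequence[BehaviorProgram], spec: RenderSpec
) -> tuple[np.ndarray, GroundTruth]:
    """Render programs as a frame stack.

    Returns ``(frames, ground_truth)``; frames are uint8 of shape
    ``(T, H, W, 3)`` (or ``(T, H, W)`` when ``spec.grayscale``).  During active
    epochs a fly's disk centre jitters around its anchor by an integer offset
    uniform on ``[-amplitude, +amplitude]`` per axis per frame; during inactive
    epochs it sits exactly on the anchor, so a noiseless inactive scene is
    bit-static.
    """
    if len(programs) != spec.n_flies:
        raise ValueError("need one program per fly")
    durations = {round(p.total_duration, 9) for p in programs}
    if len(durations) > 1:
        raise ValueError("all programs must share total_duration")
    total = programs[0].total_duration
    n_frames = int(round(total * spec.fps))
    h, w = spec.frame_size
    rng = np.random.default_rng(spec.seed)

    # per-fly, per-frame centre offsets
    offsets = np.zeros((spec.n_flies, n_frames, 2), dtype=np.int64)
    amps = np.zeros((spec.n_flies, n_frames))
    for k, prog in enumerate(programs):
        t0 = 0.0
        for e in prog.epochs:
            f0 = int(round(t0 * spec.fps))
            f1 = min(int(round((t0 + e.duration) * spec.fps)), n_frames)
            if e.state == ACTIVE and e.amplitude > 0 and f1 > f0:
                a = int(round(e.amplitude))
                offsets[k, f0:f1] = rng.integers(-a, a + 1, size=(f1 - f0, 2))
                amps[k, f0:f1] = e.amplitude
            t0 += e.duration
    disk = _disk_mask(spec.fly_radius)
    r = spec.fly_radius

    frames = np.full((n_frames, h, w), spec.background_level, dtype=np.uint8)
    for t in range(n_frames):
        fr = frames[t]
        for k, (ar, ac) in enumerate(spec.fly_positions):
            cr = ar + offsets[k, t, 0]
            cc = ac + offsets[k, t, 1]
            top, left = cr - r, cc - r
            y0, x0 = max(top, 0), max(left, 0)
            y1, x1 = min(top + disk.shape[0], h), min(left + disk.shape[1], w)
            sub = disk[y0 - top : y1 - top, x0 - left : x1 - left]
            fr[y0:y1, x0:x1][sub] = spec.fly_level

    if not spec.grayscale:
        frames = np.repeat(frames[..., None], 3, axis=-1)
        if spec.flash_frame is not None:
            shift = np.asarray(spec.flash_color_shift, dtype=np.int16)
            lit = frames[spec.flash_frame :].astype(np.int16) + shift
            frames[spec.flash_frame :] = np.clip(lit, 0, 255).astype(np.uint8)
    elif spec.flash_frame is not None:
        # grayscale flash: add the mean channel shift
        shift = int(round(np.mean(spec.flash_color_shift)))
        lit = frames[spec.flash_frame :].astype(np.int16) + shift
        frames[spec.flash_frame :] = np.clip(lit, 0, 255).astype(np.uint8)

    if spec.noise_fraction > 0:
        frames = inject_noise(frames, spec.noise_fraction, seed=rng.integers(2**31))

    gt = GroundTruth(
        programs=list(programs),
        anchors=list(spec.fly_positions),
        fps=spec.fps,
        flash_frame=spec.flash_frame,
    )
    return frames, gt


def inject_noise(frames: np.ndarray, noise_fraction: float, seed: int | None = None) -> np.ndarray:
    """Salt-and-pepper corruption: per frame, exactly ``round(f * n_pixels)``
    pixels are forced to 0 or 255 (half each, odd counts favouring salt).

    Works on ``(T, H, W)`` or ``(T, H, W, C)`` stacks; a corrupted pixel is set
    across all channels, as a saturated sensor pixel would be.
    """
    if not 0 <= noise_fraction < 1:
        raise ValueError("noise_fraction must be in [0, 1)")
    if noise_fraction == 0:
        return frames
    rng = np.random.default_rng(seed)
    out = frames.copy()
    has_channels = out.ndim == 4
    n_frames = out.shape[0]
    h, w = out.shape[1], out.shape[2]
    n_pix = h * w
    k = int(round(noise_fraction * n_pix))
    n_salt = (k + 1) // 2
    for t in range(n_frames):
        idx = rng.choice(n_pix, size=k, replace=False, shuffle=False)
        rr, cc = np.unravel_index(idx, (h, w))
        if has_channels:
            out[t, rr[:n_salt], cc[:n_salt], :] = 255
            out[t, rr[n_salt:], cc[n_salt:], :] = 0
        else:
            out[t, rr[:n_salt], cc[:n_salt]] = 255
            out[t, rr[n_salt:], cc[n_salt:]] = 0
    return out


def expected_state_intervals(
    program: BehaviorProgram, min_immobility: float = 5.0
) -> list[tuple[str, float, float]]:
    """Ideal segmentation of a program under the immobility rule.

    Inactive bouts shorter than ``min_immobility`` seconds do not count as
    immobility and are absorbed into the surrounding activity, mirroring what
    a perfect classifier applying the rule would output.  Returns a list of
    ``(state, start, end)`` tuples tiling ``[0, total_duration]``.
    """
    # raw intervals
    iv: list[list] = []
    t = 0.0
    for e in program.epochs:
        iv.append([e.state, t, t + e.duration])
        t += e.duration
    only_inactive = all(s == INACTIVE for s, *_ in iv)
    if not only_inactive:
        iv = [
            [s, a, b]
            for s, a, b in iv
            if not (s == INACTIVE and (b - a) < min_immobility)
        ] or iv
        # promote the gaps left by removed short-inactive runs to activity
        merged: list[list] = []
        prev_end = 0.0
        for s, a, b in iv:
            if a > prev_end + 1e-12:
                merged.append([ACTIVE, prev_end, a])
            merged.append([s, a, b])
            prev_end = b
        if prev_end < program.total_duration - 1e-12:
            merged.append([ACTIVE, prev_end, program.total_duration])
        # coalesce adjacent same-state intervals
        iv = []
        for s, a, b in merged:
            if iv and iv[-1][0] == s:
                iv[-1][2] = b
            else:
                iv.append([s, a, b])
    return [(s, a, b) for s, a, b in iv]


def compare_to_program(
    ethogram,
    program: BehaviorProgram,
    tolerance: float = 1.0,
    min_immobility: float = 5.0,
) -> dict:
    """Score a recovered ethogram against its generating program.

    Internal boundaries of the ideal segmentation (program after the
    immobility rule) are matched to recovered boundaries of the same state
    transition; a boundary is recovered if some recovered transition lies
    within ``tolerance`` seconds.  Also reports the state-time error as a
    fraction of the assay duration.

    Returns a dict with ``n_boundaries``, ``n_recovered``,
    ``boundary_recovery`` (fraction) and ``state_time_error`` (fraction).
    """
    ideal = expected_state_intervals(program, min_immobility)
    true_bounds = [(a, s) for s, a, _ in ideal[1:]]  # internal transition times
    rec_bounds = [(ep.start, ep.state) for ep in ethogram.epochs[1:]]
    n_rec = 0
    for tb, state in true_bounds:
        if any(abs(tb - rb) <= tolerance and state == rs for rb, rs in rec_bounds):
            n_rec += 1
    true_active = sum(b - a for s, a, b in ideal if s == ACTIVE)
    rec_active = sum(
        ep.end - ep.start for ep in ethogram.epochs if ep.state == ACTIVE
    )
    # recovered assay is one frame-interval shorter than the program; compare
    # active fractions on the common support
    dur = min(program.total_duration, ethogram.assay_duration)
    err = abs(true_active - rec_active) / program.total_duration
    return {
        "n_boundaries": len(true_bounds),
        "n_recovered": n_rec,
        "boundary_recovery": (n_rec / len(true_bounds)) if true_bounds else 1.0,
        "state_time_error": err,
        "common_duration": dur,
    }
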