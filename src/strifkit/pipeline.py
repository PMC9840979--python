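"""End-to-end orchestration: video -> detections -> traces -> ethograms ->
metrics -> contrasts.

The core entry point is :func:`analyze_video`, a pure in-memory function
used by the file-based runners, the CLI, the test-suite and the acceptance
script alike.  :func:`run_strif` adds metadata joining, CSV export and
provenance (a resolved-config copy and a stage-count log next to the
outputs); :func:`run_optogenetic` splits each fly's assay at the detected
(or supplied) flash and builds paired before/after contrasts per genotype.

All randomness flows from the single config seed, so identical config +
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detection, estimation, ethogram as etho, io as sio, motion

log = logging.getLogger("strifkit")

__all__ = ["ExperimentConfig", "FlyResult", "analyze_video", "run_strif", "run_optogenetic"]


@dataclass
class ExperimentConfig:
    """All knobs for one pipeline run; YAML-serializable."""

    video: str | None = None
    metadata: str | None = None
    output_dir: str = "strif_out"
    fps: float = 30.0
    n_expected_flies: int = 6
    # detection
    min_area: int = 20
    max_area: int = 2000
    kernel_radius: int = 1
    dark_flies: bool = True
    roi_pad: int = 4
    # motion
    median_window: int = 5
    floor_quantile: float = 0.99
    prefilter: bool = True
    # ethogram
    activity_threshold: float | None = None
    min_immobility: float = 5.0
    # optogenetics
    flash_frame: int | None = None
    detect_flash: bool = True
    # statistics
    n_boot: int = 5000
    n_perm: int = 10000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 3")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_immobility <= 0:
            raise ValueError("min_immobility must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class FlyResult:
    """Everything the pipeline derives for one fly."""

    fly_id: int
    detection: detection.FlyDetection
    trace: motion.MotionTrace
    ethogram: etho.Ethogram
    metrics: etho.StrifMetrics
    before: etho.StrifMetrics | None = None
    after: etho.StrifMetrics | None = None


def _pad_roi(d: detection.FlyDetection, pad: int, frame_shape) -> detection.FlyDetection:
    """Grow the ROI by ``pad`` on each side (clipped), keeping it square."""
    if pad <= 0:
        return d
    h, w = frame_shape[:2]
    side = d.roi.side + 2 * pad
    top = min(max(d.roi.top - pad, 0), max(h - side, 0))
    left = min(max(d.roi.left - pad, 0), max(w - side, 0))
    side = min(side, h - top, w - left)
    return dataclasses.replace(d, roi=detection.Roi(top, left, side))


def analyze_video(
    frames: np.ndarray, config: ExperimentConfig | None = None
) -> list[FlyResult]:
    """Run detection, motion tracing, segmentation and metrics on a stack.

    Detection runs on the first frame only; ROIs (grown by ``roi_pad`` pixels
    so leg/wing excursions stay inside) are fixed for the whole video.  If a
    flash is detected or supplied, each fly additionally gets before/after
    windowed metrics and the flash transition is excised from traces.
    """
    cfg = config or ExperimentConfig()
    dets = detection.detect_flies(
        frames[0],
        min_area=cfg.min_area,
        max_area=cfg.max_area,
        n_expected=cfg.n_expected_flies,
        kernel_radius=cfg.kernel_radius,
        dark_flies=cfg.dark_flies,
    )
    dets = [_pad_roi(d, cfg.roi_pad, frames.shape[1:]) for d in dets]
    log.info("detected %d flies (expected %d)", len(dets), cfg.n_expected_flies)
    traces = motion.compute_traces(
        frames,
        dets,
        fps=cfg.fps,
        median_window=cfg.median_window,
        floor_quantile=cfg.floor_quantile,
        prefilter=cfg.prefilter,
        detect_flash_onset=cfg.detect_flash,
        flash_frame=cfg.flash_frame,
    )
    results: list[FlyResult] = []
    for det, tr in zip(dets, traces):
        eth = etho.classify_states(
            tr,
            activity_threshold=cfg.activity_threshold,
            min_immobility=cfg.min_immobility,
        )
        speed = motion.strif_speed(frames, det.roi, eth)
        m = etho.compute_metrics(eth, speed=speed.value)
        res = FlyResult(det.fly_id, det, tr, eth, m)
        if tr.flash_frame is not None:
            flash_time = tr.flash_frame / cfg.fps
            if 0 < flash_time < eth.assay_duration:
                sb = motion.strif_speed(frames[: tr.flash_frame], det.roi, eth)
                sa = motion.strif_speed(frames[tr.flash_frame :], det.roi, _shift(eth, flash_time))
                res.before, res.after = etho.split_before_after(
                    eth,
                    flash_time,
                    min_immobility=cfg.min_immobility,
                    speed_before=sb.value,
                    speed_after=sa.value,
                )
        results.append(res)
    log.info("segmented %d ethograms", len(results))
    return results


def _shift(eth: etho.Ethogram, t0: float) -> etho.Ethogram:
    """Ethogram restricted to [t0, end] re-anchored at 0 (for windowed speed)."""
    eps = []
    for e in eth.epochs:
        a, b = max(e.start, t0) - t0, e.end - t0
        if b > 0 and b - max(a, 0) > 1e-12:
            eps.append(etho.EthogramEpoch(e.state, max(a, 0.0), b))
    merged = []
    for e in eps:
        if merged and merged[-1].state == e.state:
            merged[-1] = etho.EthogramEpoch(e.state, merged[-1].start, e.end)
        else:
            merged.append(e)
    return etho.Ethogram(eth.fly_id, merged, eth.assay_duration - t0, fps=eth.fps)


def _results_table(
    results: list[FlyResult], meta: pd.DataFrame | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-fly metrics table (one row per window) + failure table."""
    rows = []
    for r in results:
        for m in filter(None, [r.metrics, r.before, r.after]):
            rows.append(etho.metrics_to_frame([m]).assign(fly_id=r.fly_id))
    table = pd.concat(rows, ignore_index=True)
    failures = pd.DataFrame(columns=["position", "reason"])
    if meta is not None:
        table = table.merge(
            meta.rename(columns={"position": "fly_id"}), on="fly_id", how="left"
        )
        seen = {r.fly_id for r in results}
        missing = sorted(set(meta["position"]) - seen)
        failures = pd.DataFrame(
            {"position": missing, "reason": ["not detected"] * len(missing)}
        )
    return table, failures


def _write_outputs(
    out: Path, cfg: ExperimentConfig, table: pd.DataFrame, failures: pd.DataFrame
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config_resolved.yaml")
    table.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    failures.to_csv(out / "failures.csv", index=False)


def run_strif(
    config: ExperimentConfig, frames: np.ndarray | None = None
) -> pd.DataFrame:
    """File-based STRIF run: read video + metadata, analyze, export CSVs.

    Returns the tidy per-fly metrics table.  A fly-count mismatch is flagged
    per arena (the run continues); an unreadable video aborts.
    """
    if frames is None:
        if config.video is None:
            raise ValueError("config.video is required when frames are not given")
        frames = sio.read_frames(config.video)
    log.info("loaded %d frames of %s", frames.shape[0], frames.shape[1:])
    meta = sio.read_metadata(config.metadata) if config.metadata else None
    results = analyze_video(frames, config)
    table, failures = _results_table(results, meta)
    _write_outputs(Path(config.output_dir), config, table, failures)
    return table


def paired_contrasts(
    table: pd.DataFrame,
    value: str = "total_active",
    group_col: str = "genotype",
    n_boot: int = 5000,
    n_perm: int = 10000,
    seed: int = 0,
) -> list[estimation.EffectResult]:
    """Per-genotype paired before-vs-after contrasts from a metrics table."""
    out = []
    groups = (
        sorted(table[group_col].dropna().unique()) if group_col in table else [None]
    )
    for g in groups:
        sub = table if g is None else table[table[group_col] == g]
        b = sub[sub.window == "before_flash"].sort_values("fly_id")
        a = sub[sub.window == "after_flash"].sort_values("fly_id")
        common = sorted(set(b.fly_id) & set(a.fly_id))
        if len(common) < 5:
            continue
        bv = b.set_index("fly_id").loc[common, value].to_numpy()
        av = a.set_index("fly_id").loc[common, value].to_numpy()
        out.append(
            estimation.compare_groups(
                av,
                bv,
                label=f"{g or 'all'}:{value}:after-before",
                paired=True,
                n_boot=n_boot,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return out


def run_optogenetic(
    config: ExperimentConfig,
    frames: np.ndarray | None = None,
    value: str = "total_active",
) -> tuple[pd.DataFrame, list[estimation.EffectResult]]:
    """Optogenetic run: analyze, split at the flash, paired stats per genotype.

    Aborts with a diagnostic if no flash was detected and none was supplied.
    """
    table = run_strif(config, frames=frames)
    if not (table.window == "after_flash").any():
        raise RuntimeError(
            "no flash detected and none supplied; cannot build before/after contrasts"
        )
    contrasts = paired_contrasts(
        table,
        value=value,
        n_boot=config.n_boot,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    out = Path(config.output_dir)
    pd.DataFrame([c.to_dict() for c in contrasts]).to_csv(
        out / "contrasts.csv", index=False, float_format="%.10g"
    )
    return table, contrasts
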