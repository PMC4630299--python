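"""End-to-end screen orchestration.

Two analysis branches share the preprocessing front end (bin -> register ->
stretch):

* flow branch: centered crop -> dense LK flow -> absolute-velocity maps ->
  log-velocity montage -> row normalization -> running-SD artifact mask ->
  flow-ratio series; the screen assembles these into a flow table and runs
  pooled-control Dunnett statistics.
* tracker branch: centered crop -> contrast normalization + 8-bit ->
  difference filter -> feature detection -> track linking -> motion report.

Per-movie failures are isolated and logged; the screen completes for the
remaining movies. All CSV outputs are deterministic given identical inputs,
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from .histograms import (FlowTable, FrameMask, FrameMaskRule, HistogramSpec,
                         VelocityMontage, build_flow_table, build_frame_mask,
                         build_montage, flow_ratio_series, normalize_montage,
                         running_sd_scores)
from .lk import LKParams, absolute_velocity, flow_movie
from .movie import Calibration, Movie, read_movie
from .stats import SampleSeries, pooled_dunnett, summarize_screen
from .tracker import (DTParams, MotionReport, detect_features,
                      difference_filter, link_tracks, track_statistics)

__all__ = [
    "ScreenConfig",
    "read_manifest",
    "preprocess_movie",
    "analyze_movie_flow",
    "analyze_movie_tracker",
    "run_screen",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Default parameters of the screen pipeline; every value is overridable
    and echoed into the provenance log."""

    bin_factor: int = 4
    register: bool = True
    refine_rotation: bool = False  # translation-only suffices for stage drift
    stretch_factor: int = 2
    crop_flow: int = 450
    crop_track: int = 400
    lk: LKParams = field(default_factory=LKParams)
    histogram: HistogramSpec = field(default_factory=HistogramSpec)
    mask_rule: FrameMaskRule = field(default_factory=FrameMaskRule)
    v_threshold_umps: float = 0.25
    dt: DTParams = field(default_factory=DTParams)
    contrast_saturated: float = 0.05
    contrast_method: str = "sqrt"
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "bin_factor": self.bin_factor,
            "register": self.register,
            "refine_rotation": self.refine_rotation,
            "stretch_factor": self.stretch_factor,
            "crop_flow": self.crop_flow,
            "crop_track": self.crop_track,
            "lk": vars(self.lk).copy() if hasattr(self.lk, "__dict__") else {
                "sigma_s": self.lk.sigma_s, "sigma_t": self.lk.sigma_t,
                "sigma_w": self.lk.sigma_w, "tau": self.lk.tau},
            "histogram": {"n_bins": self.histogram.n_bins,
                          "log_min": self.histogram.log_min,
                          "log_max": self.histogram.log_max},
            "mask_rule": {"k": self.mask_rule.k,
                          "max_reject_fraction": self.mask_rule.max_reject_fraction},
            "v_threshold_umps": self.v_threshold_umps,
            "dt": {k: getattr(self.dt, k) for k in (
                "min_difference", "frame_offset", "min_tracked_intensity",
                "min_feature_size", "initial_flexibility",
                "subsequent_flexibility", "min_track_length")},
            "contrast_saturated": self.contrast_saturated,
            "contrast_method": self.contrast_method,
            "alpha": self.alpha,
        }


MANIFEST_COLUMNS = ["movie_path", "well", "cell_type", "treatment", "phase"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a plate manifest CSV with columns movie_path, well, cell_type,
    treatment, phase (pre/post). (well, phase) pairs must be unique."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    dupes = df.duplicated(subset=["well", "phase"])
    if dupes.any():
        raise ValueError(f"duplicate (well, phase) rows: {df[dupes]}")
    return df


def _maybe(mapper, movie: Movie, condition: bool) -> Movie:
    return mapper(movie) if condition else movie


def preprocess_movie(movie: Movie, config: ScreenConfig = ScreenConfig()) -> Movie:
    """The shared front end: average binning, rigid registration to the first
    frame, quintic temporal stretch. Steps with unit factors are skipped."""
    out = movie
    if config.bin_factor > 1:
        out = pp.bin_spatial(out, config.bin_factor)
    if config.register:
        out, _ = pp.register_rigid(out, 0, refine_rotation=config.refine_rotation)
    if config.stretch_factor > 1:
        out = pp.stretch_time(out, config.stretch_factor)
    return out


def analyze_movie_flow(
    movie: Movie,
    config: ScreenConfig = ScreenConfig(),
    sample_id: str | None = None,
    *,
    preprocessed: bool = False,
) -> tuple[VelocityMontage, FrameMask, np.ndarray]:
    """Flow branch for one movie: returns the normalized montage, the
    artifact retention mask and the per-time flow-ratio series."""
    work = movie if preprocessed else preprocess_movie(movie, config)
    _, h, w = work.shape
    crop = min(config.crop_flow, h, w)
    work = pp.crop_center(work, crop)
    maps = [absolute_velocity(f) for f in flow_movie(work, config.lk)]
    montage = build_montage(maps, config.histogram, work.calibration, sample_id)
    montage = normalize_montage(montage)
    scores = running_sd_scores(montage)
    mask = build_frame_mask(scores, config.mask_rule)
    montage.mask = mask.retained
    ratios = flow_ratio_series(montage, mask, config.v_threshold_umps)
    return montage, mask, ratios


def analyze_movie_tracker(
    movie: Movie,
    config: ScreenConfig = ScreenConfig(),
    *,
    preprocessed: bool = False,
):
    """Tracker branch for one movie: returns (motion report, tracks)."""
    work = movie if preprocessed else preprocess_movie(movie, config)
    _, h, w = work.shape
    crop = min(config.crop_track, h, w)
    work = pp.crop_center(work, crop)
    work = pp.enhance_contrast_8bit(work, config.contrast_saturated,
                                    method=config.contrast_method)
    moving, stats = difference_filter(work, config.dt)
    feats = [detect_features(moving.data[t], t, config.dt)
             for t in range(moving.n_frames)]
    tracks = link_tracks(feats, config.dt)
    report = track_statistics(tracks, feats, stats, work.calibration)
    return report, tracks


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def run_screen(
    manifest: pd.DataFrame,
    out_dir: str | Path,
    config: ScreenConfig = ScreenConfig(),
    calibration: Calibration | None = None,
    movies: dict[str, Movie] | None = None,
    seed: int = 0,
) -> dict:
    """Run the full screen over a plate manifest.

    ``movies`` may supply in-memory movies keyed by movie_path (used by the
    simulation-driven tests); otherwise paths are read as TIFF stacks.
    Writes per-movie intermediates and screen-level flow tables, motion
    reports, statistics and a provenance log under ``out_dir``. Failures are
    isolated per movie.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"config": config.to_dict(), "seed": seed, "movies": {}}
    flow_samples: list[tuple[VelocityMontage, FrameMask]] = []
    sample_meta: list[dict] = []
    reports: dict[str, MotionReport] = {}
    failures: dict[str, str] = {}

    for _, row in manifest.iterrows():
        sid = f"{row['well']}_{row['phase']}"
        try:
            if movies is not None and row["movie_path"] in movies:
                movie = movies[row["movie_path"]]
            else:
                movie = read_movie(row["movie_path"], calibration)
            provenance["movies"][sid] = {
                "path": str(row["movie_path"]),
                "input_hash": _hash_array(movie.data),
            }
            work = preprocess_movie(movie, config)
            montage, mask, _ = analyze_movie_flow(work, config, sid, preprocessed=True)
            report, _ = analyze_movie_tracker(work, config, preprocessed=True)
            flow_samples.append((montage, mask))
            sample_meta.append({
                "sample_id": sid, "well": row["well"],
                "cell_type": row["cell_type"],
                "group": "control" if row["phase"] == "pre" else "treated",
                "treatment": row["treatment"],
            })
            reports[sid] = report
            mask.to_frame().to_csv(out_dir / f"mask_{sid}.csv", index=False)
            montage.to_frame().to_csv(out_dir / f"montage_{sid}.csv", index=False)
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            failures[sid] = f"{type(exc).__name__}: {exc}"
            warnings.warn(f"movie {sid} failed: {exc}")
            provenance["movies"].setdefault(sid, {})["error"] = traceback.format_exc()

    results: dict = {"failures": failures}
    if flow_samples:
        table = build_flow_table(flow_samples, config.v_threshold_umps)
        table.ratios.to_csv(out_dir / "flow_table.csv", index_label="time")
        meta = pd.DataFrame(sample_meta)
        summary = summarize_screen(table, meta)
        summary.to_csv(out_dir / "screen_summary.csv", index=False)
        results["flow_table"] = table
        results["summary"] = summary

        report_df = pd.DataFrame({sid: rep.to_series() for sid, rep in reports.items()})
        report_df.to_csv(out_dir / "motion_reports.csv")
        results["motion_reports"] = reports

        dunnett_frames = []
        for cell_type, grp in meta.groupby("cell_type"):
            ctrl_ids = grp[grp["group"] == "control"]["sample_id"]
            trt_ids = grp[grp["group"] == "treated"]["sample_id"]
            if len(ctrl_ids) >= 2 and len(trt_ids) >= 1:
                controls = [SampleSeries(s, "control",
                                         table.ratios[s].dropna().to_numpy())
                            for s in ctrl_ids]
                treated = [SampleSeries(s, "treated",
                                        table.ratios[s].dropna().to_numpy())
                           for s in trt_ids]
                res = pooled_dunnett(controls, treated, config.alpha, seed=seed)
                df = res.to_frame()
                df.insert(0, "cell_type", cell_type)
                dunnett_frames.append(df)
        if dunnett_frames:
            dunnett_df = pd.concat(dunnett_frames, ignore_index=True)
            dunnett_df.to_csv(out_dir / "dunnett.csv", index=False)
            results["dunnett"] = dunnett_df

    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return results
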