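"""Two-stage difference-based particle tracker.

Stage one, the difference filter, classifies a pixel as moving when its
intensity differs by at least ``min_difference`` from the same pixel
``frame_offset`` frames away (backward or forward, whichever differs more);
everything else is static. This imposes a speed floor: an object must move
about one pixel within the offset window to register, which at the standard
calibration (0.432 um effective pixel, 4-frame offset of 1.75-s stretched
frames = 7 s) is ~0.06 um/s. Stage two detects bright features (8-connected
components) in the moving-only movie and links them greedily into tracks:
longer tracks claim features first, an established track searches around its
constant-velocity prediction within ``subsequent_flexibility`` px, a newborn
track searches within ``initial_flexibility`` px of its seed, and tracks
shorter than ``min_track_length`` are discarded. The output is a motion
report with the static/moving intensity and count split, track counts,
durations and speeds, plus treated/control ratio tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .movie import Calibration, Movie

__all__ = [
    "DTParams",
    "Feature",
    "Track",
    "MotionReport",
    "DifferenceStats",
    "difference_filter",
    "detect_features",
    "link_tracks",
    "track_statistics",
    "treatment_ratio_report",
]

REPORT_FIELDS = [
    "Static Intensity",
    "Moving Intensity",
    "Intensity Percentage Moving",
    "Static Count",
    "Moving Count",
    "Count Percentage Moving",
    "Total Track Count",
    "Average Particle Count Per Frame",
    "Average Track Duration",
    "Average Volume Per Particle",
    "Average Speed Per Track",
    "Average Max Speed Per Track",
]


@dataclass(frozen=True)
class DTParams:
    """Tracker parameters; the defaults assume an 8-bit input movie."""

    min_difference: float = 20.0
    frame_offset: int = 4
    min_tracked_intensity: float = 20.0
    min_feature_size: int = 2
    initial_flexibility: float = 10.0
    subsequent_flexibility: float = 5.0
    min_track_length: int = 4

    def __post_init__(self) -> None:
        for name in ("min_difference", "frame_offset", "min_tracked_intensity",
                     "min_feature_size", "initial_flexibility",
                     "subsequent_flexibility", "min_track_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DifferenceStats:
    """Static/moving intensity sums and object counts accumulated over all
    frames of one movie.

    Moving objects are 8-connected components of the moving partition (pixels
    at or above the ``min_difference`` floor, component intensity at least
    ``min_tracked_intensity``). The static population is counted as intensity
    maxima of the static partition with prominence at least
    ``min_difference``: stationary mitochondria frequently touch, so maxima
    counting (the same idea as the total-mitochondrial-number estimate)
    tracks the number of objects where connected components would merge
    them. The definition in use is recorded here.
    """

    static_intensity: float = 0.0
    moving_intensity: float = 0.0
    static_count: int = 0
    moving_count: int = 0
    count_definition: str = ("moving: 8-connected components >= intensity floor; "
                             "static: intensity maxima with prominence >= floor")

    @property
    def intensity_percentage_moving(self) -> float:
        total = self.static_intensity + self.moving_intensity
        return 100.0 * self.moving_intensity / total if total else 0.0

    @property
    def count_percentage_moving(self) -> float:
        total = self.static_count + self.moving_count
        return 100.0 * self.moving_count / total if total else 0.0


_EIGHT = np.ones((3, 3), dtype=int)


def _count_components(frame: np.ndarray, mask: np.ndarray, params: DTParams) -> int:
    """Components of ``mask`` restricted to pixels >= the intensity floor,
    kept when their summed intensity reaches min_tracked_intensity."""
    sel = mask & (frame >= params.min_difference)
    labels, n = ndimage.label(sel, structure=_EIGHT)
    if n == 0:
        return 0
    sums = ndimage.sum_labels(frame, labels, index=np.arange(1, n + 1))
    return int(np.count_nonzero(sums >= params.min_tracked_intensity))


def _count_static_maxima(frame: np.ndarray, mask: np.ndarray, params: DTParams) -> int:
    """Intensity maxima of the static partition with prominence >= the
    min_difference floor; a connected plateau counts once."""
    from skimage.morphology import h_maxima

    img = np.where(mask, frame, 0.0)
    if img.max() - img.min() <= params.min_difference:
        return 0
    peaks = h_maxima(img, params.min_difference)
    _, n = ndimage.label(peaks, structure=_EIGHT)
    return int(n)


def difference_filter(
    movie: Movie, params: DTParams = DTParams()
) -> tuple[Movie, DifferenceStats]:
    """Temporal difference filter isolating moving objects.

    Requires an 8-bit movie (run enhance_contrast_8bit first). Pixel (t,y,x)
    is moving iff max over the available offsets t +/- frame_offset of
    |I(t) - I(t +/- offset)| >= min_difference; the output movie keeps I(t)
    at moving pixels and zeroes the rest.
    """
    if movie.data.dtype != np.uint8:
        raise ValueError("difference_filter requires an 8-bit movie; convert "
                         "with enhance_contrast_8bit first")
    t = movie.n_frames
    off = params.frame_offset
    if t <= off:
        raise ValueError(f"movie of {t} frames needs more than the {off}-frame offset")
    data = movie.data.astype(np.int16)
    diff = np.zeros(movie.shape, dtype=np.int16)
    if off > 0:
        diff[off:] = np.abs(data[off:] - data[:-off])
        np.maximum(diff[:-off], np.abs(data[:-off] - data[off:]), out=diff[:-off])
    moving_mask = diff >= params.min_difference
    out = np.where(moving_mask, movie.data, 0).astype(np.uint8)

    stats = DifferenceStats()
    frames = movie.data.astype(float)
    stats.moving_intensity = float(frames[moving_mask].sum())
    stats.static_intensity = float(frames[~moving_mask].sum())
    for i in range(t):
        stats.moving_count += _count_components(frames[i], moving_mask[i], params)
        stats.static_count += _count_static_maxima(frames[i], ~moving_mask[i], params)
    moving_movie = movie.with_data(out, "difference_filter",
                                   min_difference=params.min_difference,
                                   frame_offset=params.frame_offset)
    return moving_movie, stats


@dataclass(frozen=True)
class Feature:
    """A detected bright cluster: intensity-weighted centroid (x, y) px,
    pixel area and total intensity."""

    frame: int
    x: float
    y: float
    area: int
    total_intensity: float


def detect_features(
    frame: np.ndarray, frame_index: int = 0, params: DTParams = DTParams()
) -> list[Feature]:
    """8-connected bright clusters with area >= min_feature_size and total
    intensity >= min_tracked_intensity, with intensity-weighted centroids."""
    img = np.asarray(frame, dtype=float)
    labels, n = ndimage.label(img > 0, structure=_EIGHT)
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(img), labels, index=idx)
    sums = ndimage.sum_labels(img, labels, index=idx)
    coms = ndimage.center_of_mass(img, labels, index=idx)  # (row, col)
    feats = []
    for area, total, (cy, cx) in zip(areas, sums, coms):
        if area >= params.min_feature_size and total >= params.min_tracked_intensity:
            feats.append(Feature(frame=frame_index, x=float(cx), y=float(cy),
                                 area=int(area), total_intensity=float(total)))
    return feats


@dataclass
class Track:
    """An ordered run of features in strictly consecutive frames."""

    track_id: int
    features: list[Feature] = field(default_factory=list)

    @property
    def duration(self) -> int:
        return len(self.features)

    @property
    def start_frame(self) -> int:
        return self.features[0].frame

    def positions(self) -> np.ndarray:
        return np.array([(f.x, f.y) for f in self.features])

    def step_displacements_px(self) -> np.ndarray:
        p = self.positions()
        return np.linalg.norm(np.diff(p, axis=0), axis=1)

    def mean_speed_umps(self, calibration: Calibration) -> float:
        steps = self.step_displacements_px()
        return float(calibration.pf_to_umps(steps.mean())) if steps.size else 0.0

    def max_speed_umps(self, calibration: Calibration) -> float:
        steps = self.step_displacements_px()
        return float(calibration.pf_to_umps(steps.max())) if steps.size else 0.0

    @property
    def net_dx(self) -> float:
        return self.features[-1].x - self.features[0].x

    @property
    def direction(self) -> str:
        """Left/right class by sign of net x displacement."""
        return "right" if self.net_dx >= 0 else "left"


def link_tracks(
    features_per_frame: list[list[Feature]],
    params: DTParams = DTParams(),
) -> list[Track]:
    """Greedy priority linking of per-frame features into tracks.

    Per frame, active tracks claim features in descending length order (ties
    broken by lower track id). A one-feature track searches within
    ``initial_flexibility`` px of its seed; an established track predicts its
    next position by its last observed step (constant velocity) and searches
    within ``subsequent_flexibility`` px. Each feature joins at most one
    track; unclaimed features seed new tracks; a track that claims nothing
    terminates. Tracks shorter than ``min_track_length`` are discarded.
    """
    active: list[Track] = []
    finished: list[Track] = []
    next_id = 0
    for feats in features_per_frame:
        unclaimed = list(feats)
        survivors: list[Track] = []
        for track in sorted(active, key=lambda tr: (-tr.duration, tr.track_id)):
            last = track.features[-1]
            if track.duration == 1:
                pred = np.array([last.x, last.y])
                radius = params.initial_flexibility
            else:
                prev = track.features[-2]
                pred = np.array([2 * last.x - prev.x, 2 * last.y - prev.y])
                radius = params.subsequent_flexibility
            best, best_d = None, np.inf
            for f in unclaimed:
                d = float(np.hypot(f.x - pred[0], f.y - pred[1]))
                if d <= radius and d < best_d:
                    best, best_d = f, d
            if best is not None:
                track.features.append(best)
                unclaimed.remove(best)
                survivors.append(track)
            else:
                finished.append(track)
        for f in unclaimed:
            survivors.append(Track(track_id=next_id, features=[f]))
            next_id += 1
        active = survivors
    finished.extend(active)
    return [tr for tr in finished if tr.duration >= params.min_track_length]


@dataclass
class MotionReport:
    """One movie's motion summary in the combined difference-filter /
    particle-tracker layout. Speed fields are NaN when there are no tracks."""

    static_intensity: float
    moving_intensity: float
    intensity_percentage_moving: float
    static_count: int
    moving_count: int
    count_percentage_moving: float
    total_track_count: int
    average_particle_count_per_frame: float
    average_track_duration: float
    average_volume_per_particle: float
    average_speed_per_track: float
    average_max_speed_per_track: float
    count_definition: str = "8-connected components >= intensity floor"

    def to_series(self) -> pd.Series:
        return pd.Series(
            [
                self.static_intensity,
                self.moving_intensity,
                self.intensity_percentage_moving,
                self.static_count,
                self.moving_count,
                self.count_percentage_moving,
                self.total_track_count,
                self.average_particle_count_per_frame,
                self.average_track_duration,
                self.average_volume_per_particle,
                self.average_speed_per_track,
                self.average_max_speed_per_track,
            ],
            index=REPORT_FIELDS,
        )

    @classmethod
    def from_series(cls, s: pd.Series) -> "MotionReport":
        return cls(
            static_intensity=float(s["Static Intensity"]),
            moving_intensity=float(s["Moving Intensity"]),
            intensity_percentage_moving=float(s["Intensity Percentage Moving"]),
            static_count=int(s["Static Count"]),
            moving_count=int(s["Moving Count"]),
            count_percentage_moving=float(s["Count Percentage Moving"]),
            total_track_count=int(s["Total Track Count"]),
            average_particle_count_per_frame=float(s["Average Particle Count Per Frame"]),
            average_track_duration=float(s["Average Track Duration"]),
            average_volume_per_particle=float(s["Average Volume Per Particle"]),
            average_speed_per_track=float(s["Average Speed Per Track"]),
            average_max_speed_per_track=float(s["Average Max Speed Per Track"]),
        )


def track_statistics(
    tracks: list[Track],
    features_per_frame: list[list[Feature]],
    stats: DifferenceStats,
    calibration: Calibration,
) -> MotionReport:
    """Assemble the motion report from linked tracks and filter statistics.

    Speeds are converted to um/s using the effective calibration of the movie
    fed to the tracker (including any temporal stretch). "Volume" is mean
    feature area in px (2-D data).
    """
    n_frames = len(features_per_frame)
    counts = [len(f) for f in features_per_frame]
    all_feats = [f for frame in features_per_frame for f in frame]
    if tracks:
        durations = np.array([tr.duration for tr in tracks], dtype=float)
        speeds = np.array([tr.mean_speed_umps(calibration) for tr in tracks])
        max_speeds = np.array([tr.max_speed_umps(calibration) for tr in tracks])
        avg_dur = float(durations.mean())
        avg_speed = float(speeds.mean())
        avg_max = float(max_speeds.mean())
    else:
        avg_dur = avg_speed = avg_max = float("nan")
    return MotionReport(
        static_intensity=stats.static_intensity,
        moving_intensity=stats.moving_intensity,
        intensity_percentage_moving=stats.intensity_percentage_moving,
        static_count=stats.static_count,
        moving_count=stats.moving_count,
        count_percentage_moving=stats.count_percentage_moving,
        total_track_count=len(tracks),
        average_particle_count_per_frame=float(np.mean(counts)) if n_frames else 0.0,
        average_track_duration=avg_dur,
        average_volume_per_particle=(
            float(np.mean([f.area for f in all_feats])) if all_feats else float("nan")
        ),
        average_speed_per_track=avg_speed,
        average_max_speed_per_track=avg_max,
        count_definition=stats.count_definition,
    )


def treatment_ratio_report(
    control: MotionReport | pd.Series, treated: MotionReport | pd.Series
) -> pd.DataFrame:
    """Side-by-side control/treated report with treated / control ratios,
    rendered to 2 decimals as in the standard combined-output table. Zero
    control denominators give NaN."""
    c = control.to_series() if isinstance(control, MotionReport) else control
    t = treated.to_series() if isinstance(treated, MotionReport) else treated
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np.asarray(c, float) != 0,
                         np.asarray(t, float) / np.asarray(c, float), np.nan)
    if np.any(np.asarray(c, float) == 0):
        import warnings
        warnings.warn("zero control denominator; ratio reported as missing")
    return pd.DataFrame({
        "Control": c,
        "Treated": t,
        "Treated/Control": np.round(ratio, 2),
    })


def render_track_overlay(movie: Movie, tracks: list[Track],
                         path=None) -> np.ndarray:
    """Max-projection of the movie with tracks drawn on top: rightward
    tracks yellow, leftward blue (by sign of net x displacement). Returns
    an RGB uint8 array; writes a PNG when ``path`` is given."""
    proj = movie.data.max(axis=0).astype(float)
    lo, hi = proj.min(), proj.max()
    gray = ((proj - lo) / (hi - lo) * 255 if hi > lo else proj * 0).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    h, w = gray.shape
    for tr in tracks:
        color = (255, 255, 0) if tr.direction == "right" else (0, 128, 255)
        for a, b in zip(tr.features[:-1], tr.features[1:]):
            n = int(max(abs(b.x - a.x), abs(b.y - a.y), 1)) * 2
            xs = np.clip(np.rint(np.linspace(a.x, b.x, n)).astype(int), 0, w - 1)
            ys = np.clip(np.rint(np.linspace(a.y, b.y, n)).astype(int), 0, h - 1)
            rgb[ys, xs] = color
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, rgb)
    return rgb


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to a (track_id, frame, x, y, area, intensity) table."""
    rows = [
        {"track_id": tr.track_id, "frame": f.frame, "x": f.x, "y": f.y,
         "area": f.area, "intensity": f.total_intensity}
        for tr in tracks for f in tr.features
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "area", "intensity"])
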