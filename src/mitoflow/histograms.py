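"""Log-velocity histograms, montages, the running-SD artifact mask and flow
tables.

Per-pixel speeds from the flow stage are natural-log transformed (zeros, i.e.
gated pixels, are treated as missing) and binned into 140 uniform bins on
[-10, 4), covering 0.000045-54.6 px/frame. Stacking one histogram row per
time point gives a velocity histogram montage; after normalizing each row by
its own mean, time points corrupted by illumination flicker or residual stage
drift stand out as rows where the distribution shape changes abruptly. The
running standard deviation over three adjacent rows, summed over bins, scores
each time point; rows scoring above a robust threshold are rejected. The flow
ratio - the fraction of above-gate flow faster than a speed threshold
(default 0.25 um/s) - is then computed per retained time point, and a screen
assembles these series into a time x sample flow table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .lk import AbsVelocityMap
from .movie import Calibration

__all__ = [
    "HistogramSpec",
    "VelocityMontage",
    "FrameMaskRule",
    "FrameMask",
    "FlowTable",
    "log_speed_histogram",
    "build_montage",
    "normalize_montage",
    "running_sd_scores",
    "build_frame_mask",
    "flow_ratio_series",
    "build_flow_table",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Natural-log speed histogram layout: 140 bins on [-10, 4) gives a bin
    width of 0.1 and speed bounds exp(-10)=4.54e-5 to exp(4)=54.6 px/frame."""

    n_bins: int = 140
    log_min: float = -10.0
    log_max: float = 4.0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not self.log_min < self.log_max:
            raise ValueError("log_min must be < log_max")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.log_min, self.log_max, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def speed_bounds_pf(self) -> tuple[float, float]:
        """The speed range covered, in px/frame."""
        return float(np.exp(self.log_min)), float(np.exp(self.log_max))


@dataclass
class VelocityMontage:
    """Time x speed-bin count matrix with its bin edges, calibration,
    normalization state and per-row retention mask."""

    counts: np.ndarray  # (T_valid, n_bins)
    bin_edges: np.ndarray  # natural-log px/frame, length n_bins + 1
    calibration: Calibration
    frame_indices: np.ndarray
    normalized: bool = False
    mask: np.ndarray | None = None  # per-row retention booleans
    sample_id: str | None = None

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin_{i}" for i in range(self.counts.shape[1])]
        df = pd.DataFrame(self.counts, columns=cols)
        df.insert(0, "frame", self.frame_indices)
        return df


def log_speed_histogram(
    velocity_map: AbsVelocityMap | np.ndarray, spec: HistogramSpec = HistogramSpec()
) -> np.ndarray:
    """Histogram of ln(speed) for the nonzero pixels of a speed map.

    Zero (gated) speeds are missing, not observations; speeds outside
    [exp(log_min), exp(log_max)] are dropped. The last bin is right-closed.
    """
    speed = velocity_map.speed if isinstance(velocity_map, AbsVelocityMap) else velocity_map
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speeds must be >= 0")
    pos = speed[speed > 0]
    logs = np.log(pos)
    counts, _ = np.histogram(logs, bins=spec.bin_edges)
    return counts


def build_montage(
    maps: Sequence[AbsVelocityMap],
    spec: HistogramSpec = HistogramSpec(),
    calibration: Calibration = Calibration(),
    sample_id: str | None = None,
) -> VelocityMontage:
    """Stack per-time-point log-speed histograms into a montage, rows ordered
    by frame index."""
    if len(maps) == 0:
        raise ValueError("need at least one velocity map")
    shapes = {m.speed.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent map shapes: {shapes}")
    order = np.argsort([m.frame_index for m in maps])
    maps = [maps[i] for i in order]
    counts = np.stack([log_speed_histogram(m, spec) for m in maps])
    return VelocityMontage(
        counts=counts.astype(float),
        bin_edges=spec.bin_edges,
        calibration=calibration,
        frame_indices=np.array([m.frame_index for m in maps]),
        sample_id=sample_id,
    )


def normalize_montage(m: VelocityMontage) -> VelocityMontage:
    """Divide each row by its own mean so the area under every histogram is
    identical; this factors out the total structure count per frame and keeps
    only the shape of the velocity distribution. Rows with zero mean become
    all-NaN (missing)."""
    if m.normalized:
        raise ValueError("montage is already normalized")
    means = m.counts.mean(axis=1)
    counts = np.full_like(m.counts, np.nan, dtype=float)
    ok = means > 0
    counts[ok] = m.counts[ok] / means[ok, None]
    return replace(m, counts=counts, normalized=True)


def running_sd_scores(m: VelocityMontage) -> np.ndarray:
    """Artifact score per time point: the per-bin population SD over the rows
    {t-1, t, t+1}, summed over bins. End rows use the available 2-row window.
    A time point whose velocity distribution differs sharply from its
    neighbours (flicker, drift) scores high."""
    if not m.normalized:
        raise ValueError("running-SD scores are computed on a normalized montage")
    t = m.n_rows
    if t < 3:
        warnings.warn("fewer than 3 time points; running-SD scores are zero")
        return np.zeros(t)
    counts = np.nan_to_num(m.counts, nan=0.0)
    scores = np.empty(t)
    for i in range(t):
        lo, hi = max(0, i - 1), min(t, i + 2)
        scores[i] = counts[lo:hi].std(axis=0, ddof=0).sum()
    return scores


@dataclass(frozen=True)
class FrameMaskRule:
    """Rejection rule for artifact scores: reject score > median + k * MAD
    (MAD scaled by 1.4826 to an SD equivalent), applied on the log scale by
    default since the running-SD score is a positive, right-skewed statistic
    whose clean-data spread is multiplicative (on the linear scale the same
    rule clips the genuine upper tail of clean samples). If more than
    ``max_reject_fraction`` of rows would be rejected the sample is flagged
    failed instead of silently masked."""

    k: float = 3.0
    max_reject_fraction: float = 0.4
    log_scale: bool = True


@dataclass
class FrameMask:
    """Per-time-point retention decision with its provenance."""

    retained: np.ndarray  # True = keep
    scores: np.ndarray
    threshold: float
    rule: FrameMaskRule = field(default_factory=FrameMaskRule)
    failed: bool = False

    @property
    def n_rejected(self) -> int:
        return int(np.count_nonzero(~self.retained))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": np.arange(len(self.scores)),
            "score": self.scores,
            "retained": self.retained,
        })


def build_frame_mask(
    scores: np.ndarray, rule: FrameMaskRule = FrameMaskRule()
) -> FrameMask:
    """Threshold running-SD scores into a retention mask.

    The threshold median + k*MAD is robust to the minority of contaminated
    rows it is meant to detect; with all-equal scores nothing is rejected.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if rule.log_scale and np.all(scores >= 0):
        eps = 1e-9 * max(float(scores.max()), 1.0)
        work = np.log(scores + eps)
    else:
        work = scores
    med = float(np.median(work))
    mad = float(np.median(np.abs(work - med))) * 1.4826
    work_threshold = med + rule.k * mad
    retained = work <= work_threshold
    threshold = (
        float(np.exp(work_threshold)) if work is not scores else float(work_threshold)
    )
    failed = False
    reject_frac = np.count_nonzero(~retained) / max(1, len(scores))
    if reject_frac > rule.max_reject_fraction:
        failed = True
        warnings.warn(
            f"{reject_frac:.0%} of time points rejected exceeds the "
            f"{rule.max_reject_fraction:.0%} cap; sample flagged as failed"
        )
    return FrameMask(retained=retained, scores=scores, threshold=threshold,
                     rule=rule, failed=failed)


def _threshold_bin_index(m: VelocityMontage, v_threshold_umps: float) -> int:
    """First bin whose left edge is at or above ln(v_threshold) in px/frame
    (the threshold is aligned to the nearest bin edge not below it)."""
    v_pf = float(m.calibration.umps_to_pf(v_threshold_umps))
    log_thr = np.log(v_pf)
    edges = m.bin_edges
    idx = int(np.searchsorted(edges[:-1], log_thr - 1e-12, side="left"))
    return idx


def flow_ratio_series(
    m: VelocityMontage,
    mask: FrameMask | np.ndarray | None = None,
    v_threshold_umps: float = 0.25,
) -> np.ndarray:
    """Fraction of above-gate flow faster than ``v_threshold_umps``, per
    retained time point; masked rows are NaN.

    The denominator is all finite histogram counts in the row (gated
    zero-flow pixels never enter the histogram). The ratio is invariant to
    row normalization.
    """
    retained = (
        mask.retained if isinstance(mask, FrameMask)
        else np.ones(m.n_rows, bool) if mask is None
        else np.asarray(mask, bool)
    )
    if len(retained) != m.n_rows:
        raise ValueError("mask length does not match montage rows")
    idx = _threshold_bin_index(m, v_threshold_umps)
    if idx >= m.counts.shape[1]:
        warnings.warn("speed threshold above histogram range; ratios are zero")
    counts = m.counts
    out = np.full(m.n_rows, np.nan)
    for t in range(m.n_rows):
        if not retained[t]:
            continue
        row = counts[t]
        total = np.nansum(row)
        out[t] = np.nansum(row[idx:]) / total if total > 0 else np.nan
    return out


def write_montage_image(path, m: VelocityMontage, log_intensity: bool = False) -> None:
    """Render a montage as a 32-bit float TIFF (rows = time, columns =
    speed bins). With ``log_intensity`` the pixel values are log1p of the
    counts, which makes the sparse fast-transport bins visible."""
    import tifffile

    img = np.nan_to_num(m.counts, nan=0.0).astype(np.float32)
    if log_intensity:
        img = np.log1p(img)
    tifffile.imwrite(path, img)


@dataclass
class FlowTable:
    """Time x sample matrix of flow ratios (NaN where masked), with
    per-sample retained-row summaries."""

    ratios: pd.DataFrame  # index = time row, columns = sample ids
    summary: pd.DataFrame  # per-sample mean, sd, n_retained
    v_threshold_umps: float = 0.25


def build_flow_table(
    samples: Sequence[tuple[VelocityMontage, FrameMask | None]],
    v_threshold_umps: float = 0.25,
) -> FlowTable:
    """Assemble per-sample flow-ratio series into a screen-level flow table.

    Samples with differing lengths are padded with NaN (and a warning).
    Summaries are computed over retained rows only.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    series = {}
    for i, (montage, mask) in enumerate(samples):
        sid = montage.sample_id or f"sample_{i}"
        series[sid] = flow_ratio_series(montage, mask, v_threshold_umps)
    lengths = {len(v) for v in series.values()}
    if len(lengths) > 1:
        warnings.warn("samples have differing time lengths; padding with NaN")
    n = max(lengths)
    ratios = pd.DataFrame({
        sid: np.concatenate([v, np.full(n - len(v), np.nan)]) for sid, v in series.items()
    })
    summary = pd.DataFrame({
        "mean": ratios.mean(skipna=True),
        "sd": ratios.std(skipna=True, ddof=1),
        "n_retained": ratios.notna().sum(),
    })
    return FlowTable(ratios=ratios, summary=summary, v_threshold_umps=v_threshold_umps)
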