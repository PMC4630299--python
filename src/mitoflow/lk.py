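"""Dense Lucas-Kanade optical flow with structure-tensor noise gating.

For each pixel the brightness-constancy equation Ix*vx + Iy*vy + It = 0 is
solved in the least-squares sense over a small Gaussian window: with window
weights w, form

    G = sum w^2 [[Ix^2, IxIy], [IxIy, Iy^2]],   b = -sum w^2 [IxIt, IyIt]

and emit v = G^-1 b only where the smaller eigenvalue of G is at least the
noise gate tau; everywhere else the pixel reports no flow (v = 0, invalid).
Gradients are Gaussian-derivative filters at spatial scale sigma_s and
temporal scale sigma_t. With sigma_s == sigma_t the flow magnitude is
linearly related to velocity; unequal scales trigger a warning.

tau is a threshold on absolute structure-tensor eigenvalues, so it is tied to
the intensity scale of the input; movies are analyzed at their native
(16-bit-like) scale, under which the default gate tau = 0.02 passes
structured regions while photon/read noise in empty background falls orders
of magnitude below it and yields no output.

The calibration procedure (parameter_sweep / select_parameters) reproduces
the published protocol: sweep the window scale sigma_w over 0.1..1 in 0.1
steps and tau over a 20-value geometric ladder from 1e-5 doubling to 5.24,
then pick the smallest sigma_w that produces flow in a foreground region and
the largest tau that still suppresses all flow in an empty background region
without extinguishing the foreground.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .movie import Movie

__all__ = [
    "LKParams",
    "FlowField",
    "AbsVelocityMap",
    "SweepReport",
    "gaussian_derivatives",
    "temporal_border",
    "lk_flow_frame",
    "flow_movie",
    "absolute_velocity",
    "tau_ladder",
    "parameter_sweep",
    "select_parameters",
    "SelectionError",
]

_DET_EPS = 1e-12


@dataclass(frozen=True)
class LKParams:
    """Flow parameters. Defaults are the calibrated operating point for
    mitochondrial transport movies: sigma_s = sigma_t = 2, sigma_w = 0.3,
    tau = 0.02."""

    sigma_s: float = 2.0
    sigma_t: float = 2.0
    sigma_w: float = 0.3
    tau: float = 0.02
    normal_flow: bool = False  # emit normal flow where only lambda_max passes

    def __post_init__(self) -> None:
        if self.sigma_s <= 0 or self.sigma_t <= 0 or self.sigma_w <= 0:
            raise ValueError("all sigmas must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass
class FlowField:
    """Per-frame flow: vx, vy in px/frame, plus the validity gate mask.
    v = 0 wherever the gate failed."""

    vx: np.ndarray
    vy: np.ndarray
    valid_mask: np.ndarray
    frame_index: int
    n_singular: int = 0


@dataclass
class AbsVelocityMap:
    """Elementwise speed sqrt(vx^2 + vy^2), px/frame; 0 where gated."""

    speed: np.ndarray
    frame_index: int


def temporal_border(sigma_t: float) -> int:
    """Frames within ceil(3 sigma_t) of either end lack full temporal support
    and are excluded from the flow output."""
    return int(np.ceil(3 * sigma_t))


def gaussian_derivatives(
    movie: Movie | np.ndarray, sigma_s: float = 2.0, sigma_t: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Separable Gaussian-derivative gradient volumes (Ix, Iy, It).

    Ix: derivative-of-Gaussian along x, Gaussian smoothing along y and t;
    Iy and It analogous. Kernel half-width is ceil(3 sigma).
    """
    data = movie.data if isinstance(movie, Movie) else np.asarray(movie)
    data = data.astype(float)
    if sigma_s != sigma_t:
        warnings.warn(
            "sigma_s != sigma_t: flow-field intensity will not be linearly "
            "related to velocity",
            stacklevel=2,
        )
    if data.shape[0] < 2 * temporal_border(sigma_t) + 1:
        raise ValueError(
            f"movie of {data.shape[0]} frames is shorter than the temporal "
            f"kernel support ({2 * temporal_border(sigma_t) + 1})"
        )

    def filt(vol, orders):
        out = vol
        for axis, (sigma, order) in enumerate(orders):
            out = ndimage.gaussian_filter1d(
                out, sigma, axis=axis, order=order, mode="nearest", truncate=3.0
            )
        return out

    ix = filt(data, [(sigma_t, 0), (sigma_s, 0), (sigma_s, 1)])
    iy = filt(data, [(sigma_t, 0), (sigma_s, 1), (sigma_s, 0)])
    it = filt(data, [(sigma_t, 1), (sigma_s, 0), (sigma_s, 0)])
    return ix, iy, it


def _window_kernel(sigma_w: float) -> np.ndarray:
    """Squared Gaussian window weights w^2 on an odd support of half-width
    max(1, ceil(3 sigma_w)); 3x3 at the default sigma_w = 0.3."""
    r = max(1, int(np.ceil(3 * sigma_w)))
    x = np.arange(-r, r + 1)
    w = np.exp(-(x**2) / (2 * sigma_w**2))
    return w**2


def _window_smooth(img: np.ndarray, w2: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(img, w2, axis=0, mode="nearest")
    return ndimage.correlate1d(out, w2, axis=1, mode="nearest")


def _tensor_fields(ix, iy, it, frame: int, sigma_w: float):
    """Windowed structure-tensor entries and RHS at one frame."""
    w2 = _window_kernel(sigma_w)
    gx, gy, gt = ix[frame], iy[frame], it[frame]
    a = _window_smooth(gx * gx, w2)
    b = _window_smooth(gx * gy, w2)
    c = _window_smooth(gy * gy, w2)
    bx = -_window_smooth(gx * gt, w2)
    by = -_window_smooth(gy * gt, w2)
    return a, b, c, bx, by


def _solve_gated(a, b, c, bx, by, tau: float, normal_flow: bool):
    """Closed-form 2x2 solve with the eigenvalue gate."""
    half_tr = 0.5 * (a + c)
    disc = np.sqrt((0.5 * (a - c)) ** 2 + b**2)
    lmin = half_tr - disc
    lmax = half_tr + disc
    det = a * c - b * b

    full = lmin >= tau
    solvable = full & (np.abs(det) > _DET_EPS)
    n_singular = int(np.count_nonzero(full & ~solvable))
    vx = np.zeros_like(a)
    vy = np.zeros_like(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        vx[solvable] = (c[solvable] * bx[solvable] - b[solvable] * by[solvable]) / det[solvable]
        vy[solvable] = (a[solvable] * by[solvable] - b[solvable] * bx[solvable]) / det[solvable]
    valid = solvable
    if normal_flow:
        # Where only the larger eigenvalue passes, project b onto the dominant
        # eigenvector: the component of motion along the gradient direction.
        normal = (~full) & (lmax >= tau)
        if np.any(normal):
            # Dominant eigenvector of [[a, b], [b, c]] for eigenvalue lmax.
            ex = np.where(np.abs(b) > _DET_EPS, b, lmax - c)
            ey = np.where(np.abs(b) > _DET_EPS, lmax - a, b)
            norm = np.hypot(ex, ey)
            ok = normal & (norm > _DET_EPS) & (lmax > _DET_EPS)
            ex, ey = ex / np.where(norm > 0, norm, 1), ey / np.where(norm > 0, norm, 1)
            proj = (bx * ex + by * ey) / np.where(lmax > 0, lmax, 1)
            vx = np.where(ok, proj * ex, vx)
            vy = np.where(ok, proj * ey, vy)
            valid = valid | ok
    return vx, vy, valid, n_singular


def lk_flow_frame(
    gradients: tuple[np.ndarray, np.ndarray, np.ndarray],
    frame: int,
    params: LKParams = LKParams(),
) -> FlowField:
    """Flow field at one frame from precomputed gradient volumes."""
    ix, iy, it = gradients
    border = temporal_border(params.sigma_t)
    if not border <= frame < ix.shape[0] - border:
        raise ValueError(
            f"frame {frame} outside the temporally valid range "
            f"[{border}, {ix.shape[0] - border})"
        )
    a, b, c, bx, by = _tensor_fields(ix, iy, it, frame, params.sigma_w)
    vx, vy, valid, n_singular = _solve_gated(a, b, c, bx, by, params.tau, params.normal_flow)
    return FlowField(vx=vx, vy=vy, valid_mask=valid, frame_index=frame,
                     n_singular=n_singular)


def flow_movie(movie: Movie, params: LKParams = LKParams()) -> list[FlowField]:
    """Flow fields for every temporally valid frame of a movie.

    Frames within the temporal kernel half-support of either end are
    excluded, so a T-frame movie yields T - 2*ceil(3 sigma_t) fields.
    """
    gradients = gaussian_derivatives(movie, params.sigma_s, params.sigma_t)
    border = temporal_border(params.sigma_t)
    t = movie.n_frames
    return [lk_flow_frame(gradients, f, params) for f in range(border, t - border)]


def absolute_velocity(fld: FlowField) -> AbsVelocityMap:
    """Speed map sqrt(vx^2 + vy^2); gated pixels are exactly 0."""
    speed = np.hypot(fld.vx, fld.vy)
    speed[~fld.valid_mask] = 0.0
    return AbsVelocityMap(speed=speed, frame_index=fld.frame_index)


def tau_ladder(start: float = 1e-5, ratio: float = 2.0, n: int = 20) -> np.ndarray:
    """Geometric tau grid; the default 20-value doubling ladder runs from
    1e-5 to 5.24."""
    return start * ratio ** np.arange(n)


@dataclass
class SweepReport:
    """Grid of (sigma_w, tau) flow summaries over a foreground ROI (contains
    moving structure) and a background ROI (empty)."""

    table: pd.DataFrame  # columns: sigma_w, tau, roi, n_valid, total_flow, mean_speed
    histograms: dict = field(default_factory=dict)  # (sigma_w, tau, roi) -> counts
    bin_edges: np.ndarray | None = None


def _roi_slices(roi) -> tuple[slice, slice]:
    y0, y1, x0, x1 = roi
    return slice(y0, y1), slice(x0, x1)


def parameter_sweep(
    movie: Movie,
    sigma_w_values=None,
    tau_values=None,
    base: LKParams = LKParams(),
    *,
    foreground_roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int],
    hist_bins: int = 140,
    hist_range: tuple[float, float] = (-10.0, 4.0),
) -> SweepReport:
    """Compute flow over a (sigma_w, tau) grid and summarize both ROIs.

    ROIs are (y0, y1, x0, x1) half-open pixel boxes. Gradients depend only on
    sigma_s/sigma_t and are shared; the tau gate is a pure threshold on the
    eigenvalue map, so each sigma_w costs one tensor pass.
    """
    if sigma_w_values is None:
        sigma_w_values = np.round(np.arange(0.1, 1.0 + 1e-9, 0.1), 10)
    if tau_values is None:
        tau_values = tau_ladder()
    sigma_w_values = np.asarray(list(sigma_w_values), dtype=float)
    tau_values = np.asarray(list(tau_values), dtype=float)
    if sigma_w_values.size == 0 or tau_values.size == 0:
        raise ValueError("sigma_w and tau value lists must be nonempty")
    _, h, w = movie.shape
    for roi in (foreground_roi, background_roi):
        y0, y1, x0, x1 = roi
        if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
            raise ValueError(f"ROI {roi} outside image of shape {(h, w)}")

    gradients = gaussian_derivatives(movie, base.sigma_s, base.sigma_t)
    border = temporal_border(base.sigma_t)
    frames = range(border, movie.n_frames - border)
    edges = np.linspace(hist_range[0], hist_range[1], hist_bins + 1)

    rows = []
    histograms: dict = {}
    rois = {"foreground": _roi_slices(foreground_roi),
            "background": _roi_slices(background_roi)}
    for sw in sigma_w_values:
        per_frame = []
        for f in frames:
            a, b, c, bx, by = _tensor_fields(*gradients, f, sw)
            half_tr = 0.5 * (a + c)
            disc = np.sqrt((0.5 * (a - c)) ** 2 + b**2)
            lmin = half_tr - disc
            det = a * c - b * b
            vx = np.zeros_like(a)
            vy = np.zeros_like(a)
            ok = np.abs(det) > _DET_EPS
            vx[ok] = (c[ok] * bx[ok] - b[ok] * by[ok]) / det[ok]
            vy[ok] = (a[ok] * by[ok] - b[ok] * bx[ok]) / det[ok]
            per_frame.append((lmin, ok, np.hypot(vx, vy)))
        for tau in tau_values:
            for name, (ys, xs) in rois.items():
                n_valid = 0
                total = 0.0
                speeds_all = []
                for lmin, ok, speed in per_frame:
                    valid = (lmin[ys, xs] >= tau) & ok[ys, xs]
                    s = speed[ys, xs][valid]
                    n_valid += int(valid.sum())
                    total += float(s.sum())
                    speeds_all.append(s)
                speeds = np.concatenate(speeds_all) if speeds_all else np.empty(0)
                pos = speeds[speeds > 0]
                counts, _ = np.histogram(np.log(pos) if pos.size else pos, bins=edges)
                histograms[(float(sw), float(tau), name)] = counts
                rows.append({
                    "sigma_w": float(sw), "tau": float(tau), "roi": name,
                    "n_valid": n_valid, "total_flow": total,
                    "mean_speed": total / n_valid if n_valid else 0.0,
                })
    return SweepReport(table=pd.DataFrame(rows), histograms=histograms, bin_edges=edges)


class SelectionError(RuntimeError):
    pass


def select_parameters(report: SweepReport) -> tuple[float, float]:
    """Pick (sigma_w, tau) from a sweep: the smallest sigma_w whose foreground
    ROI produces flow, then the largest tau at that sigma_w with zero valid
    background pixels and nonzero foreground flow."""
    t = report.table
    if not {"foreground", "background"} <= set(t["roi"].unique()):
        raise SelectionError("sweep report must summarize both ROIs")
    fg = t[t["roi"] == "foreground"]
    bg = t[t["roi"] == "background"]
    for sw in sorted(fg["sigma_w"].unique()):
        if fg[fg["sigma_w"] == sw]["n_valid"].max() > 0:
            sigma_w = sw
            break
    else:
        raise SelectionError(
            "no sigma_w in the grid produced foreground flow; diagnostics: "
            f"max foreground n_valid per sigma_w = "
            f"{fg.groupby('sigma_w')['n_valid'].max().to_dict()}"
        )
    fg_sw = fg[fg["sigma_w"] == sigma_w].set_index("tau")["n_valid"]
    bg_sw = bg[bg["sigma_w"] == sigma_w].set_index("tau")["n_valid"]
    admissible = [
        tau for tau in fg_sw.index
        if bg_sw.get(tau, 0) == 0 and fg_sw[tau] > 0
    ]
    if not admissible:
        raise SelectionError(
            f"no tau at sigma_w={sigma_w} suppresses the background while "
            f"keeping foreground flow; background n_valid = {bg_sw.to_dict()}"
        )
    return float(sigma_w), float(max(admissible))
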