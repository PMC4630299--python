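"""Movie pre-conditioning: binning, rigid registration, temporal stretching,
cropping, contrast normalization, background subtraction, maxima counting and
kymograph rendering.

The standard chain for the flow pipeline is: bin 4x (average) -> rigid-body
registration against the first frame -> 2x temporal stretch with a quintic
B-spline -> centered crop (450 px for the flow path, 400 px for the tracker
path). Each operation updates the movie's history and, where relevant, its
calibration, so px/frame velocities downstream always convert correctly to
um/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import make_interp_spline
from skimage import exposure
from skimage.measure import profile_line
from skimage.morphology import h_maxima
from skimage.registration import phase_cross_correlation

from .movie import Calibration, Movie

__all__ = [
    "RigidTransform",
    "bin_spatial",
    "register_rigid",
    "stretch_time",
    "crop_center",
    "enhance_contrast_8bit",
    "subtract_mean_projection",
    "count_maxima",
    "velocity_umps",
    "umps_to_pf",
    "kymograph",
    "rayleigh_limit_nm",
]


@dataclass(frozen=True)
class RigidTransform:
    """Per-frame rigid motion (dx, dy in px, theta in radians) relative to the
    reference frame. Applying the inverse to the frame aligns it to the
    reference."""

    dx: float
    dy: float
    theta: float

    @property
    def is_identity(self) -> bool:
        return self.dx == 0.0 and self.dy == 0.0 and self.theta == 0.0


class RegistrationError(RuntimeError):
    pass


def bin_spatial(movie: Movie, factor: int) -> Movie:
    """Average-bin each frame by ``factor`` in x and y.

    Trailing rows/columns are trimmed first if the size is not divisible.
    Each output pixel is the arithmetic mean of its factor x factor block.
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    t, h, w = movie.shape
    h2, w2 = (h // factor) * factor, (w // factor) * factor
    data = movie.data[:, :h2, :w2].astype(float)
    data = data.reshape(t, h2 // factor, factor, w2 // factor, factor).mean(axis=(2, 4))
    out = movie.with_data(data, "bin_spatial", factor=factor)
    return out.with_calibration(movie.calibration.binned(factor))


def _warp_rigid(frame: np.ndarray, dx: float, dy: float, theta: float) -> np.ndarray:
    """Resample ``frame`` by the inverse of the rigid motion (dx, dy, theta),
    rotation about the image centre, bilinear interpolation, edge replicate."""
    h, w = frame.shape
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    cos, sin = np.cos(theta), np.sin(theta)
    # Output (row, col) -> input coords: rotate about centre then translate.
    rot = np.array([[cos, -sin], [sin, cos]])
    offset = c - rot @ c + np.array([dy, dx])
    return ndimage.affine_transform(frame, rot, offset=offset, order=1, mode="nearest")


def register_rigid(
    movie: Movie,
    reference: int = 0,
    *,
    refine_rotation: bool = True,
    upsample_factor: int = 100,
    min_shift_px: float = 0.05,
) -> tuple[Movie, list[RigidTransform]]:
    """Rigid-body registration of every frame to a reference frame.

    Translation is initialized by windowed cross-correlation; (dx, dy) and,
    with ``refine_rotation``, theta are then refined by Powell minimization
    of the mean-squared intensity difference. Frames whose initial estimate
    falls below ``min_shift_px`` are passed through unresampled:
    interpolating to correct sub-noise shifts only blurs the frame and
    perturbs downstream temporal differences.
    """
    t = movie.n_frames
    if t < 2:
        raise ValueError("need at least 2 frames to register")
    ref = movie.data[reference].astype(float)
    if not np.any(ref):
        raise RegistrationError(f"reference frame {reference} is all-zero")
    # Hann window downweights the border content, which does not translate
    # with the scene under replicate-edge fill and otherwise biases the
    # correlation peak toward zero shift.
    h, w = ref.shape
    window = np.outer(np.hanning(h), np.hanning(w))
    ref_w = (ref - ref.mean()) * window
    transforms: list[RigidTransform] = []
    out = np.empty_like(movie.data, dtype=float)
    for i in range(t):
        frame = movie.data[i].astype(float)
        if i == reference:
            transforms.append(RigidTransform(0.0, 0.0, 0.0))
            out[i] = frame
            continue
        if not np.any(frame):
            raise RegistrationError(f"frame {i} is all-zero; cannot register")
        shift, _, _ = phase_cross_correlation(
            ref_w, (frame - frame.mean()) * window,
            upsample_factor=upsample_factor, normalization=None)
        # phase_cross_correlation returns the shift to apply to `frame` to
        # match `ref`; the frame's motion relative to ref is the negative.
        dx, dy, theta = -float(shift[1]), -float(shift[0]), 0.0
        if np.hypot(dx, dy) < min_shift_px:
            transforms.append(RigidTransform(0.0, 0.0, 0.0))
            out[i] = frame
            continue

        def cost(p: np.ndarray) -> float:
            warped = _warp_rigid(frame, p[0], p[1], p[2] if len(p) > 2 else 0.0)
            return float(np.mean((warped - ref) ** 2))

        x0 = np.array([dx, dy, theta] if refine_rotation else [dx, dy])
        res = optimize.minimize(cost, x0, method="Powell",
                                options={"xtol": 1e-3, "ftol": 1e-8,
                                         "maxiter": 200})
        dx, dy = float(res.x[0]), float(res.x[1])
        theta = float(res.x[2]) if refine_rotation else 0.0
        if np.hypot(dx, dy) < min_shift_px and abs(theta) < np.deg2rad(0.01):
            transforms.append(RigidTransform(0.0, 0.0, 0.0))
            out[i] = frame
            continue
        transforms.append(RigidTransform(dx, dy, theta))
        out[i] = _warp_rigid(frame, dx, dy, theta)
    movie_out = movie.with_data(
        out, "register_rigid", reference=reference, refine_rotation=refine_rotation
    )
    return movie_out, transforms


def stretch_time(movie: Movie, factor: int) -> Movie:
    """Stretch the movie along t by an integer factor with a quintic B-spline.

    Output frame j samples the per-pixel spline at time j/factor; the
    trailing half-open tail beyond the last acquired frame is edge-clamped.
    For a per-pixel polynomial of degree <= 5 (constants, linear ramps, ...)
    the inserted frames are exact.
    """
    if factor < 1:
        raise ValueError("stretch factor must be >= 1")
    if factor == 1:
        return movie.with_data(movie.data.astype(float), "stretch_time", factor=1)
    t = movie.n_frames
    k = min(5, t - 1)
    spline = make_interp_spline(np.arange(t), movie.data.astype(float), k=k, axis=0)
    times = np.clip(np.arange(factor * t) / factor, 0, t - 1)
    data = spline(times)
    out = movie.with_data(data, "stretch_time", factor=factor)
    return out.with_calibration(movie.calibration.stretched(factor))


def crop_center(movie: Movie, out_size: int | tuple[int, int]) -> Movie:
    """Centered crop to ``out_size`` (h, w). With an odd remainder the extra
    pixel is removed from the right/bottom, so output pixel (0, 0) maps to
    input pixel (margin_top, margin_left) with margin = (in - out) // 2."""
    if isinstance(out_size, int):
        out_size = (out_size, out_size)
    oh, ow = out_size
    _, h, w = movie.shape
    if oh > h or ow > w:
        raise ValueError(f"crop size {out_size} exceeds input {(h, w)}")
    y0, x0 = (h - oh) // 2, (w - ow) // 2
    data = movie.data[:, y0 : y0 + oh, x0 : x0 + ow]
    return movie.with_data(data, "crop_center", out_size=list(out_size))


def enhance_contrast_8bit(
    movie: Movie, saturated_fraction: float = 0.05, *, method: str = "sqrt"
) -> Movie:
    """Stack-wide percentile contrast stretch + histogram equalization + 8-bit.

    ``saturated_fraction`` of pixels (split between both ends) is clipped
    before the stretch. ``method`` selects the equalization weighting:
    ``"sqrt"`` (default) equalizes against the square root of the histogram,
    which flattens the histogram while damping the over-amplification of a
    dominant background band; ``"classic"`` is textbook CDF equalization;
    ``"none"`` applies the percentile stretch only. Percentiles and the
    equalization CDF are computed over the whole stack, not per frame, so
    genuine global-intensity artifacts (flicker) are not silently normalized
    away. A constant movie returns mid-gray with a warning flag in the
    history.
    """
    if not 0 <= saturated_fraction < 0.5:
        raise ValueError("saturated_fraction must be in [0, 0.5)")
    if method not in ("sqrt", "classic", "none"):
        raise ValueError("method must be 'sqrt', 'classic' or 'none'")
    data = movie.data.astype(float)
    lo = np.percentile(data, 100 * saturated_fraction / 2)
    hi = np.percentile(data, 100 * (1 - saturated_fraction / 2))
    if hi <= lo:
        out = np.full(movie.shape, 128, dtype=np.uint8)
        return movie.with_data(out, "enhance_contrast_8bit",
                               saturated_fraction=saturated_fraction, degenerate=True)
    clipped = np.clip(data, lo, hi)
    if method == "none":
        eq = (clipped - lo) / (hi - lo)
    elif method == "classic":
        eq = exposure.equalize_hist(clipped)  # stack-wide CDF, output in [0, 1]
    else:
        hist, edges = np.histogram(clipped, bins=256, range=(lo, hi))
        weights = np.sqrt(hist.astype(float))
        cdf = np.cumsum(weights)
        cdf = cdf / cdf[-1]
        # Monotone piecewise-linear map: each bin's upper edge -> its CDF.
        eq = np.interp(clipped, edges[1:], cdf)
    out = np.clip(np.rint(eq * 255), 0, 255).astype(np.uint8)
    return movie.with_data(out, "enhance_contrast_8bit",
                           saturated_fraction=saturated_fraction, method=method)


def subtract_mean_projection(movie: Movie) -> Movie:
    """Subtract the temporal mean projection from every frame (clip at 0).

    Stationary structures cancel; only transient (moving) intensity remains.
    Adding a constant to every frame leaves the output unchanged.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames")
    mean = movie.data.astype(float).mean(axis=0)
    data = np.clip(movie.data.astype(float) - mean, 0, None)
    return movie.with_data(data, "subtract_mean_projection")


def count_maxima(
    frame: np.ndarray, upscale_factor: int = 8, noise_tolerance: float = 100.0
) -> int:
    """Count local intensity maxima with prominence above ``noise_tolerance``.

    The frame is first upscaled by a quintic B-spline (the estimation of total
    mitochondrial number works on an 8x-stretched image); maxima are the
    connected plateaus surviving an h-maxima transform with h equal to the
    tolerance, so a flat plateau counts once.
    """
    if upscale_factor < 1:
        raise ValueError("upscale_factor must be >= 1")
    img = np.asarray(frame, dtype=float)
    if img.max() - img.min() <= noise_tolerance:
        return 0
    if upscale_factor > 1:
        img = ndimage.zoom(img, upscale_factor, order=5, mode="mirror")
    peaks = h_maxima(img, noise_tolerance)
    _, n = ndimage.label(peaks)
    return int(n)


def velocity_umps(v_pf: float | np.ndarray, calibration: Calibration):
    """Convert pixels/frame to um/s under the movie's effective calibration."""
    return calibration.pf_to_umps(v_pf)


def umps_to_pf(v_umps: float | np.ndarray, calibration: Calibration):
    """Convert um/s to pixels/frame under the movie's effective calibration."""
    return calibration.umps_to_pf(v_umps)


def rayleigh_limit_nm(wavelength_nm: float = 532.0, na: float = 0.95) -> float:
    """Rayleigh resolution limit 0.61 * lambda / NA, in nm."""
    if na <= 0:
        raise ValueError("numerical aperture must be positive")
    return 0.61 * wavelength_nm / na


def kymograph(movie: Movie, path: np.ndarray, width: int = 1) -> np.ndarray:
    """Position x time image sampled along a polyline.

    Column t is the maximum-intensity profile across the ``width``-px band
    perpendicular to the path, sampled along the path. A moving object
    appears as a ridge whose slope is its velocity in px/frame.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 2:
        raise ValueError("path must be an (n, 2) polyline of (x, y) points")
    _, h, w = movie.shape
    if (path[:, 0].min() < 0 or path[:, 0].max() >= w
            or path[:, 1].min() < 0 or path[:, 1].max() >= h):
        raise ValueError("path outside frame bounds")
    columns = []
    for t in range(movie.n_frames):
        segs = []
        for a, b in zip(path[:-1], path[1:]):
            # profile_line takes (row, col) endpoints.
            prof = profile_line(
                movie.data[t].astype(float), (a[1], a[0]), (b[1], b[0]),
                linewidth=width, reduce_func=np.max, mode="nearest",
            )
            segs.append(prof)
        columns.append(np.concatenate(segs))
    n = min(len(c) for c in columns)
    return np.stack([c[:n] for c in columns], axis=1)
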