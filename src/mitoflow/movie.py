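"""Movie container and spatial/temporal calibration.

A movie is a single-channel T x H x W intensity stack. All pixel <-> micron
and frame <-> second conversions go through :class:`Calibration`, which keeps
track of the acquisition pixel size and frame interval together with any
spatial binning and temporal stretching applied during preprocessing, so that
velocities measured in pixels/frame on a processed stack can always be mapped
back to um/s.

Coordinate convention: arrays are indexed ``[t, y, x]`` with y (rows)
increasing downward and x (columns) increasing rightward, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

__all__ = ["Calibration", "Movie", "read_movie", "write_movie"]


@dataclass(frozen=True)
class Calibration:
    """Acquisition calibration plus the preprocessing state that modifies it.

    Parameters
    ----------
    pixel_size_um
        Raw acquisition pixel size in micrometres per pixel.
    frame_interval_s
        Raw acquisition frame interval in seconds.
    bin_factor
        Cumulative spatial binning applied (1 before binning).
    time_stretch
        Cumulative temporal stretch applied (1 before stretching).
    """

    pixel_size_um: float = 0.108
    frame_interval_s: float = 3.5
    bin_factor: int = 1
    time_stretch: int = 1

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.bin_factor < 1 or self.time_stretch < 1:
            raise ValueError("bin_factor and time_stretch must be >= 1")

    @property
    def effective_pixel_um(self) -> float:
        """Pixel size of the (possibly binned) stack, um/px."""
        return self.pixel_size_um * self.bin_factor

    @property
    def effective_interval_s(self) -> float:
        """Frame interval of the (possibly stretched) stack, s/frame."""
        return self.frame_interval_s / self.time_stretch

    def pf_to_umps(self, v_pf: float | np.ndarray) -> float | np.ndarray:
        """Convert a velocity in pixels/frame to um/s."""
        return np.multiply(v_pf, self.effective_pixel_um / self.effective_interval_s)

    def umps_to_pf(self, v_umps: float | np.ndarray) -> float | np.ndarray:
        """Convert a velocity in um/s to pixels/frame."""
        return np.multiply(v_umps, self.effective_interval_s / self.effective_pixel_um)

    def binned(self, factor: int) -> "Calibration":
        return replace(self, bin_factor=self.bin_factor * factor)

    def stretched(self, factor: int) -> "Calibration":
        return replace(self, time_stretch=self.time_stretch * factor)


@dataclass
class Movie:
    """A single-channel time-lapse stack with calibration and provenance.

    ``history`` is an ordered list of descriptors (name + parameters) of every
    operation applied; it grows by one entry per operation and is sufficient
    to replay the preprocessing chain.
    """

    data: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)
    history: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 and self.data.ndim != 3:
            raise ValueError("movie data must be T x H x W (or a single frame)")
        if self.data.ndim == 2:
            self.data = self.data[None]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, op: str, **params: Any) -> "Movie":
        """Return a new movie with ``data``, appending ``op`` to the history."""
        hist = list(self.history) + [{"op": op, **params}]
        return Movie(data=data, calibration=self.calibration, history=hist)

    def with_calibration(self, calibration: Calibration) -> "Movie":
        return Movie(data=self.data, calibration=calibration, history=list(self.history))

    def copy(self) -> "Movie":
        return Movie(
            data=self.data.copy(),
            calibration=self.calibration,
            history=[dict(h) for h in self.history],
        )


def write_movie(path: str | Path, movie: Movie, dtype: np.dtype | None = None) -> None:
    """Write a movie as a multi-page TIFF with a YAML calibration sidecar."""
    path = Path(path)
    data = movie.data
    if dtype is not None:
        info = np.iinfo(dtype) if np.issubdtype(dtype, np.integer) else None
        if info is not None:
            data = np.clip(np.rint(data), info.min, info.max)
        data = data.astype(dtype)
    tifffile.imwrite(path, data)
    sidecar = {
        "calibration": {
            "pixel_size_um": movie.calibration.pixel_size_um,
            "frame_interval_s": movie.calibration.frame_interval_s,
            "bin_factor": movie.calibration.bin_factor,
            "time_stretch": movie.calibration.time_stretch,
        },
        "history": movie.history,
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_movie(path: str | Path, calibration: Calibration | None = None) -> Movie:
    """Read a multi-page TIFF; the YAML sidecar supplies calibration if present."""
    path = Path(path)
    data = tifffile.imread(path)
    history: list[dict[str, Any]] = []
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if calibration is None and sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        calibration = Calibration(**meta.get("calibration", {}))
        history = list(meta.get("history", []))
    return Movie(data=data, calibration=calibration or Calibration(), history=history)
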