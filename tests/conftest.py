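"""Shared fixtures: synthetic scenes and screen runs reused across tests.

Expensive end-to-end computations (the 8-well screen, the artifact-injected
montage) are session-scoped so each is computed once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mitoflow import (Calibration, absolute_velocity, build_frame_mask,
                      build_montage, flow_movie, inject_artifacts,
                      make_scene_movie, normalize_montage, running_sd_scores)
from mitoflow.pipeline import ScreenConfig, run_screen
from mitoflow.synthetic import ArtifactSpec, binned_scene_config, screen_well_config

BINNED_CAL = Calibration(pixel_size_um=0.432, frame_interval_s=3.5)


@pytest.fixture(scope="session")
def binned_cal() -> Calibration:
    return BINNED_CAL


@pytest.fixture(scope="session")
def synthetic_screen_config() -> ScreenConfig:
    """Analysis configuration for movies generated at the binned scale:
    no further binning, and contrast standardization by percentile stretch
    only (synthetic movies share one known intensity scale)."""
    return ScreenConfig(bin_factor=1, contrast_method="none")


@pytest.fixture(scope="session")
def artifact_montage():
    """100-frame dense scene with a 5-frame cluster of flicker/drift
    artifacts, flowed and converted to a normalized montage with scores."""
    cfg = binned_scene_config(n_frames=100, n_stationary=250, n_moving=2, seed=11)
    movie, gt = make_scene_movie(cfg)
    spec = ArtifactSpec(
        flicker_frames=((44, 1.5), (46, 0.65), (48, 1.4)),
        drift_frames=((45, 2.0, -1.5), (47, -1.5, 1.0)),
    )
    contaminated, gt2 = inject_artifacts(movie, spec, gt)
    maps = [absolute_velocity(f) for f in flow_movie(contaminated)]
    montage = normalize_montage(build_montage(maps, calibration=contaminated.calibration))
    scores = running_sd_scores(montage)
    mask = build_frame_mask(scores)
    return {
        "montage": montage,
        "scores": scores,
        "mask": mask,
        "artifact_frames": sorted(gt2.artifact_frames),
    }


def build_screen_movies(base_seed: int, n_wells: int = 8):
    """8 wells: 4 pre-drug controls (6 movers) and 4 treated (3 movers)."""
    movies, rows = {}, []
    for i in range(n_wells):
        treated = i >= n_wells // 2
        cfg = screen_well_config(3 if treated else 6, seed=base_seed * 100 + i)
        movie, _ = make_scene_movie(cfg)
        key = f"well{i}"
        movies[key] = movie
        rows.append({
            "movie_path": key,
            "well": f"W{i % (n_wells // 2)}",
            "cell_type": "hippocampal",
            "treatment": "nocodazole" if treated else "none",
            "phase": "post" if treated else "pre",
        })
    return movies, pd.DataFrame(rows)


@pytest.fixture(scope="session")
def screen_result(tmp_path_factory, synthetic_screen_config):
    """Full 8-well screen (control 6 movers vs treated 3 movers)."""
    movies, manifest = build_screen_movies(base_seed=5)
    out = tmp_path_factory.mktemp("screen")
    res = run_screen(manifest, out, synthetic_screen_config, movies=movies, seed=5)
    res["out_dir"] = out
    res["manifest"] = manifest
    return res


def mover_speed_mode(v_pf: float, seed: int, n_frames: int = 40) -> float:
    """Mode of the above-gate log-speed distribution for two full-length
    movers at ``v_pf`` px/frame (no stationary spots)."""
    v = BINNED_CAL.pf_to_umps(v_pf)
    cfg = binned_scene_config(
        image_size=(128, 128), n_frames=n_frames, n_stationary=0, n_moving=2,
        mover_speeds_umps=(v, v),
        run_pause_schedule=(((0, n_frames, (v, 0.0)),), ((0, n_frames, (0.0, v)),)),
        seed=seed,
    )
    movie, _ = make_scene_movie(cfg)
    speeds = np.concatenate(
        [absolute_velocity(f).speed[f.valid_mask] for f in flow_movie(movie)]
    )
    pos = speeds[speeds > 0]
    hist, edges = np.histogram(np.log(pos), bins=140, range=(-10, 4))
    i = int(hist.argmax())
    return float(np.exp(0.5 * (edges[i] + edges[i + 1])))
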