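# mitoflow

Automated quantification of fast mitochondrial transport in time-lapse
fluorescence movies.

Neurons move mitochondria along axons and dendrites at roughly 0.1–2 μm/s,
and this fast transport is disrupted in many neurological diseases, which
makes it an attractive readout for drug screens. Screening hundreds of wells
on a robotic microscope, however, produces far more movies than anyone can
track by hand. `mitoflow` implements an automated analysis pipeline for such
screens, aimed at researchers quantifying organelle motility in
MitoTracker-labelled neuronal cultures:

* **Dense Lucas–Kanade optical flow** with Gaussian-derivative gradients and
  a structure-tensor noise gate. For each pixel the brightness-constancy
  equation `Ix·vx + Iy·vy + It = 0` is solved over a Gaussian window by
  forming `G = Σ w²·∇I∇Iᵀ` and `b = −Σ w²·∇I·It`; a velocity `v = G⁻¹b`
  (px/frame) is emitted only where the smaller eigenvalue of `G` is at least
  the gate τ, so empty background reports no motion. Defaults:
  Σs = Σt = 2, Σw = 0.3, τ = 0.02.
* **Log-velocity histogram montages**: per-frame histograms of ln(speed)
  (140 bins on [−10, 4), i.e. speeds 0.000045–54.6 px/frame), normalized per
  time point, stacked into a time × velocity-bin matrix.
* **Automated artifact rejection**: a running standard deviation of the
  velocity histograms over three adjacent time points, summed over bins,
  scores each frame; frames corrupted by illumination flicker or residual
  stage drift score high and are masked by a robust
  median + 3·MAD rule (applied on the log scale).
* **Flow tables and screen statistics**: the fraction of above-gate flow
  faster than a threshold (default 0.25 μm/s) per retained time point and
  sample, compared across treatments with a pooled-control Dunnett
  many-to-one procedure (family-wise 95% confidence intervals).
* **A difference-based particle tracker**: a temporal difference filter
  isolates objects that move at least ~1 pixel within a 4-frame offset
  window (≈0.06 μm/s at the standard calibration), and a greedy
  priority-ordered linker assembles the detected features into tracks,
  yielding static/moving intensity and count splits, track counts, durations
  and speeds.
* **A synthetic-movie generator** with exact ground truth (mover
  trajectories and speeds, artifact frames) that emulates the screen's
  acquisition conditions, so every stage is testable without microscope
  data.

## Worked example

Simulate a well, analyze it, and read off how much fast transport it
contains:

```python
import numpy as np
from mitoflow import make_scene_movie
from mitoflow.pipeline import ScreenConfig, analyze_movie_flow, analyze_movie_tracker
from mitoflow.synthetic import screen_well_config

config = ScreenConfig(bin_factor=1, contrast_method="none")  # synthetic movies
movie, truth = make_scene_movie(screen_well_config(6, seed=1))

montage, mask, ratios = analyze_movie_flow(movie, config)
print(f"flow ratio > 0.25 um/s: {np.nanmean(ratios):.4f}")
print(f"time points retained:   {mask.retained.sum()} / {len(mask.retained)}")

report, tracks = analyze_movie_tracker(movie, config)
print(f"tracks: {report.total_track_count}, "
      f"mean speed {report.average_speed_per_track:.2f} um/s")
```

prints

```
flow ratio > 0.25 um/s: 0.0070
time points retained:   108 / 108
tracks: 21, mean speed 0.32 um/s
```

The flow ratio says ~0.7% of the above-gate pixels in this well move faster
than 0.25 μm/s (six movers at 0.4 μm/s among 250 stationary mitochondria);
the artifact mask found nothing to reject in this clean well; the tracker
followed the movers' transport bouts as 21 tracks averaging 0.32 μm/s
(slightly under the true 0.4 μm/s — automated estimators systematically
undershoot manual tracking).

A full screen runs from a plate manifest, via the library
(`mitoflow.pipeline.run_screen`) or the CLI:

```bash
mitoflow simulate well_A1.tif --seed 1
mitoflow run-screen manifest.csv results/ --seed 1
```

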