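"""Screen-level statistics: pooled-control Dunnett comparisons, Welch
t-tests and per-sample summaries.

The screening design rescans the same wells before (control) and after
treatment; control wells are pooled into a single reference group and every
treated sample is compared against it with Dunnett's many-to-one procedure,
which controls the family-wise error rate at the stated level across all
simultaneous comparisons. Observations within a series are the per-time-point
flow ratios of one well (or per-well summary values, depending on the chosen
experimental unit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .histograms import FlowTable

__all__ = [
    "SampleSeries",
    "DunnettResult",
    "pooled_dunnett",
    "two_sample_t",
    "summarize_screen",
    "DegenerateVarianceError",
]


@dataclass
class SampleSeries:
    """One sample's observations for inference."""

    sample_id: str
    group: str  # "control" or "treated"
    values: np.ndarray
    cell_type: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.values = self.values[np.isfinite(self.values)]

    @property
    def n(self) -> int:
        return len(self.values)


class DegenerateVarianceError(ValueError):
    pass


@dataclass
class DunnettResult:
    """Per-treated-sample mean differences vs the pooled control with
    simultaneous two-sided CIs at family level alpha; a sample is significant
    iff its CI excludes 0."""

    sample_ids: list[str]
    mean_diff: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return (self.ci_lower > 0) | (self.ci_upper < 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.sample_ids,
            "mean_diff": self.mean_diff,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_value": self.p_values,
            "significant": self.significant,
        })


def pooled_dunnett(
    controls: Sequence[SampleSeries],
    treated: Sequence[SampleSeries],
    alpha: float = 0.05,
    seed: int | None = None,
) -> DunnettResult:
    """Dunnett many-to-one comparison of each treated sample against the
    pooled control.

    Control series are concatenated into one reference group (their order is
    irrelevant); critical points come from the equicorrelated multivariate-t
    distribution, so the confidence intervals are simultaneous at family
    level ``alpha``. ``seed`` fixes the quasi-random integration of the
    multivariate-t quantile.
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 control samples to pool")
    if len(treated) < 1:
        raise ValueError("need at least 1 treated sample")
    for s in list(controls) + list(treated):
        if s.n < 2:
            raise ValueError(f"sample {s.sample_id} has n < 2")
    pooled = np.concatenate([s.values for s in controls])
    groups = [s.values for s in treated]
    if np.ptp(pooled) == 0 and all(np.ptp(g) == 0 for g in groups):
        raise DegenerateVarianceError("all observations identical; variance is zero")
    rng = np.random.default_rng(seed if seed is not None else 0)
    res = sps.dunnett(*groups, control=pooled, alternative="two-sided", rng=rng)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return DunnettResult(
        sample_ids=[s.sample_id for s in treated],
        mean_diff=np.array([g.mean() - pooled.mean() for g in groups]),
        ci_lower=np.asarray(ci.low),
        ci_upper=np.asarray(ci.high),
        p_values=np.asarray(res.pvalue),
        alpha=alpha,
    )


def two_sample_t(a: SampleSeries, b: SampleSeries) -> tuple[float, float, float]:
    """Two-sided Welch t-test of b vs a.

    Returns (t, p, percent change) where percent change is
    100 * (mean_b - mean_a) / mean_a.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both series need n >= 2")
    if np.ptp(a.values) == 0 and np.ptp(b.values) == 0:
        if a.values.mean() == b.values.mean():
            return 0.0, 1.0, 0.0
        raise DegenerateVarianceError("zero variance with unequal means")
    t, p = sps.ttest_ind(b.values, a.values, equal_var=False)
    pct = 100.0 * (b.values.mean() - a.values.mean()) / a.values.mean()
    return float(t), float(p), float(pct)


def summarize_screen(flow_table: FlowTable, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-sample summaries (mean, SD, 95% CI, n retained) joined with the
    manifest's well / group / cell-type labels, ready for box plots.

    ``manifest`` must map every flow-table column through a ``sample_id``
    column and carry ``group`` (and optionally ``cell_type``, ``well``).
    """
    required = {"sample_id", "group"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    meta = manifest.set_index("sample_id")
    missing = [c for c in flow_table.ratios.columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples missing from manifest: {missing}")
    rows = []
    for sid in flow_table.ratios.columns:
        vals = flow_table.ratios[sid].dropna().to_numpy()
        n = len(vals)
        mean = vals.mean() if n else np.nan
        sd = vals.std(ddof=1) if n > 1 else 0.0
        half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n) if n > 1 else 0.0
        row = {
            "sample_id": sid,
            "group": meta.loc[sid, "group"],
            "mean": mean, "sd": sd,
            "ci_lower": mean - half, "ci_upper": mean + half,
            "n_retained": n,
        }
        if "cell_type" in meta.columns:
            row["cell_type"] = meta.loc[sid, "cell_type"]
        if "well" in meta.columns:
            row["well"] = meta.loc[sid, "well"]
        rows.append(row)
    return pd.DataFrame(rows)
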