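"""Short-term pilot-evaluation statistics for monthly cancer-incidence series.

A one-month awareness campaign should appear in registry data as a step in the
monthly count of symptomatic diagnoses shortly after launch. The detection
statistic is a one-sample t test of the candidate month against the preceding
baseline months, using the prediction-variance inflation factor sqrt(1 + 1/n)
(the candidate month is a new observation, not the baseline mean). Two
descriptive excesses accompany the test: the year-on-year change against the
same calendar month one year earlier, and the excess over baseline mean + 2 sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PilotSeries",
    "StepTestResult",
    "step_change_ttest",
    "year_on_year_increase",
    "pooled_and_regional_tests",
]


@dataclass(frozen=True)
class PilotSeries:
    """Monthly diagnosis counts for one or more regions.

    ``counts`` has shape (n_regions, n_months); ``months`` is the calendar
    index 0..n_months-1. ``campaign_start`` marks the month the campaign
    launched (None if not applicable).
    """

    counts: np.ndarray
    regions: tuple[str, ...]
    campaign_start: int | None = None

    def __post_init__(self) -> None:
        counts = np.atleast_2d(np.asarray(self.counts))
        object.__setattr__(self, "counts", counts)
        if counts.shape[0] != len(self.regions):
            raise ValueError("one region name per row of counts required")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.campaign_start is not None and not (
            0 <= self.campaign_start < counts.shape[1]
        ):
            raise ValueError("campaign_start outside series range")

    @property
    def n_months(self) -> int:
        return self.counts.shape[1]

    @property
    def months(self) -> np.ndarray:
        return np.arange(self.n_months)

    @property
    def pooled(self) -> np.ndarray:
        """Counts summed across regions."""
        return self.counts.sum(axis=0)

    def to_frame(self):
        """Tidy DataFrame with columns month, region, count."""
        import pandas as pd

        rows = [
            {"month": m, "region": r, "count": int(self.counts[i, m])}
            for i, r in enumerate(self.regions)
            for m in range(self.n_months)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StepTestResult:
    t_statistic: float
    p_value: float
    baseline_mean: float
    baseline_sd: float
    observed: float
    n_baseline: int
    pct_vs_same_month_prior_year: float
    pct_vs_mean_plus_2sd: float


def step_change_ttest(
    counts: np.ndarray,
    test_month: int,
    baseline_start: int = 0,
    inflate_prediction_variance: bool = True,
) -> StepTestResult:
    """Test whether one month's count steps above the preceding baseline.

    t = (observed - mean) / (sd * sqrt(1 + 1/n)) with n-1 degrees of freedom
    and a two-sided p-value. Set ``inflate_prediction_variance=False`` for the
    plain z-style statistic (observed - mean) / sd.
    """
    counts = np.asarray(counts, dtype=float)
    if not (0 <= test_month < counts.size):
        raise ValueError("test_month outside series")
    baseline = counts[baseline_start:test_month]
    n = baseline.size
    if n < 3:
        raise ValueError("need at least 3 baseline months before the test month")
    mean = float(baseline.mean())
    sd = float(baseline.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate baseline: zero variance")
    obs = float(counts[test_month])
    scale = sd * np.sqrt(1.0 + 1.0 / n) if inflate_prediction_variance else sd
    t = (obs - mean) / scale
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    try:
        yoy = year_on_year_increase(counts, test_month)
    except ValueError:
        yoy = float("nan")
    threshold = mean + 2.0 * sd
    pct_2sd = (obs - threshold) / threshold if threshold > 0 else float("nan")
    return StepTestResult(
        t_statistic=float(t),
        p_value=p,
        baseline_mean=mean,
        baseline_sd=sd,
        observed=obs,
        n_baseline=n,
        pct_vs_same_month_prior_year=float(yoy),
        pct_vs_mean_plus_2sd=float(pct_2sd),
    )


def year_on_year_increase(counts: np.ndarray, month: int) -> float:
    """Relative change against the same calendar month one year earlier."""
    counts = np.asarray(counts, dtype=float)
    prior = month - 12
    if prior < 0:
        raise ValueError("no prior-year month in the series")
    if counts[prior] <= 0:
        raise ValueError("prior-year count is zero; relative change undefined")
    return float((counts[month] - counts[prior]) / counts[prior])


def pooled_and_regional_tests(
    series: PilotSeries,
    test_month: int,
    baseline_start: int = 0,
    inflate_prediction_variance: bool = True,
) -> dict[str, StepTestResult]:
    """Step-change test per region and on the region-summed series.

    Returns a mapping region-name -> result, plus key ``"pooled"``. With a
    single region the pooled result equals the regional one.
    """
    out: dict[str, StepTestResult] = {}
    for i, region in enumerate(series.regions):
        out[region] = step_change_ttest(
            series.counts[i], test_month, baseline_start, inflate_prediction_variance
        )
    out["pooled"] = step_change_ttest(
        series.pooled, test_month, baseline_start, inflate_prediction_variance
    )
    return out
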