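"""Virtual liquid biopsy of the placenta: aggregate biomarker measurements
expressed as percent of gestational-age-matched control levels and analyze
their gestational-age trends with a 12-week split.

The measurement table has one row per published observation: study id, marker
id, gestational week, percent-of-control, and optionally the sample size.
Trends are Pearson correlations of percent-of-control against week, computed
per marker (a pooled option exists).  The trimester summary bins measurements
into half-open [start, 12) and [12, end] windows and labels each side as
below / at / above control (100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "percent_of_control",
    "ga_trend",
    "trimester_summary",
    "select_panel",
    "plot_trend",
]

MEASUREMENT_COLUMNS = ("study", "marker", "week", "percent_of_control")


@dataclass(frozen=True)
class TrendResult:
    """Gestational-age trend of one biomarker."""

    marker: str
    pearson_r: float
    p_value: float
    n_points: int
    first_trimester_mean: float | None
    post12_slope_sign: int  # sign of the post-12-week regression slope

    def __post_init__(self) -> None:
        if not (-1.0 <= self.pearson_r <= 1.0):
            raise ValueError("Pearson r outside [-1, 1]")


def percent_of_control(case_level: float, control_level: float) -> float:
    """Case level as a percentage of the control level."""
    if control_level <= 0:
        raise ValueError("control level must be positive")
    return 100.0 * case_level / control_level


def _validate(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns {missing}")
    if (measurements["percent_of_control"] <= 0).any():
        raise ValueError("percent_of_control must be positive")
    return measurements


def ga_trend(
    measurements: pd.DataFrame,
    marker: str | None = None,
    cutoff_week: float = 12.0,
    weight_by_n: bool = False,
) -> TrendResult:
    """Pearson correlation of percent-of-control with gestational week.

    ``marker`` selects one marker from the table; omit it to pool all rows
    (used when a panel is analyzed jointly).  With ``weight_by_n`` each
    measurement is replicated in proportion to its reported sample size
    (weighted Pearson; aggregation is unweighted by default).
    """
    df = _validate(measurements)
    if marker is not None:
        df = df[df["marker"] == marker]
        label = marker
    else:
        label = "pooled"
    weeks = df["week"].to_numpy(dtype=float)
    percent = df["percent_of_control"].to_numpy(dtype=float)
    if np.unique(weeks).size < 3:
        raise ValueError("need measurements at >= 3 distinct weeks")
    if np.ptp(percent) == 0:
        raise ValueError("undefined correlation: constant percent values")
    if weight_by_n:
        if "n" not in df.columns or df["n"].isna().any():
            raise ValueError("weight_by_n requires an 'n' column without missing values")
        w = df["n"].to_numpy(dtype=float)
        r = _weighted_pearson(weeks, percent, w)
        # p from the effective number of measurements (Kish)
        n_eff = w.sum() ** 2 / (w**2).sum()
        t = r * np.sqrt(max(n_eff - 2, 1) / max(1 - r**2, 1e-300))
        p = float(2 * stats.t.sf(abs(t), max(n_eff - 2, 1)))
    else:
        r, p = stats.pearsonr(weeks, percent)
    early = percent[weeks < cutoff_week]
    late_mask = weeks >= cutoff_week
    slope_sign = 0
    if late_mask.sum() >= 2 and np.ptp(weeks[late_mask]) > 0:
        slope = stats.linregress(weeks[late_mask], percent[late_mask]).slope
        slope_sign = int(np.sign(slope))
    return TrendResult(
        marker=label,
        pearson_r=float(r),
        p_value=float(p),
        n_points=len(df),
        first_trimester_mean=float(early.mean()) if early.size else None,
        post12_slope_sign=slope_sign,
    )


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = (w * x).sum(), (w * y).sum()
    cov = (w * (x - mx) * (y - my)).sum()
    sx = np.sqrt((w * (x - mx) ** 2).sum())
    sy = np.sqrt((w * (y - my) ** 2).sum())
    return float(cov / (sx * sy))


def select_panel(atlas, genes: Sequence[str] | None = None, min_score: float = 1.4) -> list[str]:
    """Biopsy panel selection: genes whose placental enrichment score (target
    over mean of other tissues) reaches ``min_score``."""
    from .tissue_specificity import enrichment_score

    if genes is None:
        genes = list(atlas.matrix.index)
    return [g for g in genes if enrichment_score(atlas, g) >= min_score]


def _direction(mean_percent: float, tol: float = 1e-9) -> str:
    if mean_percent > 100.0 + tol:
        return "above control"
    if mean_percent < 100.0 - tol:
        return "below control"
    return "at control"


def trimester_summary(measurements: pd.DataFrame, cutoff_week: float = 12.0) -> pd.DataFrame:
    """Per-marker mean percent-of-control before and after the cutoff week.

    Bins are half-open: [start, cutoff) and [cutoff, end].  A side with no
    data is reported as absent (NaN mean, direction "absent").
    """
    df = _validate(measurements)
    rows = []
    for marker, sub in df.groupby("marker", sort=True):
        early = sub.loc[sub["week"] < cutoff_week, "percent_of_control"]
        late = sub.loc[sub["week"] >= cutoff_week, "percent_of_control"]
        rows.append(
            {
                "marker": marker,
                "early_mean": float(early.mean()) if len(early) else np.nan,
                "early_n": len(early),
                "early_direction": _direction(early.mean()) if len(early) else "absent",
                "late_mean": float(late.mean()) if len(late) else np.nan,
                "late_n": len(late),
                "late_direction": _direction(late.mean()) if len(late) else "absent",
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def plot_trend(measurements: pd.DataFrame, marker: str, ax=None):
    """Scatter of percent-of-control against gestational week with the 100%
    control reference line."""
    import matplotlib.pyplot as plt

    df = _validate(measurements)
    df = df[df["marker"] == marker]
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(df["week"], df["percent_of_control"], s=18)
    ax.axhline(100.0, linestyle="--", color="grey", label="control level")
    ax.set_xlabel("gestational age (weeks)")
    ax.set_ylabel("% of control")
    ax.set_title(marker)
    return ax
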