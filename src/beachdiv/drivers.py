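"""Beach physical characteristics and driver statistics.

Width of the active intertidal zone, mean sand grain size and macrophyte
wrack cover are the physical variables that structure sandy-beach
communities.  This module computes them from their raw measurements
(sieve-mass fractions, line-intercept transect segments), compares periods
(percent difference, one-way ANOVA on fall-survey values) and regresses
area-adjusted richness on each characteristic by OLS.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "SieveSample",
    "BeachCharacteristics",
    "AnovaResult",
    "RegressionResult",
    "arithmetic_mean_grain_size",
    "wrack_cover",
    "percent_difference",
    "one_way_anova",
    "ols_fit",
    "driver_regressions",
    "in_fall_window",
    "FALL_WINDOW",
]

logger = logging.getLogger(__name__)

# fall survey window (month numbers, inclusive); Aug-Nov by default, the
# Aug-Dec alternative is selectable
FALL_WINDOW = (8, 11)


@dataclass(frozen=True)
class SieveSample:
    """Masses retained on a graded sieve stack plus the pan.

    ``apertures_mm`` are the sieve openings in decreasing order;
    ``masses_g`` has one extra entry for the pan fraction (grains finer
    than the smallest sieve).
    """

    apertures_mm: tuple[float, ...]
    masses_g: tuple[float, ...]

    def __post_init__(self) -> None:
        ap = np.asarray(self.apertures_mm, dtype=float)
        ms = np.asarray(self.masses_g, dtype=float)
        if len(ms) != len(ap) + 1:
            raise ValueError("masses_g must have one more entry than apertures (pan)")
        if np.any(ap <= 0) or np.any(np.diff(ap) >= 0):
            raise ValueError("apertures_mm must be positive and strictly decreasing")
        if np.any(ms < 0):
            raise ValueError("masses_g must be non-negative")
        if ms.sum() <= 0:
            raise ValueError("total sieve mass must be > 0")


@dataclass(frozen=True)
class BeachCharacteristics:
    """Per site x period physical summary used by the driver regressions."""

    site: str
    period: str
    intertidal_width_m: float
    mean_grain_mm: float
    wrack_cover_m2_per_m: float = float("nan")  # recent period only

    def __post_init__(self) -> None:
        if self.intertidal_width_m <= 0:
            raise ValueError(f"{self.site}: intertidal width must be > 0")
        if self.mean_grain_mm <= 0:
            raise ValueError(f"{self.site}: mean grain size must be > 0")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def arithmetic_mean_grain_size(s: SieveSample) -> float:
    """Mass-weighted arithmetic mean grain size (mm).

    Each retained fraction is assigned the arithmetic midpoint of its size
    class: the open-ended top class gets 1.5x the top aperture, interior
    classes the midpoint of the bounding apertures, and the pan half the
    smallest aperture.
    """
    ap = np.asarray(s.apertures_mm, dtype=float)
    mids = np.empty(len(ap) + 1)
    mids[0] = 1.5 * ap[0]
    mids[1:-1] = (ap[:-1] + ap[1:]) / 2.0
    mids[-1] = ap[-1] / 2.0
    ms = np.asarray(s.masses_g, dtype=float)
    return float((ms * mids).sum() / ms.sum())


def wrack_cover(transects: Sequence[Sequence[float]]) -> float:
    """Line-intercept wrack cover (m² of wrack per m of shoreline).

    Each transect contributes the sum of its intercept segment lengths; the
    site value is the arithmetic mean over transects.
    """
    if not transects:
        raise ValueError("wrack_cover requires at least one transect")
    covers = []
    for i, segs in enumerate(transects):
        segs = np.asarray(list(segs), dtype=float)
        if np.any(segs < 0):
            raise ValueError(f"transect {i}: negative intercept length")
        covers.append(segs.sum() if segs.size else 0.0)
    return float(np.mean(covers))


def percent_difference(mean_hist: float, mean_recent: float) -> float:
    """Signed percent difference of a characteristic, historical baseline."""
    if mean_hist <= 0:
        raise ValueError("historical mean must be > 0")
    return 100.0 * (mean_recent - mean_hist) / mean_hist


def in_fall_window(date: _dt.date, window: tuple[int, int] = FALL_WINDOW) -> bool:
    """True when a survey date falls in the configured fall-survey months."""
    lo, hi = window
    return lo <= date.month <= hi


def one_way_anova(values: Iterable[float], labels: Iterable) -> AnovaResult:
    """One-way fixed-effects ANOVA across groups defined by ``labels``.

    Matches the classical sum-of-squares decomposition (two-group F equals
    the squared pooled t statistic).  Zero within-group variance with
    unequal group means is degenerate: F is infinite and p reported as 0
    with the ``degenerate`` flag set.
    """
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(labels))
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    n = values.size
    if n - len(groups) < 1:
        raise ValueError("ANOVA requires at least one within-group degree of freedom")
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = n - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(
            F=float("inf"), df_between=df_b, df_within=df_w, p=0.0, degenerate=True
        )
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(st.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def ols_fit(x: Iterable[float], y: Iterable[float]) -> RegressionResult:
    """Simple OLS of y on x with intercept; two-sided slope p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("OLS requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is not identifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p=float(model.pvalues[1]),
        n=int(x.size),
    )


def driver_regressions(
    characteristics: Sequence[BeachCharacteristics],
    adjusted_richness: pd.DataFrame,
    predictors: tuple[str, ...] = (
        "mean_grain_mm",
        "intertidal_width_m",
        "wrack_cover_m2_per_m",
    ),
) -> pd.DataFrame:
    """OLS of adjusted richness on each beach characteristic, per group.

    ``adjusted_richness`` is tidy with columns site, group, S_adj (one value
    per site per group).  Sites missing a predictor are dropped from that
    predictor's regressions with a logged warning.  Returns a tidy table of
    slope/intercept/r²/p/n per (predictor, group).
    """
    chars = pd.DataFrame([vars(c) for c in characteristics])
    if chars.duplicated(subset=["site"]).any():
        raise ValueError("one BeachCharacteristics row per site expected")
    merged = adjusted_richness.merge(chars, on="site", how="left")

    rows = []
    for predictor, group in product(predictors, adjusted_richness["group"].unique()):
        sub = merged[merged["group"] == group][["site", predictor, "S_adj"]]
        dropped = sub[sub[predictor].isna()]["site"].tolist()
        if dropped:
            logger.warning(
                "predictor %s missing for sites %s; dropped from regression",
                predictor,
                dropped,
            )
        sub = sub.dropna(subset=[predictor, "S_adj"])
        if len(sub) < 3:
            raise ValueError(
                f"regression of S_adj on {predictor} ({group}): only "
                f"{len(sub)} sites remain after drops"
            )
        fit = ols_fit(sub[predictor], sub["S_adj"])
        rows.append(
            {
                "predictor": predictor,
                "group": group,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p": fit.p,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)
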