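"""Two-period richness comparison on species–area curves.

Effort differed enormously between survey periods (a site's historical
cumulative area can exceed its recent area several-fold, or vice versa), so
raw richness values are not comparable.  The comparison instead reads the
recent-period species–area curve at the *historical* cumulative area
("adjusted richness"), expresses change as a signed percentage of the
historical value, and calls the change significant when the historical
richness falls outside the recent curve's 95% confidence band at that area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    CurvePoint,
    RarefactionCurve,
    richness_at_effort,
)
from .incidence import (
    IncidenceMatrix,
    SpeciesTrait,
    select_max_area_design,
    subset_by_group,
    summarize_incidence,
    wrack_zone_area,
)

__all__ = [
    "HistoricalPoint",
    "ChangeResult",
    "ChangeConfig",
    "ChangeSummary",
    "adjusted_richness_at_area",
    "percent_change",
    "classify_change",
    "compare_periods",
    "summarize_changes",
    "format_summary",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

IMPACT_CATEGORIES = ("none", "groomed_fill", "fill_pipes", "orv_recovery", "habitat_loss")


@dataclass(frozen=True)
class HistoricalPoint:
    """Cumulative observed richness and sampled area from the earlier period."""

    site: str
    group: str
    S_hist: int
    A_hist: float

    def __post_init__(self) -> None:
        if self.A_hist <= 0:
            raise ValueError(f"{self.site}/{self.group}: A_hist must be > 0")
        if self.S_hist < 0:
            raise ValueError(f"{self.site}/{self.group}: S_hist must be >= 0")


@dataclass(frozen=True)
class ChangeResult:
    site: str
    group: str
    S_hist: int
    A_hist: float
    S_adj: float
    ci_low: float
    ci_high: float
    pct_change: float
    direction: str  # increase | decrease | none
    significant: bool
    mode: str  # rarefied | extrapolated
    impact_category: str = "none"


@dataclass
class ChangeConfig:
    """Knobs of the two-period comparison."""

    groups: tuple[str, ...] = ("overall", "wrack")
    ci_level: float = 0.95
    bootstrap_B: int = 200
    seed: int = 0
    impact_categories: dict[str, str] = field(default_factory=dict)
    # wrack-group area basis: restrict to the upper-beach wrack zone
    # ("wrack_zone") or use the full active-intertidal areas ("total")
    wrack_area_basis: str = "wrack_zone"


def adjusted_richness_at_area(
    curve: RarefactionCurve,
    A_hist: float,
    bootstrap_B: int = 200,
    seed: int = 0,
) -> CurvePoint:
    """Read the curve at a cumulative area (m²), converting via mean unit area."""
    if A_hist <= 0:
        raise ValueError("A_hist must be > 0")
    s = curve.summary
    t = A_hist / s.a_bar
    return richness_at_effort(
        s, t, ci_level=curve.ci_level, bootstrap_B=bootstrap_B, seed=seed
    )


def percent_change(S_hist: float, S_adj: float) -> float:
    """Signed percent change with the historical richness as baseline.

    Positive = richness gain over time; negative = loss.  Undefined for a
    zero baseline: returns NaN (reported downstream as "not estimable").
    """
    if S_hist == 0:
        return math.nan
    if S_hist < 0:
        raise ValueError("S_hist must be >= 0")
    return 100.0 * (S_adj - S_hist) / S_hist


def classify_change(S_hist: float, point: CurvePoint) -> tuple[str, bool]:
    """Direction and significance from the CI-position rule.

    Historical richness above the band means richness *declined* to the
    recent period; below the band means it increased.  Inside the band
    (bounds inclusive) the change is not significant and direction follows
    the sign of the adjusted-minus-historical difference.
    """
    if not (np.isfinite(point.ci_low) and np.isfinite(point.ci_high)):
        raise ValueError("curve point must carry a finite confidence interval")
    if S_hist > point.ci_high:
        return "decrease", True
    if S_hist < point.ci_low:
        return "increase", True
    diff = point.S_t - S_hist
    if diff > 0:
        return "increase", False
    if diff < 0:
        return "decrease", False
    return "none", False


def _recent_group_matrix(
    m: IncidenceMatrix,
    traits: dict[str, SpeciesTrait],
    group: str,
    wrack_area_basis: str,
) -> IncidenceMatrix:
    """Restrict the recent matrix to a group's species (and wrack zone)."""
    sub = subset_by_group(m, traits, group)
    if group == "overall" or wrack_area_basis != "wrack_zone":
        return sub
    # wrack-zone restriction: drop units seaward of the lowest wrack sample
    if sub.n_species == 0 or not sub.detections.any():
        return sub.restrict_units(np.zeros(sub.n_units, dtype=bool))
    positions = np.array([u.cross_shore_position_m for u in sub.units])
    edge = positions[sub.detections.any(axis=0)].max()
    return sub.restrict_units(positions <= edge)


def compare_periods(
    historical: list[HistoricalPoint],
    recent: dict[str, IncidenceMatrix],
    traits: dict[str, SpeciesTrait],
    config: ChangeConfig | None = None,
) -> list[ChangeResult]:
    """Adjusted-richness comparison for every historical site x group point.

    For each point: keep the recent sampling design with the greatest
    cumulative area, restrict to the group's species (wrack groups also
    restrict to the upper-beach wrack zone by default), build the incidence
    summary, read richness with CI at the historical cumulative area, and
    classify the change.
    """
    config = config or ChangeConfig()
    missing = sorted({h.site for h in historical} - set(recent))
    if missing:
        raise KeyError(f"no recent-period data for sites: {missing}")

    results: list[ChangeResult] = []
    for h in historical:
        m = recent[h.site]
        kept = select_max_area_design(m.units)
        kept_ids = {u.unit_id for u in kept}
        m_design = m.restrict_units([u.unit_id in kept_ids for u in m.units])
        sub = _recent_group_matrix(m_design, traits, h.group, config.wrack_area_basis)
        cat = config.impact_categories.get(h.site, "none")

        if sub.n_units == 0 or not sub.detections.any():
            # group absent from the recent sample: adjusted richness is 0
            pct = percent_change(h.S_hist, 0.0)
            direction, significant = (
                ("decrease", True) if h.S_hist > 0 else ("none", False)
            )
            results.append(
                ChangeResult(
                    site=h.site,
                    group=h.group,
                    S_hist=h.S_hist,
                    A_hist=h.A_hist,
                    S_adj=0.0,
                    ci_low=0.0,
                    ci_high=0.0,
                    pct_change=pct,
                    direction=direction,
                    significant=significant,
                    mode="rarefied",
                    impact_category=cat,
                )
            )
            continue

        s = summarize_incidence(sub)
        t = h.A_hist / s.a_bar
        point = richness_at_effort(
            s,
            t,
            ci_level=config.ci_level,
            bootstrap_B=config.bootstrap_B,
            seed=config.seed,
        )
        direction, significant = classify_change(h.S_hist, point)
        results.append(
            ChangeResult(
                site=h.site,
                group=h.group,
                S_hist=h.S_hist,
                A_hist=h.A_hist,
                S_adj=point.S_t,
                ci_low=point.ci_low,
                ci_high=point.ci_high,
                pct_change=percent_change(h.S_hist, point.S_t),
                direction=direction,
                significant=significant,
                mode="extrapolated" if point.mode == "extrapolated" else "rarefied",
                impact_category=cat,
            )
        )
    return results


def historical_points_from_matrices(
    matrices: dict[str, IncidenceMatrix],
    traits: dict[str, SpeciesTrait],
    groups: tuple[str, ...] = ("overall", "wrack"),
    wrack_area_basis: str = "wrack_zone",
) -> list[HistoricalPoint]:
    """Cumulative richness and sampled area per site x group, one period.

    Overall groups use the full cumulative (active-intertidal) area; wrack
    groups use the upper-beach wrack-zone area by default.  Site x group
    combinations with zero sampled area or no detected species yield no
    point (there is no baseline to compare against) and are logged.
    """
    points: list[HistoricalPoint] = []
    for site, m in sorted(matrices.items()):
        for group in groups:
            sub = subset_by_group(m, traits, group)
            s_hist = int(sub.detections.any(axis=1).sum())
            if group == "overall" or wrack_area_basis != "wrack_zone":
                a_hist = sum(u.area_m2 for u in m.units)
            else:
                a_hist = wrack_zone_area(sub.units, sub.detections)
            if s_hist == 0 or a_hist <= 0:
                logger.warning(
                    "site %s group %s: no historical baseline (S=%d, A=%.3g); skipped",
                    site, group, s_hist, a_hist,
                )
                continue
            points.append(
                HistoricalPoint(site=site, group=group, S_hist=s_hist, A_hist=float(a_hist))
            )
    return points


@dataclass
class ChangeSummary:
    by_category: pd.DataFrame
    n_wrack_exceeds_overall: int
    frac_wrack_exceeds_overall: float


def results_to_frame(results: list[ChangeResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def summarize_changes(results: list[ChangeResult]) -> ChangeSummary:
    """Aggregate change results per impact category x group.

    Means are arithmetic over the (full-precision) percent changes; counts
    tally direction and significance.  Also reports how many sites show a
    larger |percent change| for the wrack group than overall — the pattern
    in which functional-group change outruns the community-wide signal.
    """
    if not results:
        raise ValueError("summarize_changes requires at least one result")
    df = results_to_frame(results)
    by = (
        df.groupby(["impact_category", "group"], sort=True)
        .agg(
            n=("pct_change", "size"),
            mean_pct_change=("pct_change", "mean"),
            n_increase=("direction", lambda d: int((d == "increase").sum())),
            n_decrease=("direction", lambda d: int((d == "decrease").sum())),
            n_none=("direction", lambda d: int((d == "none").sum())),
            n_significant=("significant", "sum"),
        )
        .reset_index()
    )
    wide = df.pivot_table(
        index="site", columns="group", values="pct_change", aggfunc="first"
    )
    n_exceeds, frac = 0, math.nan
    if {"overall", "wrack"} <= set(wide.columns):
        both = wide.dropna(subset=["overall", "wrack"])
        if len(both):
            n_exceeds = int((both["wrack"].abs() > both["overall"].abs()).sum())
            frac = n_exceeds / len(both)
    return ChangeSummary(
        by_category=by,
        n_wrack_exceeds_overall=n_exceeds,
        frac_wrack_exceeds_overall=frac,
    )


def format_summary(summary: ChangeSummary) -> str:
    """Human-readable rendering; percentages rounded to whole numbers here only."""
    lines = ["impact_category  group  n  mean_pct  incr  decr  none  signif"]
    for row in summary.by_category.itertuples(index=False):
        mean = "n/a" if pd.isna(row.mean_pct_change) else f"{row.mean_pct_change:+.0f}%"
        lines.append(
            f"{row.impact_category}  {row.group}  {row.n}  {mean}  "
            f"{row.n_increase}  {row.n_decrease}  {row.n_none}  {row.n_significant}"
        )
    if not math.isnan(summary.frac_wrack_exceeds_overall):
        lines.append(
            f"sites where |wrack change| exceeds |overall change|: "
            f"{summary.n_wrack_exceeds_overall} "
            f"({100 * summary.frac_wrack_exceeds_overall:.0f}%)"
        )
    lines.append("note: no multiple-testing correction is applied across sites/groups")
    return "\n".join(lines)
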