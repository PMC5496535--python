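"""Incidence (presence/absence) survey data structures and summaries.

Sample-based richness estimation works from a *reference sample*: a set of
replicated sampling units (here, sediment cores or pooled surveys on one
beach in one survey period) in which each species is scored as detected or
not.  This module ingests the tabular survey formats, restricts matrices to
functional groups (overall / wrack-associated / low-dispersal
wrack-associated), accounts for cumulative sampled area — including the
narrower upper-beach wrack zone — and reduces a matrix to the incidence
frequency counts (Q1, Q2, ... "uniques", "duplicates") that the estimators
consume.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTrait",
    "SamplingUnit",
    "IncidenceMatrix",
    "IncidenceSummary",
    "read_incidence_table",
    "read_traits_table",
    "read_species_lists",
    "validate_species_lists",
    "summarize_incidence",
    "cumulative_sampling_area",
    "wrack_zone_area",
    "subset_by_group",
    "select_max_area_design",
    "pool_units_by_survey",
]

GROUPS = ("overall", "wrack", "low_dispersal_wrack")
PERIODS = ("historical", "recent")
DESIGNS = ("proportional", "fixed")


@dataclass(frozen=True)
class SpeciesTrait:
    """Functional-group membership of one species.

    ``low_dispersal`` species (direct developers, flightless wrack beetles)
    are by definition a subset of the wrack-associated fauna.
    """

    species_id: str
    taxon_group: str = ""
    wrack_associated: bool = False
    low_dispersal: bool = False

    def __post_init__(self) -> None:
        if self.low_dispersal and not self.wrack_associated:
            raise ValueError(
                f"species {self.species_id!r}: low_dispersal implies "
                "wrack_associated (low-dispersal taxa are a subset of the "
                "wrack-associated group)"
            )


@dataclass(frozen=True)
class SamplingUnit:
    """One replicated sampling unit (a core, or a pooled survey).

    ``cross_shore_position_m`` is measured seaward from the 24-hr high-tide
    line (0 at the line, increasing toward the low swash limit), so the
    "lowest" sample on the beach face has the *largest* coordinate.
    """

    unit_id: str
    site: str
    period: str
    area_m2: float
    date: _dt.date | None = None
    cross_shore_position_m: float = 0.0
    design: str = "fixed"

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError(f"unit {self.unit_id!r}: area_m2 must be > 0")
        if self.cross_shore_position_m < 0:
            raise ValueError(
                f"unit {self.unit_id!r}: cross_shore_position_m must be >= 0"
            )
        if self.period not in PERIODS:
            raise ValueError(
                f"unit {self.unit_id!r}: period must be one of {PERIODS}"
            )
        if self.design not in DESIGNS:
            raise ValueError(
                f"unit {self.unit_id!r}: design must be one of {DESIGNS}"
            )


@dataclass
class IncidenceMatrix:
    """Species-by-unit detection matrix for one site and period.

    ``detections[i, j]`` is True when species ``species_ids[i]`` was found in
    ``units[j]``.  Rows of all-False detections are permitted (cumulative
    lists differ between periods); observed richness counts detected species
    only.
    """

    species_ids: list[str]
    units: list[SamplingUnit]
    detections: np.ndarray

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=bool)
        if self.detections.shape != (len(self.species_ids), len(self.units)):
            raise ValueError(
                f"detections shape {self.detections.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.units)} units"
            )
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species_ids in incidence matrix")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def restrict_units(self, keep: Sequence[bool] | np.ndarray) -> "IncidenceMatrix":
        keep = np.asarray(keep, dtype=bool)
        return IncidenceMatrix(
            species_ids=list(self.species_ids),
            units=[u for u, k in zip(self.units, keep) if k],
            detections=self.detections[:, keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.detections.astype(int),
            index=pd.Index(self.species_ids, name="species_id"),
            columns=[u.unit_id for u in self.units],
        )


@dataclass(frozen=True)
class IncidenceSummary:
    """Incidence frequency counts of a reference sample.

    Attributes
    ----------
    R : int
        Number of sampling units.
    S_obs : int
        Observed richness (species with >= 1 detection).
    Y : ndarray
        Incidence counts of the detected species (1 <= Y_i <= R).
    Q : ndarray
        ``Q[k-1]`` = number of species detected in exactly k units,
        k = 1..R (Q1 = uniques, Q2 = duplicates).
    A_total : float
        Cumulative sampled area, m².
    a_bar : float
        Mean area per unit, m² (A_total / R); maps effort to the area axis.
    """

    R: int
    S_obs: int
    Y: np.ndarray
    Q: np.ndarray
    A_total: float
    a_bar: float

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("summary requires at least one sampling unit")
        if int(self.Q.sum()) != self.S_obs:
            raise ValueError("sum of Q_k must equal S_obs")
        if int((np.arange(1, self.R + 1) * self.Q).sum()) != int(self.Y.sum()):
            raise ValueError("sum of k*Q_k must equal total incidences")

    @property
    def Q1(self) -> int:
        return int(self.Q[0]) if self.R >= 1 else 0

    @property
    def Q2(self) -> int:
        return int(self.Q[1]) if self.R >= 2 else 0


# ---------------------------------------------------------------------------
# readers


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"true", "t", "1", "yes"}:
        return True
    if s in {"false", "f", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean value {x!r}")


def read_unit_metadata(path) -> dict[str, SamplingUnit]:
    """Read the unit-metadata CSV into a mapping unit_id -> SamplingUnit."""
    meta = pd.read_csv(path, dtype={"unit_id": str})
    required = {"unit_id", "site", "period", "area_m2"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"unit metadata {path}: missing columns {sorted(missing)}")
    units: dict[str, SamplingUnit] = {}
    for row in meta.itertuples(index=False):
        date = None
        if hasattr(row, "date") and not pd.isna(row.date):
            date = _dt.date.fromisoformat(str(row.date))
        units[str(row.unit_id)] = SamplingUnit(
            unit_id=str(row.unit_id),
            site=str(row.site),
            period=str(row.period),
            area_m2=float(row.area_m2),
            date=date,
            cross_shore_position_m=float(
                getattr(row, "cross_shore_position_m", 0.0) or 0.0
            ),
            design=str(getattr(row, "design", "fixed")),
        )
    return units


def read_incidence_table(path, unit_metadata_path) -> IncidenceMatrix:
    """Read a species x unit 0/1 CSV plus its unit-metadata CSV.

    The detection table's first column is ``species_id``; every remaining
    column is a unit id that must appear in the metadata.  Cells are parsed
    strictly as 0/1 — anything else is a hard error naming the cell.
    """
    table = pd.read_csv(path, dtype=str).set_index("species_id")
    meta = read_unit_metadata(unit_metadata_path)

    units: list[SamplingUnit] = []
    for unit_id in table.columns:
        if unit_id not in meta:
            raise ValueError(
                f"incidence table {path}: unit {unit_id!r} has no row in "
                f"unit metadata {unit_metadata_path}"
            )
        units.append(meta[unit_id])

    det = np.zeros((table.shape[0], table.shape[1]), dtype=bool)
    for i, sp in enumerate(table.index):
        for j, unit_id in enumerate(table.columns):
            cell = str(table.iloc[i, j]).strip()
            if cell == "0":
                det[i, j] = False
            elif cell == "1":
                det[i, j] = True
            else:
                raise ValueError(
                    f"incidence table {path}: non-binary cell {cell!r} at "
                    f"species {sp!r}, unit {unit_id!r}"
                )
    return IncidenceMatrix(list(table.index), units, det)


def read_traits_table(path) -> dict[str, SpeciesTrait]:
    """Read the species-trait CSV into a mapping species_id -> SpeciesTrait."""
    df = pd.read_csv(path, dtype={"species_id": str})
    traits: dict[str, SpeciesTrait] = {}
    for row in df.itertuples(index=False):
        traits[str(row.species_id)] = SpeciesTrait(
            species_id=str(row.species_id),
            taxon_group=str(getattr(row, "taxon_group", "")),
            wrack_associated=_parse_bool(row.wrack_associated),
            low_dispersal=_parse_bool(row.low_dispersal),
        )
    return traits


def read_species_lists(path) -> pd.DataFrame:
    """Load cumulative species x site x period lists (long CSV).

    Expected columns: species_id, site, period, wrack_associated,
    low_dispersal.  This is the loader for externally supplied cumulative
    species lists; no such file ships with the package.
    """
    df = pd.read_csv(path, dtype={"species_id": str, "site": str, "period": str})
    required = {"species_id", "site", "period"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"species lists {path}: missing columns {sorted(missing)}")
    return df


def validate_species_lists(df: pd.DataFrame) -> dict[str, float]:
    """Summary statistics of a cumulative species-list table.

    Returns total distinct species, per-period distinct species, and the
    wrack-associated share of each period's pool (as a percentage).
    """
    out: dict[str, float] = {"total_species": df["species_id"].nunique()}
    for period in sorted(df["period"].unique()):
        sub = df[df["period"] == period]
        n = sub["species_id"].nunique()
        out[f"species_{period}"] = n
        if "wrack_associated" in df.columns:
            wr = sub[sub["wrack_associated"].map(_parse_bool)]["species_id"].nunique()
            out[f"wrack_share_pct_{period}"] = 100.0 * wr / n if n else 0.0
    return out


# ---------------------------------------------------------------------------
# summaries and restrictions


def summarize_incidence(m: IncidenceMatrix) -> IncidenceSummary:
    """Reduce a detection matrix to its incidence frequency counts."""
    if m.n_units == 0:
        raise ValueError("cannot summarize a matrix with zero sampling units")
    R = m.n_units
    counts = m.detections.sum(axis=1).astype(int)
    Y = counts[counts > 0]
    S_obs = int(Y.size)
    Q = np.bincount(Y, minlength=R + 1)[1:] if S_obs else np.zeros(R, dtype=int)
    A_total = cumulative_sampling_area(m.units)
    return IncidenceSummary(
        R=R,
        S_obs=S_obs,
        Y=np.sort(Y),
        Q=Q.astype(int),
        A_total=A_total,
        a_bar=A_total / R,
    )


def cumulative_sampling_area(units: Iterable[SamplingUnit]) -> float:
    """Total sampled area (m²) over a list of units.

    Grouping by site x period is the caller's responsibility; the sum is
    additive over any partition of the unit list.
    """
    units = list(units)
    if not units:
        raise ValueError("cumulative_sampling_area requires at least one unit")
    return float(sum(u.area_m2 for u in units))


def wrack_zone_area(units: Sequence[SamplingUnit], detections: np.ndarray) -> float:
    """Cumulative area (m²) of the upper-beach wrack zone.

    The wrack zone runs from the 24-hr high-tide line down to the lowest
    (most seaward) sample containing a wrack-associated species.
    ``detections`` must be the incidence matrix restricted to
    wrack-associated species, aligned column-wise with ``units``.  Returns 0
    when no wrack-associated species was detected anywhere.
    """
    detections = np.asarray(detections, dtype=bool)
    if detections.ndim != 2 or detections.shape[1] != len(units):
        raise ValueError(
            f"detections with {detections.shape} columns are not aligned to "
            f"{len(units)} units"
        )
    present = detections.any(axis=0)
    if not present.any():
        return 0.0
    positions = np.array([u.cross_shore_position_m for u in units])
    zone_edge = positions[present].max()
    return float(sum(u.area_m2 for u, p in zip(units, positions) if p <= zone_edge))


def subset_by_group(
    m: IncidenceMatrix,
    traits: dict[str, SpeciesTrait],
    group: str,
) -> IncidenceMatrix:
    """Restrict a matrix to one functional group's species rows.

    ``overall`` returns the input unchanged; ``wrack`` keeps species with
    ``wrack_associated=True``; ``low_dispersal_wrack`` keeps species with
    both flags.  Every species in the matrix must have a trait row; species
    present in the traits but absent from the matrix are ignored.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    missing = [s for s in m.species_ids if s not in traits]
    if missing:
        raise KeyError(f"species without trait rows: {missing}")
    if group == "overall":
        return m
    if group == "wrack":
        keep = np.array([traits[s].wrack_associated for s in m.species_ids])
    else:
        keep = np.array(
            [traits[s].wrack_associated and traits[s].low_dispersal
             for s in m.species_ids]
        )
    return IncidenceMatrix(
        species_ids=[s for s, k in zip(m.species_ids, keep) if k],
        units=list(m.units),
        detections=m.detections[keep, :],
    )


def select_max_area_design(units: Sequence[SamplingUnit]) -> list[SamplingUnit]:
    """Keep only the units of the sampling design covering the most area.

    When both the proportional and the fixed-area design were run in one
    site x period, analysis uses whichever sampled the greater cumulative
    area; on an exact tie the fixed design wins (the design independent of
    intertidal width is the preferred one among beach ecologists).
    """
    units = list(units)
    if not units:
        raise ValueError("select_max_area_design requires at least one unit")
    totals: dict[str, float] = {}
    for u in units:
        totals[u.design] = totals.get(u.design, 0.0) + u.area_m2
    if len(totals) == 1:
        return units
    best = max(totals, key=lambda d: (totals[d], d == "fixed"))
    return [u for u in units if u.design == best]


def pool_units_by_survey(m: IncidenceMatrix) -> IncidenceMatrix:
    """Pool core-level units into one unit per survey date.

    A species is detected in the pooled unit if it was detected in any core
    of that survey; areas sum and the cross-shore position is the maximum
    over the pooled cores.  Units without a date each remain their own unit.
    """
    keys: list[tuple] = []
    for u in m.units:
        keys.append((u.site, u.period, u.design, u.date if u.date else u.unit_id))
    order: list[tuple] = []
    groups: dict[tuple, list[int]] = {}
    for j, key in enumerate(keys):
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(j)

    units: list[SamplingUnit] = []
    cols: list[np.ndarray] = []
    for key in order:
        idx = groups[key]
        first = m.units[idx[0]]
        units.append(
            SamplingUnit(
                unit_id=f"{first.site}:{first.period}:{key[3]}",
                site=first.site,
                period=first.period,
                area_m2=float(sum(m.units[j].area_m2 for j in idx)),
                date=first.date,
                cross_shore_position_m=float(
                    max(m.units[j].cross_shore_position_m for j in idx)
                ),
                design=first.design,
            )
        )
        cols.append(m.detections[:, idx].any(axis=1))
    return IncidenceMatrix(list(m.species_ids), units, np.column_stack(cols))
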