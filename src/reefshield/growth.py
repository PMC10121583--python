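"""Coral growth assays: buoyant weight and caliper series to rates.

Assay corals (Acropora palmata branch tips, Pseudodiploria strigosa
colonies) mounted on fixed stations are re-photographed, measured (height,
planar diameters) and buoyant-weighed roughly twice a year. This module
converts repeated measurements into calcification rates normalised by
planar footprint (kg CaCO3 m-2 y-1), linear extension rates (cm y-1), and
planar-area change rates (cm2 y-1).

Buoyant weight converts to dry skeletal mass through Archimedes' principle:
m_dry = m_buoyant / (1 - rho_seawater / rho_skeleton). The planar footprint
is an ellipse from the maximum and minimum caliper diameters.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .census import SchemaError, ValidationError

__all__ = [
    "GrowthRecord",
    "RHO_SEAWATER",
    "RHO_ARAGONITE",
    "ellipse_area",
    "buoyant_to_dry",
    "calcification_rate",
    "extension_rates",
    "colony_rates",
    "summarize_growth",
    "read_growth",
    "write_growth",
]

#: Default seawater density (g cm-3), standard buoyant-weight practice.
RHO_SEAWATER = 1.023
#: Default aragonite skeletal density (g cm-3).
RHO_ARAGONITE = 2.93

STATUSES = ("alive", "partial_mortality", "dead")
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class GrowthRecord:
    """One visit's measurements of one assay colony.

    ``time`` is either a :class:`datetime.date` or a decimal year;
    mass in g (buoyant), height in cm, planar diameters in cm.
    """

    colony_id: str
    species: str
    station: str
    time: "_dt.date | float"
    buoyant_mass: float
    height: float
    d_max: float
    d_min: float
    status: str = "alive"

    def validate(self) -> "GrowthRecord":
        if self.status not in STATUSES:
            raise ValidationError(
                f"colony {self.colony_id}: unknown status {self.status!r}"
            )
        if self.status != "dead":
            if self.buoyant_mass <= 0:
                raise ValidationError(
                    f"colony {self.colony_id}: non-positive buoyant mass"
                )
            if self.d_max < self.d_min:
                raise ValidationError(
                    f"colony {self.colony_id}: d_max {self.d_max} < d_min {self.d_min}"
                )
        return self


def _years(t0, t1) -> float:
    """Elapsed time in years between two record times."""
    if isinstance(t0, _dt.date) and isinstance(t1, _dt.date):
        return (t1 - t0).days / DAYS_PER_YEAR
    return float(t1) - float(t0)


def ellipse_area(d_max: float, d_min: float) -> float:
    """Planar footprint (cm2) from maximum and minimum diameters (cm)."""
    if d_min <= 0 or d_max <= 0:
        raise ValidationError("diameters must be positive")
    if d_max < d_min:
        raise ValidationError(f"d_max {d_max} < d_min {d_min}")
    return math.pi / 4.0 * d_max * d_min


def buoyant_to_dry(
    buoyant_mass: float,
    rho_seawater: float = RHO_SEAWATER,
    rho_skeleton: float = RHO_ARAGONITE,
) -> float:
    """Dry skeletal mass (g) from buoyant mass (g) via Archimedes."""
    if not rho_skeleton > rho_seawater > 0:
        raise ValidationError(
            f"need rho_skeleton > rho_seawater > 0, got "
            f"{rho_skeleton}, {rho_seawater}"
        )
    return buoyant_mass / (1.0 - rho_seawater / rho_skeleton)


def _check_pair(r0: GrowthRecord, r1: GrowthRecord) -> float:
    if r0.colony_id != r1.colony_id:
        raise ValidationError(
            f"records belong to different colonies: {r0.colony_id} / {r1.colony_id}"
        )
    dt = _years(r0.time, r1.time)
    if dt <= 0:
        raise ValidationError(f"colony {r0.colony_id}: non-positive interval {dt} y")
    return dt


def calcification_rate(
    r0: GrowthRecord,
    r1: GrowthRecord,
    rho_seawater: float = RHO_SEAWATER,
    rho_skeleton: float = RHO_ARAGONITE,
    area_mode: str = "mean",
) -> float:
    """Area-normalised calcification rate (kg CaCO3 m-2 y-1) over an interval.

    (dry-mass change in kg) / (normalising planar area in m2) / (interval
    in years). ``area_mode`` picks the normalising footprint: the interval
    ``mean`` (default), ``start``, or ``end`` planar ellipse area. A dead
    endpoint is an error here; summaries exclude such colonies upstream.
    """
    dt = _check_pair(r0, r1)
    if r1.status == "dead" or r0.status == "dead":
        raise ValidationError(
            f"colony {r0.colony_id}: calcification undefined across a dead endpoint"
        )
    dm_kg = (
        buoyant_to_dry(r1.buoyant_mass, rho_seawater, rho_skeleton)
        - buoyant_to_dry(r0.buoyant_mass, rho_seawater, rho_skeleton)
    ) / 1000.0
    a0 = ellipse_area(r0.d_max, r0.d_min)
    a1 = ellipse_area(r1.d_max, r1.d_min)
    area_cm2 = {"start": a0, "end": a1, "mean": (a0 + a1) / 2.0}.get(area_mode)
    if area_cm2 is None:
        raise ValidationError(f"unknown area_mode {area_mode!r}")
    return dm_kg / (area_cm2 / 1e4) / dt


def extension_rates(r0: GrowthRecord, r1: GrowthRecord) -> tuple[float, float]:
    """(height rate cm y-1, planar-area rate cm2 y-1) by finite difference.

    Negative rates are legitimate (partial-mortality shrinkage).
    """
    dt = _check_pair(r0, r1)
    dh = (r1.height - r0.height) / dt
    da = (ellipse_area(r1.d_max, r1.d_min) - ellipse_area(r0.d_max, r0.d_min)) / dt
    return dh, da


def colony_rates(
    records: Sequence[GrowthRecord],
    area_mode: str = "mean",
    rho_seawater: float = RHO_SEAWATER,
    rho_skeleton: float = RHO_ARAGONITE,
) -> pd.DataFrame:
    """Per-colony rates from each colony's first to last living record.

    Colonies that die are flagged (``died`` True) and carry NaN rates;
    a colony needs at least two living records to contribute.
    """
    rows = []
    by_colony: dict[str, list[GrowthRecord]] = {}
    for r in records:
        by_colony.setdefault(r.colony_id, []).append(r)
    for cid, recs in by_colony.items():
        recs = sorted(
            recs,
            key=lambda r: r.time.toordinal()
            if isinstance(r.time, _dt.date)
            else float(r.time),
        )
        for a, b in zip(recs, recs[1:]):
            if _years(a.time, b.time) <= 0:
                raise ValidationError(f"colony {cid}: record times not increasing")
        died = any(r.status == "dead" for r in recs)
        living = [r for r in recs if r.status != "dead"]
        row = {
            "colony_id": cid,
            "species": recs[0].species,
            "station": recs[0].station,
            "died": died,
            "calcification_rate": np.nan,
            "height_rate": np.nan,
            "area_rate": np.nan,
        }
        if len(living) >= 2:
            first, last = living[0], living[-1]
            row["calcification_rate"] = calcification_rate(
                first, last, rho_seawater, rho_skeleton, area_mode
            )
            row["height_rate"], row["area_rate"] = extension_rates(first, last)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_growth(
    records: Sequence[GrowthRecord],
    level: str = "colony",
    area_mode: str = "mean",
) -> pd.DataFrame:
    """Species-level mean and SE of the three growth rates.

    ``level="colony"`` averages over colonies; ``level="station"`` first
    averages within station, then across stations (both exposed because
    either could underlie a reported species mean). Colonies that died are
    excluded.
    """
    per = colony_rates(records, area_mode=area_mode)
    per = per[~per["died"]].dropna(subset=["calcification_rate"])
    if per.empty:
        raise ValidationError("no surviving colonies with >= 2 records")
    if level == "station":
        per = (
            per.groupby(["species", "station"], as_index=False)[
                ["calcification_rate", "height_rate", "area_rate"]
            ].mean()
        )
    elif level != "colony":
        raise ValidationError(f"unknown summary level {level!r}")
    out = []
    for sp, g in per.groupby("species"):
        n = len(g)
        row = {"species": sp, "n": n, "level": level}
        for col in ("calcification_rate", "height_rate", "area_rate"):
            row[f"{col}_mean"] = g[col].mean()
            row[f"{col}_se"] = g[col].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)


_GROWTH_COLUMNS = [
    "colony_id",
    "species",
    "station",
    "time",
    "buoyant_mass",
    "height",
    "d_max",
    "d_min",
    "status",
]


def write_growth(records: Iterable[GrowthRecord], path) -> None:
    """Write growth records to CSV (dates ISO-formatted, decimal years as-is)."""
    rows = []
    for r in records:
        t = r.time.isoformat() if isinstance(r.time, _dt.date) else r.time
        rows.append(
            {
                "colony_id": r.colony_id,
                "species": r.species,
                "station": r.station,
                "time": t,
                "buoyant_mass": r.buoyant_mass,
                "height": r.height,
                "d_max": r.d_max,
                "d_min": r.d_min,
                "status": r.status,
            }
        )
    pd.DataFrame(rows, columns=_GROWTH_COLUMNS).to_csv(path, index=False)


def read_growth(path) -> list[GrowthRecord]:
    """Read growth records from CSV written by :func:`write_growth`."""
    df = pd.read_csv(path, dtype={"colony_id": str, "time": str})
    for col in _GROWTH_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"growth file {path} is missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        t_raw = str(row["time"])
        try:
            time: "_dt.date | float" = float(t_raw)
        except ValueError:
            time = _dt.date.fromisoformat(t_raw)
        out.append(
            GrowthRecord(
                colony_id=str(row["colony_id"]),
                species=str(row["species"]),
                station=str(row["station"]),
                time=time,
                buoyant_mass=float(row["buoyant_mass"]),
                height=float(row["height"]),
                d_max=float(row["d_max"]),
                d_min=float(row["d_min"]),
                status=str(row["status"]),
            ).validate()
        )
    return out
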