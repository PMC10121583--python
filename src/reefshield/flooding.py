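"""Post-processing of shoreline total-water-level (TWL) tables.

Maximum total water levels along the shoreline are computed externally by a
phase-resolving wave model forced with static sea-level offsets
(+0.0, +0.2, +0.5, +1.2, +2.0 m) and 10- and 50-year storm conditions; this
module never runs wave physics. It interpolates the tabulated TWLs to
restoration-adjusted sea levels: a reef-crest elevation gain of h m under a
sea-level rise of s m is equivalent to running the storm at an effective
rise of max(s - h, 0) — clamped at the +0.0 scenario, because the tables
include no shallower-than-present reef configurations. Alongshore
summaries report the mean +/- SE over shoreline points per sector, with
restoration-case uncertainty combined as the root-sum-square of the TWL SE
and the projected-elevation SE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import SchemaError, ValidationError

__all__ = [
    "TWL_COLUMNS",
    "STORMS",
    "TWLTable",
    "read_twl",
    "write_twl",
    "interp_twl",
    "restoration_adjusted_twl",
    "adjust_table",
    "alongshore_summary",
    "combined_se",
]

STORMS = ("10yr", "50yr")
TWL_COLUMNS = ["point_id", "sector", "storm", "slr_offset", "max_twl"]


@dataclass
class TWLTable:
    """Shoreline-point maximum TWLs indexed by storm and sea-level offset.

    Wraps a long-format DataFrame with columns ``point_id``, ``sector``,
    ``storm``, ``slr_offset`` (m), ``max_twl`` (m) and optionally
    ``wave_driven_component``. Every (point, storm) pair must carry the
    full offset set, and TWL must be non-decreasing in the offset.
    ``metadata`` carries forcing provenance (significant wave heights,
    periods, surge levels, datum) as opaque annotations.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def offsets(self) -> tuple[float, ...]:
        return tuple(sorted(self.data["slr_offset"].unique()))

    def validate(self) -> "TWLTable":
        for col in TWL_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"TWL table is missing column {col!r}")
        offsets = set(self.offsets)
        for (pid, storm), g in self.data.groupby(["point_id", "storm"]):
            have = set(g["slr_offset"])
            if have != offsets:
                raise ValidationError(
                    f"point {pid!r} storm {storm!r} tabulates offsets "
                    f"{sorted(have)}, expected {sorted(offsets)}"
                )
            twl = g.sort_values("slr_offset")["max_twl"].to_numpy()
            if np.any(np.diff(twl) < 0):
                raise ValidationError(
                    f"point {pid!r} storm {storm!r}: max_twl decreases with "
                    "sea-level offset"
                )
        return self

    def series(self, point_id, storm: str) -> tuple[np.ndarray, np.ndarray]:
        g = self.data[
            (self.data["point_id"] == point_id) & (self.data["storm"] == storm)
        ].sort_values("slr_offset")
        if g.empty:
            raise ValidationError(
                f"no TWL records for point {point_id!r}, storm {storm!r}"
            )
        return g["slr_offset"].to_numpy(float), g["max_twl"].to_numpy(float)


def write_twl(table: TWLTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_twl(path, metadata: dict | None = None) -> TWLTable:
    df = pd.read_csv(path)
    return TWLTable(data=df, metadata=metadata or {}).validate()


def interp_twl(table: TWLTable, point_id, storm: str, slr: float) -> float:
    """Piecewise-linear TWL (m) at an arbitrary sea level within the table.

    Exact at tabulated nodes; requests outside [min offset, max offset]
    raise rather than extrapolate.
    """
    offsets, twl = table.series(point_id, storm)
    if not offsets[0] <= slr <= offsets[-1]:
        raise ValidationError(
            f"sea level {slr} m outside tabulated range "
            f"[{offsets[0]}, {offsets[-1]}] (no extrapolation)"
        )
    return float(np.interp(slr, offsets, twl))


def restoration_adjusted_twl(
    table: TWLTable,
    point_id,
    storm: str,
    slr: float,
    elevation_gain: float,
) -> float:
    """TWL (m) at a sea level offset by a reef-crest elevation gain.

    effective rise = max(slr - gain, 0): where restoration outpaces
    sea-level rise the +0.0-scenario TWL applies (the table has no
    shallower-than-present configurations).
    """
    if elevation_gain < 0:
        raise ValidationError("elevation gain must be non-negative")
    return interp_twl(table, point_id, storm, max(slr - elevation_gain, 0.0))


def adjust_table(
    table: TWLTable,
    slr: float,
    storm: str,
    sector_gains: Mapping[str, float],
) -> pd.DataFrame:
    """Restoration-adjusted TWL for every shoreline point at one (slr, storm).

    Elevation gains are sector-specific (northern vs southern reef crest).
    Returns point_id, sector, storm, slr, effective_slr, max_twl (adjusted),
    unadjusted_twl.
    """
    rows = []
    pts = table.data[table.data["storm"] == storm][
        ["point_id", "sector"]
    ].drop_duplicates()
    if pts.empty:
        raise ValidationError(f"no TWL records for storm {storm!r}")
    for _, p in pts.iterrows():
        sector = p["sector"]
        if sector not in sector_gains:
            raise ValidationError(f"no elevation gain supplied for sector {sector!r}")
        gain = sector_gains[sector]
        rows.append(
            {
                "point_id": p["point_id"],
                "sector": sector,
                "storm": storm,
                "slr": slr,
                "effective_slr": max(slr - gain, 0.0),
                "max_twl": restoration_adjusted_twl(
                    table, p["point_id"], storm, slr, gain
                ),
                "unadjusted_twl": interp_twl(table, p["point_id"], storm, slr),
            }
        )
    return pd.DataFrame(rows)


def combined_se(se_twl: float, se_elev: float) -> float:
    """Root-sum-square of TWL and reef-elevation uncertainties."""
    if se_twl < 0 or se_elev < 0:
        raise ValidationError("standard errors must be non-negative")
    return math.hypot(se_twl, se_elev)


def alongshore_summary(
    df: pd.DataFrame,
    value_col: str = "max_twl",
    by: Sequence[str] = ("sector", "storm"),
    elevation_se: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Alongshore mean +/- SE of TWL over shoreline points, per group.

    ``df`` is either ``TWLTable.data`` (then grouping usually includes
    ``slr_offset``) or the output of :func:`adjust_table`. When
    ``elevation_se`` maps sector -> SE of projected reef-elevation change,
    a ``combined_se`` column reports the root-sum-square of the alongshore
    TWL SE and that elevation SE (restoration runs).
    """
    by = list(by)
    missing = [c for c in by + [value_col] if c not in df.columns]
    if missing:
        raise SchemaError(f"summary input missing columns {missing}")
    rows = []
    for key, g in df.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(g)
        if n < 2:
            raise ValidationError(
                f"group {dict(zip(by, key))} has {n} shoreline point(s); "
                "need >= 2 for an SE"
            )
        mean = g[value_col].mean()
        se = g[value_col].std(ddof=1) / math.sqrt(n)
        row = dict(zip(by, key))
        row.update({"n": n, "mean": mean, "se": se})
        if elevation_se is not None:
            sector = row.get("sector")
            if sector not in elevation_se:
                raise ValidationError(f"no elevation SE for sector {sector!r}")
            row["combined_se"] = combined_se(se, elevation_se[sector])
        rows.append(row)
    return pd.DataFrame(rows)
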