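"""Per-site carbonate budgets and reef-accretion potential.

The budget of a site is the balance of gross calcium-carbonate production
(cover x calcification x rugosity, summed over calcifying taxa) against four
bioerosion components: parrotfish grazing, urchin grazing, endolithic
macrobioerosion (sponges, molluscs, worms) and microbioerosion (bacteria,
algae, fungi). Net production (kg CaCO3 m-2 y-1) is converted to a vertical
framework accretion rate F_i (mm y-1) through the weighted mean skeletal
density of the coral assemblage,

    D_i = sum_n (x_n / X_i) * d_n,

and, for net-positive sites only, credited with the sediment and void
fractions observed in Holocene reef cores,

    A_i = F_i * (1 + sed/frame + void/frame),

giving the reef-accretion potential A_i (mm y-1). Net-erosional sites use
the default Caribbean density (1670 kg m-3) and take A_i = F_i: eroding
framework earns no sediment/void credit. Bioerosion components are stored
as positive magnitudes and subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .census import (
    MissingRateError,
    RateTable,
    SiteCensus,
    ValidationError,
    cover_from_points,
)

__all__ = [
    "BudgetResult",
    "gross_production",
    "parrotfish_bioerosion",
    "urchin_bioerosion",
    "substrate_bioerosion",
    "framework_density",
    "accretion_potential",
    "project_elevation",
    "site_budget",
    "aggregate_zones",
    "apply_zonal_elevation",
    "read_ascii_grid",
    "write_ascii_grid",
    "budgets_to_frame",
]

BASE_YEAR = 2016


@dataclass
class BudgetResult:
    """Carbonate-budget outputs for one site.

    Production/bioerosion in kg CaCO3 m-2 y-1 (bioerosion as positive
    magnitudes), density in kg m-3, accretion rates in mm y-1, projected
    elevation change in m.
    """

    site_id: str
    gross_production: float
    parrotfish_bioerosion: float
    urchin_bioerosion: float
    macro_bioerosion: float
    micro_bioerosion: float
    net_production: float
    framework_density: float
    framework_accretion: float
    accretion_potential: float
    elevation_change_2050: float
    elevation_change_2100: float

    @property
    def total_bioerosion(self) -> float:
        return (
            self.parrotfish_bioerosion
            + self.urchin_bioerosion
            + self.macro_bioerosion
            + self.micro_bioerosion
        )


def gross_production(
    cover: Mapping[str, float], rates: RateTable
) -> tuple[float, dict[str, float]]:
    """Gross carbonate production (kg CaCO3 m-2 y-1) and per-taxon breakdown.

    G = sum_t cover_t * c_t * r_t over calcifying taxa, where cover is the
    planar cover *fraction*, c_t the planar calcification rate per 100 %
    cover, and r_t the rugosity correction (1 for non-coral calcifiers such
    as coralline algae). Non-calcifying categories contribute nothing; a
    known calcifier with no calcification rate raises
    :class:`~reefshield.census.MissingRateError`.
    """
    breakdown: dict[str, float] = {}
    for taxon, frac in cover.items():
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"cover fraction for {taxon!r} outside [0, 1]: {frac}")
        if taxon in rates.calcification:
            r = rates.rugosity_correction.get(taxon, 1.0)
            breakdown[taxon] = frac * rates.calcification[taxon] * r
        elif taxon in rates.coral_taxa:
            raise MissingRateError(
                f"calcifying taxon {taxon!r} has no calcification rate"
            )
    return sum(breakdown.values()), breakdown


def parrotfish_bioerosion(
    fish_counts: Sequence,
    rates: RateTable,
    belt_area: float = 120.0,
    n_transects: int = 2,
    strict: bool = True,
) -> float:
    """Site-level parrotfish bioerosion (kg CaCO3 m-2 y-1).

    Within each belt transect, individual rates (g ind-1 y-1, by species,
    size bin and life phase) are multiplied by the observed counts, summed,
    and divided by the belt area; the site value is the mean of the two
    transects. A transect that was surveyed but yielded no fish contributes
    zero. A site with only one transect surveyed (``n_transects=1``) errors
    in strict mode; with ``strict=False`` the single-transect value is used
    as-is.
    """
    if n_transects < 1:
        raise ValidationError("at least one fish transect is required")
    if n_transects != 2 and strict:
        raise ValidationError(
            f"strict mode requires exactly 2 fish transects, got {n_transects}"
        )
    per_transect = {t: 0.0 for t in range(1, n_transects + 1)}
    for obs in fish_counts:
        key = (obs.species, obs.size_bin, obs.phase)
        if key not in rates.parrotfish_rates:
            raise MissingRateError(f"no parrotfish rate for {key}")
        if obs.transect_index not in per_transect:
            raise ValidationError(
                f"fish observation on unsurveyed transect {obs.transect_index}"
            )
        per_transect[obs.transect_index] += (
            obs.count * rates.parrotfish_rates[key] / belt_area / 1000.0
        )
    return float(np.mean(list(per_transect.values())))


def urchin_bioerosion(
    urchin_counts: Sequence,
    rates: RateTable,
    transect_area: float = 10.0,
) -> float:
    """Site-level urchin bioerosion (kg CaCO3 m-2 y-1).

    Urchin densities (ind m-2) per size bin are multiplied by the size-
    specific individual rate evaluated at the bin midpoint and scaled by the
    reingestion factor (default 0.57: only that fraction of eroded carbonate
    is a net framework loss), then summed across species and bins.
    """
    from .census import URCHIN_BIN_MM

    total = 0.0
    for obs in urchin_counts:
        mid_mm = obs.size_bin + URCHIN_BIN_MM / 2.0
        rate_kg = rates.urchin_rate(mid_mm) / 1000.0
        total += (obs.count / transect_area) * rate_kg * rates.reingestion_factor
    return total


def substrate_bioerosion(
    dead_coral_cover: float,
    available_substrate: float,
    rates: RateTable,
) -> tuple[float, float]:
    """Endolithic (macro, micro) bioerosion (kg CaCO3 m-2 y-1).

    macro = dead-coral cover x 0.4; micro = available substrate x 0.27.
    By convention the available substrate defaults to the same dead-coral
    fraction (see :func:`site_budget`).
    """
    for name, frac in (
        ("dead_coral_cover", dead_coral_cover),
        ("available_substrate", available_substrate),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"{name} outside [0, 1]: {frac}")
    return dead_coral_cover * rates.macro_rate, available_substrate * rates.micro_rate


def framework_density(coral_cover: Mapping[str, float], rates: RateTable) -> float:
    """Cover-weighted mean skeletal density of the coral assemblage (kg m-3).

    D_i = sum_n (x_n / X_i) * d_n with X_i the total live coral cover.
    Taxa without a tabulated density take the default (1670 kg m-3).
    """
    X = sum(coral_cover.values())
    if X <= 0:
        raise ValidationError("framework density undefined with zero coral cover")
    return sum(
        (x / X) * rates.coral_density.get(t, rates.default_density)
        for t, x in coral_cover.items()
    )


def accretion_potential(
    net_production: float, density: float, rates: RateTable
) -> tuple[float, float]:
    """Framework accretion F_i and reef-accretion potential A_i (mm y-1).

    F_i = 1000 * net / D_i. Net-positive sites earn the sediment/void
    credit A_i = F_i * (1 + sed/frame + void/frame); net-erosional sites
    take A_i = F_i.
    """
    if density <= 0:
        raise ValidationError(f"framework density must be positive, got {density}")
    F = 1000.0 * net_production / density
    if net_production > 0:
        A = F * (1.0 + rates.sed_pct / rates.frame_pct + rates.void_pct / rates.frame_pct)
    else:
        A = F
    return F, A


def project_elevation(
    accretion_mm_y: float, target_year: int, base_year: int = BASE_YEAR
) -> float:
    """Projected elevation change (m) from a constant accretion rate."""
    if target_year < base_year:
        raise ValidationError(
            f"target year {target_year} precedes base year {base_year}"
        )
    return accretion_mm_y * (target_year - base_year) / 1000.0


def site_budget(
    census: SiteCensus,
    rates: RateTable,
    micro_substrate: float | None = None,
    strict: bool = True,
) -> BudgetResult:
    """Full carbonate budget for one site.

    Chains cover estimation, gross production, the four bioerosion
    components, net production, framework density (weighted when net > 0,
    default 1670 kg m-3 otherwise), accretion potential, and elevation
    projections to 2050 and 2100. ``micro_substrate`` overrides the
    substrate fraction for microbioerosion; by default both endolithic terms
    act on the dead-coral cover.
    """
    cover = cover_from_points(census)
    G, _ = gross_production(cover, rates)
    P = parrotfish_bioerosion(
        census.fish_counts,
        rates,
        belt_area=census.fish_belt_area,
        n_transects=census.n_fish_transects,
        strict=strict,
    )
    U = urchin_bioerosion(
        census.urchin_counts, rates, transect_area=census.benthic_transect_area
    )
    dead = sum(cover.get(c, 0.0) for c in rates.dead_substrate_categories)
    avail = dead if micro_substrate is None else micro_substrate
    Ma, Mi = substrate_bioerosion(dead, avail, rates)
    net = G - (P + U + Ma + Mi)
    coral_cover = {
        t: f for t, f in cover.items() if t in rates.coral_taxa and f > 0
    }
    if net > 0:
        D = framework_density(coral_cover, rates)
    else:
        D = rates.default_density
    F, A = accretion_potential(net, D, rates)
    return BudgetResult(
        site_id=census.site_id,
        gross_production=G,
        parrotfish_bioerosion=P,
        urchin_bioerosion=U,
        macro_bioerosion=Ma,
        micro_bioerosion=Mi,
        net_production=net,
        framework_density=D,
        framework_accretion=F,
        accretion_potential=A,
        elevation_change_2050=project_elevation(A, 2050),
        elevation_change_2100=project_elevation(A, 2100),
    )


_NUMERIC_FIELDS = [
    "gross_production",
    "parrotfish_bioerosion",
    "urchin_bioerosion",
    "macro_bioerosion",
    "micro_bioerosion",
    "net_production",
    "framework_density",
    "framework_accretion",
    "accretion_potential",
    "elevation_change_2050",
    "elevation_change_2100",
]


def budgets_to_frame(results: Iterable[BudgetResult]) -> pd.DataFrame:
    """Tabulate budget results, one row per site."""
    return pd.DataFrame(
        [{"site_id": r.site_id, **{f: getattr(r, f) for f in _NUMERIC_FIELDS}} for r in results]
    )


def aggregate_zones(
    results: Sequence[BudgetResult],
    censuses: Sequence[SiteCensus],
    include_overall: bool = True,
) -> pd.DataFrame:
    """Zone (sector x habitat) means and standard errors of budget fields.

    SE = sample SD / sqrt(n). Single-site groups report SE = 0 with
    ``se_defined`` False. Mean benthic cover per taxon is appended as
    ``cover_<category>`` columns. An overall (all-site) row is included
    by default with sector/habitat set to ``"all"``.
    """
    if not results:
        raise ValidationError("no budget results to aggregate")
    meta = {c.site_id: c for c in censuses}
    rows = []
    for r in results:
        if r.site_id not in meta:
            raise ValidationError(f"no census metadata for site {r.site_id!r}")
        c = meta[r.site_id]
        row = {
            "site_id": r.site_id,
            "sector": c.sector,
            "habitat": c.habitat,
            **{f: getattr(r, f) for f in _NUMERIC_FIELDS},
        }
        for cat, frac in cover_from_points(c).items():
            row[f"cover_{cat}"] = frac
        rows.append(row)
    df = pd.DataFrame(rows).fillna({c: 0.0 for c in []})
    cover_cols = [c for c in df.columns if c.startswith("cover_")]
    df[cover_cols] = df[cover_cols].fillna(0.0)
    value_cols = _NUMERIC_FIELDS + cover_cols

    def _summarise(g: pd.DataFrame) -> dict:
        n = len(g)
        out: dict = {"n_sites": n, "se_defined": n > 1}
        for col in value_cols:
            out[f"{col}_mean"] = g[col].mean()
            out[f"{col}_se"] = (g[col].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return out

    summaries = []
    for (sector, habitat), g in df.groupby(["sector", "habitat"], sort=True):
        summaries.append({"sector": sector, "habitat": habitat, **_summarise(g)})
    if include_overall:
        summaries.append({"sector": "all", "habitat": "all", **_summarise(df)})
    return pd.DataFrame(summaries)


# ---------------------------------------------------------------------------
# Zonal bathymetry adjustment (ESRI ASCII grids)
# ---------------------------------------------------------------------------


def apply_zonal_elevation(
    bathy: np.ndarray,
    zones: np.ndarray,
    deltas: Mapping[str, float],
    nodata: float | None = None,
    none_label: str = "none",
) -> np.ndarray:
    """Add a per-zone elevation change (m) to a bathymetry grid.

    ``zones`` holds string labels congruent with ``bathy`` (elevation
    positive-up); cells labelled ``none_label`` (or empty) and nodata cells
    pass through unchanged. A label with no entry in ``deltas`` is an error.
    """
    bathy = np.asarray(bathy, dtype=float)
    zones = np.asarray(zones)
    if bathy.shape != zones.shape:
        raise ValidationError(
            f"bathymetry shape {bathy.shape} != zone-grid shape {zones.shape}"
        )
    out = bathy.copy()
    labels = {str(z) for z in np.unique(zones)}
    labels.discard(none_label)
    labels.discard("")
    unknown = labels - set(deltas)
    if unknown:
        raise ValidationError(f"zone labels with no elevation delta: {sorted(unknown)}")
    for label in labels:
        mask = zones.astype(str) == label
        if nodata is not None:
            mask &= bathy != nodata
        out[mask] += deltas[label]
    return out


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII (.asc) raster: (array, header dict).

    Header keys are lower-cased; ``nodata_value`` is optional.
    """
    header: dict = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            key = parts[0].lower()
            header[key] = int(parts[1]) if key in {"ncols", "nrows"} else float(parts[1])
            data_start = i + 1
        else:
            break
    arr = np.loadtxt(lines[data_start:], dtype=float)
    arr = np.atleast_2d(arr)
    if "nrows" in header and arr.shape != (header["nrows"], header["ncols"]):
        raise ValidationError(
            f"grid {path}: data shape {arr.shape} does not match header "
            f"({header['nrows']}, {header['ncols']})"
        )
    return arr, header


def write_ascii_grid(array: np.ndarray, path, header: dict | None = None) -> None:
    """Write an ESRI ASCII (.asc) raster."""
    array = np.atleast_2d(np.asarray(array, dtype=float))
    header = dict(header or {})
    header.setdefault("ncols", array.shape[1])
    header.setdefault("nrows", array.shape[0])
    header.setdefault("xllcorner", 0.0)
    header.setdefault("yllcorner", 0.0)
    header.setdefault("cellsize", 1.0)
    with open(path, "w") as fh:
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            if key in header:
                fh.write(f"{key} {header[key]}\n")
        for row in array:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
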