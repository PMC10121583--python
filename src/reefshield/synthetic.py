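"""Synthetic census, growth-assay, and TWL fixtures with known ground truth.

Every generator emulates the corresponding sampling design so the full
pipeline is testable without field data:

* census — multinomial point counts per image over a fixed benthic category
  list; Poisson parrotfish counts per (species, size bin, phase) on each of
  two belt transects; Poisson urchin counts per (species, size bin);
* growth — linear planar-area and height trajectories with a dry-mass curve
  whose interval-mean calcification rate is exactly the configured truth,
  plus Gaussian measurement noise and random whole-colony mortality;
* TWL — per-point maximum total water levels that are linear and monotone
  in the sea-level offset with alongshore Gaussian scatter.

A single :class:`numpy.random.Generator` is threaded explicitly through all
draws (no hidden global state), so a fixed seed gives identical output, and
an ``exact`` census mode replaces random draws with their expectations so
budgets can be checked against closed-form oracles to machine precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .census import (
    FISH_BIN_MM,
    HABITATS,
    SECTORS,
    FishObservation,
    SiteCensus,
    URCHIN_BIN_MM,
    UrchinObservation,
    ValidationError,
)
from .flooding import TWLTable
from .growth import GrowthRecord, RHO_ARAGONITE, RHO_SEAWATER, ellipse_area

import pandas as pd

__all__ = ["SynthParams", "gen_census", "gen_growth", "gen_twl", "write_truth"]


def _default_cover() -> dict[str, float]:
    # Degraded Caribbean fore-reef mosaic: ~7 % live coral, abundant dead
    # framework and macroalgae.
    return {
        "Acropora palmata": 0.02,
        "Pseudodiploria strigosa": 0.02,
        "Orbicella annularis": 0.02,
        "Porites astreoides": 0.01,
        "crustose coralline algae": 0.04,
        "dead coral": 0.35,
        "macroalgae": 0.30,
        "sand": 0.24,
    }


def _default_fish_lambda() -> dict[tuple[str, int, str], float]:
    # Expected counts per 120 m2 belt transect; protected-reef parrotfish
    # assemblage dominated by Sparisoma viride.
    return {
        ("Sparisoma viride", 165, "initial"): 3.0,
        ("Sparisoma viride", 255, "terminal"): 1.0,
        ("Scarus vetula", 210, "initial"): 1.5,
        ("Scarus taeniopterus", 120, "initial"): 4.0,
        ("Scarus iseri", 105, "initial"): 5.0,
        ("Sparisoma aurofrenatum", 150, "initial"): 2.0,
    }


def _default_urchin_lambda() -> dict[tuple[str, int], float]:
    # Expected counts per 10 m2 benthic transect; post-die-off Diadema
    # densities remain low.
    return {
        ("Echinometra lucunter", 20): 4.0,
        ("Echinometra viridis", 40): 2.0,
        ("Diadema antillarum", 60): 0.5,
        ("Eucidaris tribuloides", 20): 0.5,
    }


@dataclass
class SynthParams:
    """Ground-truth parameters for all three generators."""

    # census
    cover_probs: dict[str, float] = field(default_factory=_default_cover)
    images_per_transect: tuple[int, int] = (10, 13)  # inclusive draw range
    points_per_image: int = 75
    fish_lambda: dict[tuple[str, int, str], float] = field(
        default_factory=_default_fish_lambda
    )
    urchin_lambda: dict[tuple[str, int], float] = field(
        default_factory=_default_urchin_lambda
    )
    # growth (truth rates are the measured A. palmata means)
    calc_rate: float = 29.07  # kg m-2 y-1
    height_rate: float = 6.99  # cm y-1
    area_rate: float = 196.21  # cm2 y-1
    initial_area_cm2: float = 28.27  # ~6-cm branch-tip footprint
    initial_height_cm: float = 6.0
    initial_dry_mass_g: float = 100.0
    mass_noise_sd: float = 0.0  # g, on buoyant mass
    size_noise_sd: float = 0.0  # cm, on diameters and height
    mortality_prob: float = 0.02  # per visit interval, whole colony
    # TWL
    twl_base: dict[str, float] = field(
        default_factory=lambda: {"10yr": 4.17, "50yr": 4.94}
    )
    twl_slope: float = 0.8  # m TWL per m sea-level rise
    twl_noise_sd: float = 0.15  # alongshore point scatter, m
    slr_offsets: tuple[float, ...] = (0.0, 0.2, 0.5, 1.2, 2.0)
    seed: int = 0

    def validate(self) -> "SynthParams":
        total = sum(self.cover_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"cover probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.cover_probs.values()):
            raise ValidationError("cover probabilities must be non-negative")
        for lam in list(self.fish_lambda.values()) + list(self.urchin_lambda.values()):
            if lam < 0:
                raise ValidationError("Poisson intensities must be non-negative")
        for sd in (self.mass_noise_sd, self.size_noise_sd, self.twl_noise_sd):
            if sd < 0:
                raise ValidationError("noise SDs must be non-negative")
        return self

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apportion(probs: Sequence[float], total: int) -> list[int]:
    """Largest-remainder apportionment of ``total`` points to ``probs``."""
    raw = [p * total for p in probs]
    base = [int(math.floor(r)) for r in raw]
    short = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def default_layout(n_per_zone: int = 9) -> list[tuple[str, str, str]]:
    """(site_id, sector, habitat) tuples for the stratified 2 x 3 design."""
    abbr_s = {"northern": "N", "southern": "S"}
    abbr_h = {"fore_reef": "FR", "reef_crest": "RC", "back_reef": "BR"}
    layout = []
    for sector in SECTORS:
        for habitat in HABITATS:
            for i in range(1, n_per_zone + 1):
                layout.append(
                    (f"{abbr_s[sector]}-{abbr_h[habitat]}-{i:02d}", sector, habitat)
                )
    return layout


def gen_census(
    params: SynthParams,
    layout: Sequence[tuple[str, str, str]] | None = None,
    exact: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[list[SiteCensus], dict]:
    """Generate site censuses plus a truth record.

    Default layout is the stratified design: 2 sectors x 3 habitats x 9
    sites = 54. In ``exact`` mode every random draw is replaced by its
    expectation — point tallies by largest-remainder apportionment of
    cover x points (exact when cover x points is integral) and Poisson
    counts by their (integral) intensities — so site budgets can be
    compared against closed-form values computed from the parameters.
    """
    params.validate()
    if exact:
        for cat, p in params.cover_probs.items():
            if abs(p * params.points_per_image - round(p * params.points_per_image)) > 1e-9:
                raise ValidationError(
                    f"exact mode: cover of {cat!r} x {params.points_per_image} "
                    "points is not integral"
                )
        for key, lam in {**params.fish_lambda, **params.urchin_lambda}.items():
            if abs(lam - round(lam)) > 1e-9:
                raise ValidationError(
                    f"exact mode: intensity for {key} is not an integer"
                )
    rng = params.rng() if rng is None else rng
    layout = default_layout() if layout is None else list(layout)
    if not layout:
        raise ValidationError("site layout is empty")
    cats = list(params.cover_probs)
    probs = [params.cover_probs[c] for c in cats]
    lo, hi = params.images_per_transect
    sites = []
    for site_id, sector, habitat in layout:
        n_images = lo if exact else int(rng.integers(lo, hi + 1))
        images = []
        for _ in range(n_images):
            if exact:
                counts = _apportion(probs, params.points_per_image)
            else:
                counts = rng.multinomial(params.points_per_image, probs)
            images.append({c: int(n) for c, n in zip(cats, counts) if n > 0})
        fish = []
        for (sp, size_bin, phase), lam in params.fish_lambda.items():
            for transect in (1, 2):
                n = int(round(lam)) if exact else int(rng.poisson(lam))
                if n > 0:
                    fish.append(FishObservation(sp, size_bin, phase, n, transect))
        urchins = []
        for (sp, size_bin), lam in params.urchin_lambda.items():
            n = int(round(lam)) if exact else int(rng.poisson(lam))
            if n > 0:
                urchins.append(UrchinObservation(sp, size_bin, n))
        sites.append(
            SiteCensus(
                site_id=site_id,
                sector=sector,
                habitat=habitat,
                benthic_points=images,
                fish_counts=fish,
                urchin_counts=urchins,
                points_per_image=params.points_per_image,
            ).validate()
        )
    truth = {
        "cover_probs": dict(params.cover_probs),
        "fish_lambda": {"|".join(map(str, k)): v for k, v in params.fish_lambda.items()},
        "urchin_lambda": {
            "|".join(map(str, k)): v for k, v in params.urchin_lambda.items()
        },
        "points_per_image": params.points_per_image,
        "layout": [list(t) for t in layout],
        "exact": exact,
        "seed": params.seed,
    }
    return sites, truth


def gen_growth(
    params: SynthParams,
    n_colonies: int = 30,
    n_visits: int = 5,
    species: str = "Acropora palmata",
    rng: np.random.Generator | None = None,
) -> tuple[list[GrowthRecord], dict]:
    """Generate assay growth series plus a truth record.

    Planar area grows linearly at the truth rate; dry mass follows the
    integral of calcification over the (linearly growing) footprint, so the
    interval-mean-normalised calcification rate equals ``params.calc_rate``
    exactly in the noise-free limit. Visits are every half year. Colonies
    die whole with probability ``mortality_prob`` per interval; once dead a
    colony's visits carry status ``dead`` and are excluded from summaries.
    """
    params.validate()
    rng = params.rng() if rng is None else rng
    records: list[GrowthRecord] = []
    aspect = 1.3  # d_max / d_min of the elliptical footprint
    stations = ("ST1", "ST2", "ST3")
    for i in range(n_colonies):
        cid = f"C{i + 1:03d}"
        station = stations[i % len(stations)]
        alive = True
        for v in range(n_visits):
            t = 0.5 * v
            if v > 0 and alive and rng.random() < params.mortality_prob:
                alive = False
            area = params.initial_area_cm2 + params.area_rate * t
            # dm/dt = rate * area(t): integrate analytically (kg -> g)
            dry = params.initial_dry_mass_g + 1000.0 * params.calc_rate * (
                params.initial_area_cm2 * t + params.area_rate * t**2 / 2.0
            ) / 1e4
            buoyant = dry * (1.0 - RHO_SEAWATER / RHO_ARAGONITE)
            height = params.initial_height_cm + params.height_rate * t
            d_min = math.sqrt(4.0 * area / (math.pi * aspect))
            d_max = aspect * d_min
            if params.mass_noise_sd > 0:
                buoyant += rng.normal(0.0, params.mass_noise_sd)
            if params.size_noise_sd > 0:
                height += rng.normal(0.0, params.size_noise_sd)
                d_max += rng.normal(0.0, params.size_noise_sd)
                d_min += rng.normal(0.0, params.size_noise_sd)
                d_min = min(max(d_min, 0.1), d_max)
            records.append(
                GrowthRecord(
                    colony_id=cid,
                    species=species,
                    station=station,
                    time=t,
                    buoyant_mass=max(buoyant, 0.1),
                    height=max(height, 0.1),
                    d_max=d_max,
                    d_min=d_min,
                    status="alive" if alive else "dead",
                ).validate()
            )
    truth = {
        "calc_rate": params.calc_rate,
        "height_rate": params.height_rate,
        "area_rate": params.area_rate,
        "mass_noise_sd": params.mass_noise_sd,
        "size_noise_sd": params.size_noise_sd,
        "mortality_prob": params.mortality_prob,
        "n_colonies": n_colonies,
        "n_visits": n_visits,
        "seed": params.seed,
    }
    return records, truth


def gen_twl(
    params: SynthParams,
    n_north: int = 145,
    n_south: int = 71,
    rng: np.random.Generator | None = None,
) -> tuple[TWLTable, dict]:
    """Generate a shoreline TWL table plus a truth record.

    max_twl(point, storm, slr) = base(storm) + point scatter + slope x slr:
    monotone in the offset by construction. Point counts default to the
    alongshore transect counts of the study shoreline (145 northern, 71
    southern points).
    """
    params.validate()
    rng = params.rng() if rng is None else rng
    rows = []
    for sector, n_pts in (("northern", n_north), ("southern", n_south)):
        for i in range(n_pts):
            pid = f"{sector[0].upper()}{i + 1:03d}"
            noise = (
                rng.normal(0.0, params.twl_noise_sd) if params.twl_noise_sd > 0 else 0.0
            )
            for storm, base in params.twl_base.items():
                for slr in params.slr_offsets:
                    rows.append(
                        {
                            "point_id": pid,
                            "sector": sector,
                            "storm": storm,
                            "slr_offset": slr,
                            "max_twl": base + noise + params.twl_slope * slr,
                        }
                    )
    table = TWLTable(data=pd.DataFrame(rows)).validate()
    truth = {
        "twl_base": dict(params.twl_base),
        "twl_slope": params.twl_slope,
        "twl_noise_sd": params.twl_noise_sd,
        "n_north": n_north,
        "n_south": n_south,
        "slr_offsets": list(params.slr_offsets),
        "seed": params.seed,
    }
    return table, truth


def write_truth(truth: dict, path) -> None:
    """Write a generator truth record as JSON beside its fixture."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
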