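"""Shared fixtures: a small hand-auditable rate table and census builders."""

import pytest

from reefshield.census import (
    FishObservation,
    RateTable,
    SiteCensus,
    UrchinObservation,
)


@pytest.fixture
def rates() -> RateTable:
    """Small rate table with round numbers so budgets can be hand-checked.

    The urchin rate function is a constant 200 g ind-1 y-1
    (coefficients (200, 0)); parrotfish rates cover only the entries the
    tests observe.
    """
    return RateTable(
        calcification={
            "Acropora palmata": 10.88,
            "coral B": 5.0,
            "crustose coralline algae": 1.0,
        },
        rugosity_correction={"Acropora palmata": 3.3309, "coral B": 2.0},
        coral_density={"Acropora palmata": 1500.0, "coral B": 1800.0},
        parrotfish_rates={
            ("Sparisoma viride", 165, "initial"): 120_000.0,
            ("Scarus vetula", 210, "terminal"): 60_000.0,
        },
        urchin_rate_coeffs=(200.0, 0.0),
        urchin_size_range_mm=(0.0, 200.0),
    ).validate()


def make_site(
    site_id="S1",
    sector="northern",
    habitat="fore_reef",
    images=None,
    fish=(),
    urchins=(),
    points_per_image=75,
) -> SiteCensus:
    """Site with sensible defaults; ``images`` is a list of category->count."""
    if images is None:
        images = [{"sand": points_per_image}]
    return SiteCensus(
        site_id=site_id,
        sector=sector,
        habitat=habitat,
        benthic_points=[dict(im) for im in images],
        fish_counts=list(fish),
        urchin_counts=list(urchins),
        points_per_image=points_per_image,
    )


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def fish_obs():
    return FishObservation


@pytest.fixture
def urchin_obs():
    return UrchinObservation
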