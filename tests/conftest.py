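import numpy as np
import pytest

from beachdiv.incidence import (
    IncidenceMatrix,
    IncidenceSummary,
    SamplingUnit,
    SpeciesTrait,
)


def make_units(n, area=0.25, site="A", period="recent", design="fixed",
               positions=None):
    positions = positions if positions is not None else [float(j) for j in range(n)]
    return [
        SamplingUnit(
            unit_id=f"{site}_{period}_u{j}",
            site=site,
            period=period,
            area_m2=area,
            cross_shore_position_m=positions[j],
            design=design,
        )
        for j in range(n)
    ]


@pytest.fixture
def toy_matrix():
    """5 species over 4 units of 0.25 m² with incidence counts (1,1,2,3,4)."""
    det = np.array(
        [
            [1, 0, 0, 0],  # unique
            [0, 1, 0, 0],  # unique
            [1, 1, 0, 0],  # duplicate
            [1, 1, 1, 0],
            [1, 1, 1, 1],
        ],
        dtype=bool,
    )
    return IncidenceMatrix(
        species_ids=[f"sp{i}" for i in range(5)],
        units=make_units(4),
        detections=det,
    )


@pytest.fixture
def toy_summary():
    return IncidenceSummary(
        R=4,
        S_obs=5,
        Y=np.array([1, 1, 2, 3, 4]),
        Q=np.array([2, 1, 1, 1]),
        A_total=1.0,
        a_bar=0.25,
    )


@pytest.fixture
def toy_traits(toy_matrix):
    """sp2 and sp4 are wrack-associated; sp4 additionally low-dispersal."""
    return {
        sid: SpeciesTrait(
            species_id=sid,
            wrack_associated=sid in ("sp2", "sp4"),
            low_dispersal=sid == "sp4",
        )
        for sid in toy_matrix.species_ids
    }


def random_matrix(rng, max_R=8, max_species=12):
    """A random non-empty incidence matrix for property-style checks."""
    R = int(rng.integers(2, max_R + 1))
    n = int(rng.integers(1, max_species + 1))
    det = rng.random((n, R)) < rng.uniform(0.1, 0.9)
    if not det.any():
        det[0, 0] = True
    return IncidenceMatrix(
        species_ids=[f"sp{i}" for i in range(n)],
        units=make_units(R),
        detections=det,
    )
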