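import pytest

from cliftsim.layout import SpotGrid
from cliftsim.library import FLAG, HA, alternating_probe, permutation_variants
from cliftsim.thermal import thick_foil_stack, thin_film_stack


@pytest.fixture(scope="session")
def thick_foil():
    return thick_foil_stack()


@pytest.fixture(scope="session")
def thin_film():
    return thin_film_stack()


@pytest.fixture(scope="session")
def ha_flag_variants():
    return permutation_variants(HA, FLAG)


@pytest.fixture(scope="session")
def probes():
    return [
        alternating_probe(("Ala", "Gly"), n, "biotin", id=f"probe{n}")
        for n in (3, 6, 9)
    ]


@pytest.fixture
def replicate_grid():
    """4×4 grid of 4 peptide ids, 4 replicates each."""
    ids = [f"pep{r}" for r in range(4) for _ in range(4)]
    return SpotGrid(150.0, 4, 4, assignments=dict(enumerate(ids)))
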