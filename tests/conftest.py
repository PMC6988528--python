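import numpy as np
import pandas as pd
import pytest

from taxback import SimulationConfig, TaxonomyTable, simulate_dataset


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    """Five species, three genera, two tribes, one family.

    Amara has three congeners (one without a subgenus); Blemus is monotypic.
    """
    return TaxonomyTable(
        pd.DataFrame(
            {
                "species": ["Amara aenea", "Amara ovata", "Amara plebeja",
                            "Blemus discus", "Nebria brevicollis"],
                "subgenus": ["Amara s.str.", "Amara s.str.", None, None, None],
                "genus": ["Amara", "Amara", "Amara", "Blemus", "Nebria"],
                "tribe": ["Zabrini", "Zabrini", "Zabrini", "Trechini", "Nebriini"],
                "subfamily": ["Harpalinae", "Harpalinae", "Harpalinae",
                              "Trechinae", "Nebriinae"],
                "family": ["Carabidae"] * 5,
            }
        )
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Deterministic mid-sized synthetic dataset shared across tests."""
    config = SimulationConfig(n_genera=15, images_per_species=25, seed=7)
    taxonomy, specimens, matrix, latent = simulate_dataset(config)
    truths = pd.Series(
        {r.image_id: r.species_label for r in specimens}, name="species"
    )
    return {
        "config": config,
        "taxonomy": taxonomy,
        "specimens": specimens,
        "matrix": matrix,
        "latent": latent,
        "truths": truths,
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
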