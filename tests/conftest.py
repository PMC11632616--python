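import numpy as np
import pytest

from waterbridges.stats_report import build_inventory
from waterbridges.synthetic_fixtures import default_ensemble, generate_fixture

ENSEMBLE_SEED = 2024


@pytest.fixture(scope="session")
def ensemble():
    """The default synthetic survey: manifest, structure, expected inventory.

    Generated once per session; placement is deterministic for a fixed seed.
    """
    manifest = default_ensemble(seed=ENSEMBLE_SEED)
    structure, expected = generate_fixture(manifest)
    return manifest, structure, expected


@pytest.fixture(scope="session")
def ensemble_inventory(ensemble):
    _, structure, _ = ensemble
    return build_inventory(structure)
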