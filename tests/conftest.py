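import warnings

import pytest

from prepolymer import PlantedSystemSpec, annotate, detect_hbonds, make_planted_hbond_system

warnings.filterwarnings("ignore", module="MDAnalysis")


@pytest.fixture(scope="session")
def planted_200_50():
    """The reference planted system: 200 nucleotides, 50 planted bonds, 85 Å box."""
    spec = PlantedSystemSpec(n_nucleotides=200, n_planted_bonds=50, seed=1)
    config, truth = make_planted_hbond_system(spec)
    return config, truth


@pytest.fixture(scope="session")
def planted_200_50_bonds(planted_200_50):
    config, _ = planted_200_50
    topo = annotate(config)
    return detect_hbonds(config, topo)
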