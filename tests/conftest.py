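import pytest

from phasemotif.io import ProteinRecord, RegionAnnotation
from phasemotif.synthetic import GeneratorConfig, PlantSpec, generate_database


@pytest.fixture
def toy_records():
    return [
        ProteinRecord("P1", "FGGGRGGFGGDRGGAAAA", family="RNA-binding",
                      source_set="positive", pdp=0.85),
        ProteinRecord("P2", "LLLVVVILLFAVLLMAIL", family="none",
                      source_set="negative", pdp=0.1),
    ]


@pytest.fixture
def toy_regions():
    return [
        RegionAnnotation("P1", 0, 14, "DPR"),
        RegionAnnotation("P1", 14, 18, "NODPR"),
    ]


@pytest.fixture(scope="session")
def small_database():
    """A small seeded synthetic database shared across tests."""
    config = GeneratorConfig(
        n_positive=20,
        n_negative=20,
        protein_length_range=(300, 400),
        seed=11,
        planted_motifs=[PlantSpec("GGDRGG", presence_fraction=0.6)],
    )
    return generate_database(config)
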