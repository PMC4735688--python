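import pytest

from rarecoal.model import Branch, DemographyModel, JoinEvent, UnitScale


@pytest.fixture(scope="session")
def unit_scale():
    return UnitScale()


@pytest.fixture()
def two_pop_model():
    """Two populations of 4 haploids joining at 0.002 (sizes 1 and 0.5,
    ancestral size 2)."""
    return DemographyModel(
        branches=[Branch("A", 1.0, 4), Branch("B", 0.5, 4)],
        joins=[JoinEvent(0.002, "A", "B", 2.0)],
    )


@pytest.fixture()
def five_pop_model():
    """Five-tip nested tree in the shape used for the recovery study."""
    return DemographyModel(
        branches=[
            Branch("P1", 0.8, 20),
            Branch("P2", 0.6, 20),
            Branch("P3", 1.0, 20),
            Branch("P4", 0.5, 20),
            Branch("P5", 1.2, 20),
        ],
        joins=[
            JoinEvent(0.0020, "P1", "P2", 0.9),
            JoinEvent(0.0035, "P3", "P4", 0.8),
            JoinEvent(0.0050, "P1", "P3", 1.0),
            JoinEvent(0.0080, "P1", "P5", 1.5),
        ],
    )
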