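import pytest

from fsmi.chip import (
    AntibodyRecord,
    ChipDefinition,
    Origin,
    generate_layout,
    ldchip168,
    masechip,
)
from fsmi.simulate import BindingParams, NoiseModel


def build_chip(
    n_antibodies=3,
    replicates=3,
    control_spot_count=6,
    grid=(1, 1),
    clusters=None,
    phyla=None,
    name="tiny",
):
    """Small synthetic panel for unit tests."""
    antibodies = [
        AntibodyRecord(
            antibody_id=f"AB{i + 1}",
            name=f"AB{i + 1}",
            immunogen_source=f"strain {i + 1}",
            origin=Origin.MASE_ISOLATE,
            cluster=(clusters[i] if clusters else ""),
            phylum=(phyla[i] if phyla else ""),
        )
        for i in range(n_antibodies)
    ]
    return ChipDefinition(
        name=name,
        antibodies=antibodies,
        replicates_per_antibody=replicates,
        control_spot_count=control_spot_count,
        grid=grid,
    )


@pytest.fixture(scope="session")
def mase():
    return masechip()


@pytest.fixture(scope="session")
def mase_layout(mase):
    return generate_layout(mase)


@pytest.fixture(scope="session")
def ldchip():
    return ldchip168()


@pytest.fixture(scope="session")
def binding():
    return BindingParams.default()


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel.default()


@pytest.fixture
def tiny_chip():
    return build_chip()
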