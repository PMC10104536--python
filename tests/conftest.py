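import pytest

from preribo.simulate import make_reference

SMALL_REGIONS = {
    "NTS": 100,
    "5'ETS": 200,
    "18S": 600,
    "ITS1": 150,
    "5.8S": 100,
    "ITS2": 100,
    "25S": 500,
    "3'ETS": 100,
}


@pytest.fixture(scope="session")
def ref():
    """Full-size synthetic 45S rDNA unit (~7.7 kb)."""
    return make_reference(1)


@pytest.fixture(scope="session")
def small_ref():
    """Compact (<2 kb) reference for exhaustive-oracle comparisons."""
    return make_reference(1, region_lengths=SMALL_REGIONS,
                          a2_offset_from_d=60, a3_offset_from_d=120)
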