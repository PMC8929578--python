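import pytest

from ononis_cns.io import load_fixture_compounds
from ononis_cns.pampa import PampaGeometry


@pytest.fixture(scope="session")
def panel():
    """The bundled eight-compound isoflavonoid panel."""
    return load_fixture_compounds()


@pytest.fixture(scope="session")
def characterized(panel):
    """The six compounds with measured logP/logD74/logPe, by id."""
    return {r.id: r for r in panel if r.logPe is not None}


@pytest.fixture(scope="session")
def geometry():
    return PampaGeometry()
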