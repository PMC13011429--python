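import numpy as np
import pytest

from intronscan.synthetic_genomes import make_locus_fixture


@pytest.fixture(scope="session")
def asn_fixture():
    """A plus-strand Asn(GTT) 35/36 fixture with exact candidate boundaries."""
    return make_locus_fixture(11, site="35/36", anticodon="GTT", jitter=0,
                              strand="+", db_identity=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
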