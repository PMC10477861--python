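import numpy as np
import pytest

from acpmine import PeptideCatalog, PeptideRecord, generate_catalog


def make_catalog(seqs, prefix="p", name="test"):
    return PeptideCatalog(
        records=[PeptideRecord(id=f"{prefix}{i + 1}", sequence=s)
                 for i, s in enumerate(seqs)],
        name=name,
    )


@pytest.fixture
def toy_catalog():
    return make_catalog(["MKTPWRA", "AAAKKKDDD", "GHILVWYCMF"])


@pytest.fixture
def random_catalog():
    return generate_catalog(8, (12, 20), seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
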