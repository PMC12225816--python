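import pytest

from skelvox import db


@pytest.fixture(scope="session")
def curated():
    return db.load_db("curated")


@pytest.fixture(scope="session")
def raw():
    return db.load_db("raw")
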