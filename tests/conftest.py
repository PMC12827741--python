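import pytest

import pseudolink as pl


@pytest.fixture
def pid_config():
    return pl.PIDConfig(mixing_key=b"unit-test-key")


@pytest.fixture
def store():
    """Default-schema store with an internal check-charactered `pid` type."""
    return pl.default_store(b"unit-test-key")


@pytest.fixture
def linkage_config():
    return pl.default_linkage_config()


@pytest.fixture
def bloom_config():
    return pl.BloomFilterConfig(hmac_secret=b"unit-test-secret")


ANNA = {
    "first_name": "Anna",
    "last_name": "Meier",
    "birth_day": 4,
    "birth_month": 7,
    "birth_year": 1981,
    "city": "Mainz",
}

ANNA_MARRIED = {
    "first_name": "Anna",
    "last_name": "Schmidt",
    "birth_day": 4,
    "birth_month": 7,
    "birth_year": 1981,
    "city": "Heidelberg",
}

BORIS = {
    "first_name": "Boris",
    "last_name": "Krause",
    "birth_day": 12,
    "birth_month": 1,
    "birth_year": 1970,
    "city": "Berlin",
}


@pytest.fixture
def anna():
    return dict(ANNA)


@pytest.fixture
def anna_married():
    return dict(ANNA_MARRIED)


@pytest.fixture
def boris():
    return dict(BORIS)
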