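import pytest

from hamr.synthetic import (
    FixtureSpec,
    build_fixture,
    make_butane,
    make_hexagon,
    make_macrolactone12,
)


@pytest.fixture(scope="session")
def butane():
    return make_butane()


@pytest.fixture(scope="session")
def hexagon():
    return make_hexagon()


@pytest.fixture(scope="session")
def macrolactone():
    return make_macrolactone12()


@pytest.fixture(scope="session")
def crystal_fixture():
    """Noise-free macrolactone12 crystal at 1.0 Å (the headline fixture)."""
    return build_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def cheap_crystal_fixture():
    """Same crystal truncated to 1.3 Å: smaller data for fast MR tests."""
    return build_fixture(FixtureSpec(d_min=1.3))
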