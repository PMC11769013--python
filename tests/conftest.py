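import pytest

from cardiobox import (
    AllometricExponents,
    DISPLAY_ORDER,
    Strategy,
    build_all,
    load_packaged_displayed_limits,
    load_packaged_reference,
)

# Example exponents for exercising the normalisation layer in tests.
# These are synthetic stand-ins, NOT the published allometric constants
# (which the package deliberately does not ship).
EXAMPLE_EXPONENTS = dict(zip(DISPLAY_ORDER, (0.33, 0.25, 0.29, 0.24, 0.26, 0.30, 0.23)))


@pytest.fixture(scope="session")
def exponent_map():
    return dict(EXAMPLE_EXPONENTS)


@pytest.fixture(scope="session")
def exponents():
    return AllometricExponents(EXAMPLE_EXPONENTS)


@pytest.fixture(scope="session")
def reference_table():
    """The packaged reference percentile grid (802 healthy / 2967 total dogs)."""
    return load_packaged_reference()


@pytest.fixture(scope="session")
def published_limits():
    """The packaged published displayed box limits."""
    return load_packaged_displayed_limits()


@pytest.fixture(scope="session")
def limits_set(reference_table):
    """Box limits built from the packaged reference, default strategy."""
    return build_all(reference_table, Strategy.TABLE_CONSISTENT)
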