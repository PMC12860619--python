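import pytest

from apoennt import builtin_tables, get_builtin


@pytest.fixture(scope="session")
def lec_aria_e():
    return get_builtin("lecanemab", "any-ARIA-E")


@pytest.fixture(scope="session")
def lec_aria_h():
    return get_builtin("lecanemab", "any-ARIA-H")


@pytest.fixture(scope="session")
def lec_sympt():
    return get_builtin("lecanemab", "symptomatic-ARIA-E")


@pytest.fixture(scope="session")
def don_aria_h():
    return get_builtin("donanemab", "any-ARIA-H")


@pytest.fixture(scope="session")
def all_tables():
    return builtin_tables()
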