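import pytest

from pkitargets import generate_catalog
from pkitargets.records import PromiscuityProfile


@pytest.fixture(scope="session")
def catalog200():
    """The default-sized synthetic benchmark: 200 compounds, seed 11."""
    return generate_catalog(n_compounds=200, seed=11)


@pytest.fixture(scope="session")
def catalog_small():
    """A small catalog for cheap cross-module checks."""
    return generate_catalog(
        n_compounds=40, n_pk_targets=15, n_nonpk_targets=10, seed=5
    )


def _profile(ck, pk, nonpk):
    return PromiscuityProfile(ck, frozenset(pk), frozenset(nonpk))


@pytest.fixture
def toy_profiles():
    """c1 and c2 share targets A and X; T3/Y are singletons."""
    return [
        _profile("c1", {"A", "B"}, {"X"}),
        _profile("c2", {"A"}, {"X", "Y"}),
        _profile("c3", {"T3"}, {"X"}),
    ]
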