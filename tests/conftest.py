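import pytest

from redalph import published_collection
from redalph.alphabet_io import loads_collection


@pytest.fixture(scope="session")
def published():
    """The bundled 34-alphabet reconstruction."""
    return published_collection()


@pytest.fixture()
def toy_collection():
    """Three tiny hand-written alphabets (a1 == a3, a2 is their opposite)."""
    return loads_collection(
        "a1\tone group\tother\tACDEFGHIKLMNPQRSTVWY\n"
        "a2\tsingletons\tother\tA,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y\n"
        "a3\tone group again\tother\tACDEFGHIKLMNPQRSTVWY\n"
    )
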