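import pytest
from hypothesis import settings

from evoincentives import donation_game, public_goods_game

# derandomized property tests: the same examples on every run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def dg():
    """The small worked-example Donation game: b=1.8, c=1."""
    return donation_game(1.8, 1.0)


@pytest.fixture
def dg2():
    """Donation game b=2, c=1 used in the limit experiments."""
    return donation_game(2.0, 1.0)


@pytest.fixture
def pgg():
    """Public Goods game r=3, n=5, c=1."""
    return public_goods_game(1.0, 3.0, 5)
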