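import numpy as np
import pytest

import coopcost as cc


@pytest.fixture
def dg3():
    """Donation game, N=3, B=2, c=1 (payoff gap -2)."""
    return cc.donation_game(3)


@pytest.fixture
def dg6():
    return cc.donation_game(6)


@pytest.fixture
def reward():
    def make(theta, t=1, a=1.0):
        return cc.IncentiveScheme(cc.Kind.REWARD, theta, t, a=a)

    return make


def small_game_grid():
    """A spread of valid DG and PGG specs used by several property tests."""
    games = []
    for N in (3, 5, 8, 12):
        games.append(cc.donation_game(N, B=2, c=1))
        games.append(cc.donation_game(N, B=5, c=0.5))
        if N >= 4:
            games.append(cc.public_goods_game(N, c=1, r=2, n=min(4, N)))
        games.append(cc.public_goods_game(N, c=2, r=1.5, n=3))
    return games
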