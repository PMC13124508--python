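import numpy as np
import pytest

from imtscast.core import (IMTSEpisode, IrregularSeries, Observation, Query)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_episode(episode_id="ep0", n_variables=3, n_obs=12, T=24.0, H=24.0,
                 n_queries=3, seed=0, value_fn=None):
    """Deterministic hand-rolled episode for unit tests."""
    r = np.random.default_rng(seed)
    series = []
    for i in range(n_variables):
        t = np.sort(r.uniform(0, T, n_obs))
        t = np.unique(t)
        if value_fn is None:
            v = r.normal(0, 1, len(t))
        else:
            v = value_fn(i, t)
        series.append(IrregularSeries(
            i + 1, tuple(Observation(float(a), float(b))
                         for a, b in zip(t, v))))
    queries = []
    for i in range(n_variables):
        taus = np.sort(r.uniform(T + 0.01, T + H, n_queries))
        for tau in taus:
            target = (float(r.normal()) if value_fn is None
                      else float(value_fn(i, np.array([tau]))[0]))
            queries.append(Query(i + 1, float(tau), target))
    return IMTSEpisode(episode_id, tuple(series), T, H, tuple(queries))


@pytest.fixture
def episode():
    return make_episode()
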