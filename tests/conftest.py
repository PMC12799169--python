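import numpy as np
import pytest

from netcoord import (
    CAAParams,
    HashedNGramEmbedder,
    NetworkSpec,
    RunConfig,
    fukushima_event_set,
    make_toy_transcript,
    run_simulation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_transcript():
    return make_toy_transcript()


@pytest.fixture(scope="session")
def small_name_game_transcript():
    """A short simulated naming-game run (<= 200 rows) for oracle checks."""
    config = RunConfig(
        network=NetworkSpec(size=10, structure="homogeneous"),
        T=20,
        content="name",
        model="name_game",
        seed=7,
    )
    return run_simulation(config)


@pytest.fixture(scope="session")
def small_caa_transcript():
    config = RunConfig(
        network=NetworkSpec(size=8, structure="spatial"),
        T=25,
        content="hashtag",
        model="caa",
        caa_params=CAAParams(alpha=0.6),
        seed=11,
    )
    return run_simulation(config)


@pytest.fixture(scope="session")
def embedder():
    return HashedNGramEmbedder()


@pytest.fixture(scope="session")
def events():
    return fukushima_event_set()
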