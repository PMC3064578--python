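import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cport import (
    ResidueId,
    ScoreTable,
    SyntheticSpec,
    simulate_scores,
    toy_complex,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def rid(chain: str, number: int, icode: str = "") -> ResidueId:
    return ResidueId(chain, number, icode)


@pytest.fixture
def toy_reference():
    """Two-chain pseudo-backbone complex with a central planted interface."""
    return toy_complex(20, seed=11)


@pytest.fixture
def small_scores():
    """Deterministic six-predictor fixture with a planted interface."""
    spec = SyntheticSpec(n_chains=3, chain_length=40, signal=0.9, seed=7)
    return simulate_scores(spec)


def make_score_table(values: dict, predictor: str = "WHISCY", direction: str = "higher_is_better") -> ScoreTable:
    """Helper: ScoreTable from {(chain, resnum): score}."""
    return ScoreTable(
        predictor,
        direction,
        {ResidueId(c, n): s for (c, n), s in values.items()},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
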