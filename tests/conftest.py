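import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from trustpomcp import PlannerContext, SearchConfig


@pytest.fixture(scope="session")
def small_config() -> SearchConfig:
    """Small but non-trivial search budget for fast end-to-end tests."""
    return SearchConfig(n_paths=200, nested_n_paths=40)


@pytest.fixture(scope="session")
def shared_ctx(small_config) -> PlannerContext:
    """Session-wide planner context: results are key-seeded, so sharing
    caches across tests changes nothing but speed."""
    return PlannerContext(small_config)
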