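"""Shared fixtures: configurations and a cached synthetic battery."""

from __future__ import annotations

import pytest

from stemtrace.directed_search import SearchConfig
from stemtrace.synthetic import Battery, generate_battery


@pytest.fixture(scope="session")
def default_cfg() -> SearchConfig:
    return SearchConfig()


@pytest.fixture(scope="session")
def small_battery() -> Battery:
    """Sixty default-parameter plants, reused by every test that only
    needs a representative sample."""
    return generate_battery(60, seed=11)
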