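"""Shared fixtures: tooling geometry and cached synthetic campaigns."""

import pytest

from tabrom.reference_models import get_truth
from tabrom.rom_core import TabletGeometry
from tabrom.synthetic import DEFAULT_GEOMETRY, CampaignSpec, simulate_campaign


@pytest.fixture(scope="session")
def geom() -> TabletGeometry:
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def cs_truth():
    return get_truth("cs")


@pytest.fixture(scope="session")
def mgst_truth():
    return get_truth("mgst")


@pytest.fixture(scope="session")
def cs_runs_clean():
    """Noise-free 30-run glidant campaign."""
    runs, _ = simulate_campaign(CampaignSpec(campaign="cs", seed=5).without_noise())
    return runs


@pytest.fixture(scope="session")
def mgst_runs_clean():
    """Noise-free 20-run lubricant campaign."""
    runs, _ = simulate_campaign(CampaignSpec(campaign="mgst", seed=5).without_noise())
    return runs
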