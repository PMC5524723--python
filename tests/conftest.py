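"""Shared fixtures: seeded synthetic tank scenes."""

import pytest

from aquaenhance.synth import SceneConfig, fixture_suite, generate


@pytest.fixture(scope="session")
def scene42():
    """Default low-contrast tank scene, seed 42, with ground truth."""
    return generate(SceneConfig(seed=42))


@pytest.fixture(scope="session")
def suite10():
    """The ten-scene fixture suite (seeds 100..109) with ground truth."""
    return fixture_suite(10, 100)
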