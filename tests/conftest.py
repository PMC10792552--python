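"""Shared fixtures: the two bundled scenarios, analyzed once per session."""

from dataclasses import dataclass

import pytest

from anesmap import assemble_recording, deep_scenario, light_scenario, run_pipeline


@dataclass
class Bundle:
    config: object
    rec: object
    truth: object
    result: object


def _analyze(config):
    rec, truth = assemble_recording(config)
    return Bundle(config=config, rec=rec, truth=truth, result=run_pipeline(rec))


@pytest.fixture(scope="session")
def deep_bundle():
    """Deep-anesthesia scenario (burst suppression + gamma rebound), analyzed."""
    return _analyze(deep_scenario(seed=7))


@pytest.fixture(scope="session")
def light_bundle():
    """Light-anesthesia scenario (no IES, no gamma rebound), analyzed."""
    return _analyze(light_scenario(seed=11))
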