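"""Shared fixtures: one default synthetic world analysed end to end."""

import warnings

import pytest

import ecofoot as ef
from ecofoot.pipeline import analyze_world


@pytest.fixture(scope="session")
def world():
    return ef.generate(ef.WorldConfig(seed=0))


@pytest.fixture(scope="session")
def analysis(world):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_world(world)
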