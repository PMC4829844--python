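"""Shared fixtures: one toy genome and one control panel per session.

The control panel and its derived reference are expensive relative to a
single sample, so they are built once and shared; replicate tests vary
only the tumor sample, which leaves the statistics unchanged.
"""

import numpy as np
import pytest

import chordcna as cc
from chordcna.normalize import build_reference, correct_panel


@pytest.fixture(scope="session")
def toy_genome():
    return cc.build_genome("toy", 100_000, seed=1)


@pytest.fixture(scope="session")
def control_panel(toy_genome):
    return cc.simulate_control_panel(toy_genome, 30, seed=3)


@pytest.fixture(scope="session")
def panel_corrected(toy_genome, control_panel):
    return correct_panel(control_panel, toy_genome)


@pytest.fixture(scope="session")
def reference(toy_genome, control_panel, panel_corrected):
    return build_reference(control_panel, toy_genome, corrected=panel_corrected)


@pytest.fixture(scope="session")
def table1_profiles():
    return cc.table1_str_profiles()
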