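"""Shared fixtures: the canonical synthetic experiment and small helpers."""

from __future__ import annotations

import pytest

from sagetally import SimulationSpec, build_index, simulate_experiment


@pytest.fixture(scope="session")
def default_spec():
    """The standard study conditions: 500 tags, depth 2e5, 4-fold effect."""
    return SimulationSpec(seed=1)


@pytest.fixture(scope="session")
def default_experiment(default_spec):
    """(transcripts, truth, tables) for the canonical seed-1 experiment."""
    return simulate_experiment(default_spec)


@pytest.fixture(scope="session")
def default_index(default_experiment):
    transcripts, _, _ = default_experiment
    return build_index(transcripts)
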