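"""Shared fixtures: the canonical mixed synthetic scenario, built once.

The default mixed scenario (6 h of hour-long quiet / mild-exercise /
severe-smoke episodes, twice each) is the workhorse for pipeline-level
tests; building it through the full preprocessing + feature pipeline takes
several seconds, so it is session-scoped.
"""

from __future__ import annotations

import pytest

from asthmawatch.pipeline import build_dataset
from asthmawatch.synth import default_mixed_script, generate


@pytest.fixture(scope="session")
def mixed_dataset():
    """Generated default mixed scenario (seed 0)."""
    config, script = default_mixed_script()
    return generate(config, script)


@pytest.fixture(scope="session")
def mixed_windowed(mixed_dataset):
    """The mixed scenario run through the full feature pipeline, labeled."""
    ds = mixed_dataset
    return build_dataset(
        ds.records, ds.profile, ds.online, acts=ds.acts, windows=ds.windows
    )


@pytest.fixture(scope="session")
def mixed_xy(mixed_windowed):
    X, y = mixed_windowed.labeled()
    return X, y
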