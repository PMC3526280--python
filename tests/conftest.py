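"""Shared fixtures: cached pipeline runs on the organism-style methylomes.

Full pipeline runs are the expensive part of the suite, so each fixture
genome is analyzed once per session and the result shared across motif
recovery, extent, residual and acceptance tests.
"""

from __future__ import annotations

import functools

import pytest

from kinmeth.pipeline import PipelineConfig, PipelineResult, run_pipeline

#: the seed used for all cached fixture analyses in this suite
SUITE_SEED = 1


@functools.lru_cache(maxsize=None)
def _run(name: str) -> PipelineResult:
    target = 0.05 if name == "bce" else 0.01
    config = PipelineConfig(fixture=name, seed=SUITE_SEED, target_unassigned=target)
    return run_pipeline(config)


@pytest.fixture(scope="session")
def pipeline_for():
    """Factory returning the cached pipeline result for a fixture name."""
    return _run
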