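"""Shared fixtures: the default planted benchmark and its screen results.

Building the benchmark and screening it are the expensive steps, so both
are session-scoped; every test that inspects recovery shares one run.
"""

from __future__ import annotations

from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from evescout import pipeline, synth
from evescout.config import ScreenConfig

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: user-supplied public accession sequences (see data/accessions/README.md)
ACCESSION_DIR = Path(__file__).resolve().parents[1] / "data" / "accessions"


@pytest.fixture(scope="session")
def benchmark():
    return synth.make_benchmark(seed=synth.DEFAULT_BENCHMARK_SEED)


@pytest.fixture(scope="session")
def screen_config():
    return ScreenConfig()


@pytest.fixture(scope="session")
def screen_candidates(benchmark, screen_config):
    return pipeline.run_screen(benchmark.contigs, benchmark.queries, screen_config)


@pytest.fixture(scope="session")
def truth_matches(benchmark, screen_candidates):
    return pipeline.match_candidates_to_truth(screen_candidates, benchmark.truths)
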