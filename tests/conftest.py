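"""Shared fixtures: pre-analysed synthetic sessions and one cohort.

The heavy fixtures are session-scoped so the 10-seed sweeps and the
longitudinal cohort are generated and analysed once for the whole run.
"""

from __future__ import annotations

import numpy as np
import pytest

import betasleep as bs
from betasleep.pipeline import PipelineConfig, run_cohort, run_session

SEEDS = tuple(range(1, 11))

#: minimum scored REM windows (1 min) before a session's REM spectrum is used
MIN_REM_WINDOWS = 30


class AnalysedSession:
    """One generated session plus everything the pipeline derived from it."""

    def __init__(self, seed: int, config: bs.GeneratorConfig, keep_recording: bool):
        rec, truth, bursts = bs.simulate_session(config, seed=seed)
        self.seed = seed
        self.result = run_session(rec, PipelineConfig())
        self.truth = truth
        self.bursts = bursts
        self.recording = rec if keep_recording else None

    @property
    def n_rem(self) -> int:
        return self.result.n_windows_by_state.get(bs.REM, 0)


def _sweep(config: bs.GeneratorConfig) -> list[AnalysedSession]:
    return [AnalysedSession(s, config, keep_recording=(s <= 2)) for s in SEEDS]


@pytest.fixture(scope="session")
def wt_runs():
    return _sweep(bs.GeneratorConfig.wild_type())


@pytest.fixture(scope="session")
def r61_runs():
    return _sweep(bs.GeneratorConfig.r61_symptomatic())


@pytest.fixture(scope="session")
def cohort_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    sim = bs.simulate_cohort(out, seed=1)
    result = run_cohort(sim["manifest"], sim["clasping"], PipelineConfig())
    return {"sim": sim, "result": result}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
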