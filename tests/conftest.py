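import numpy as np
import pytest

from tenscalib.core import ParamGrid
from tenscalib.pipeline import run_offline_pipeline
from tenscalib.subjects import CohortSpec, generate_trials, sample_cohort


@pytest.fixture(scope="session")
def grid() -> ParamGrid:
    return ParamGrid()


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Tiny cohort for fast environment fits."""
    return CohortSpec(
        n_men=3,
        n_women=3,
        trials_per_nerve={"peroneal": 40, "tibial": 20, "sural": 20},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec, grid):
    return sample_cohort(small_spec, grid)


@pytest.fixture(scope="session")
def small_trials(small_cohort, small_spec, grid):
    return generate_trials(small_cohort, small_spec, grid)


@pytest.fixture(scope="session")
def trained_run():
    """Full offline pipeline (dataset, environment, both trained agents).

    Trained once per session and shared by every test that needs agents;
    episode budget reduced relative to the library default to keep the suite
    quick while leaving the policies well converged.
    """
    return run_offline_pipeline(seed=1, episodes=1200)


@pytest.fixture(scope="session")
def bench_cohort(grid):
    """Noiseless 15-nerve benchmark: five subjects x three nerves."""
    subjects = []
    for k, nerve in enumerate(("peroneal", "tibial", "sural")):
        spec = CohortSpec(
            n_men=3, n_women=2, trials_per_nerve={nerve: 1}, seed=101 + k
        )
        subjects.extend(sample_cohort(spec, grid))
    return subjects


@pytest.fixture(scope="session")
def bench_records(trained_run, bench_cohort):
    """RL/BFA/naive benchmark records on the 15-nerve cohort."""
    from tenscalib.evaluation import run_benchmark

    return run_benchmark(
        bench_cohort,
        trained_run.agent_low,
        trained_run.agent_high,
        trained_run.trials,
        seed=0,
    )
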