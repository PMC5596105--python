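import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sporomir.config import SimConfig
from sporomir.evaluate import evaluate
from sporomir.pipeline import run_pipeline
from sporomir.simulate import simulate

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The default-scale simulated experiment and its full pipeline run.

    40 planted MIR loci, 18 libraries x 100k reads, fixed seed; shared by
    the planted-truth recovery and invariant tests.
    """
    outdir = tmp_path_factory.mktemp("default_sim")
    cfg = SimConfig(seed=1)
    sim = simulate(cfg, outdir)
    result = run_pipeline(outdir)
    metrics = evaluate(result, sim.truth)
    return cfg, sim, result, metrics


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A reduced simulated experiment for cheaper cross-module checks."""
    outdir = tmp_path_factory.mktemp("small_sim")
    cfg = SimConfig(
        seed=11,
        reads_per_library=20_000,
        n_mir_loci=15,
        n_transcripts=120,
        n_regulator_transcripts=40,
    )
    sim = simulate(cfg, outdir)
    result = run_pipeline(outdir)
    return cfg, sim, result
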