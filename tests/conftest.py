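import pytest

from chm_atlas.pipeline import RunConfig, run_all
from chm_atlas.synthetic_data import SimConfig, simulate


def small_sim_config(seed: int = 7) -> SimConfig:
    """A 2-Mb two-chromosome study small enough for per-module tests."""
    return SimConfig(
        seed=seed,
        chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000},
        n_universal_chm=10, n_process_chm=6, n_chnonm=6, n_cmnonh=6,
        n_cpgrich_nonchm=8,
    )


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_data(small_config):
    """(sequences, truth, tracks, annotations) for the small study."""
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_report(small_config):
    return run_all(RunConfig(sim=small_config))


@pytest.fixture(scope="session")
def full_run():
    """Default study conditions (10-Mb genome, 6 processes, seed 1):
    the dataset plus the full pipeline report."""
    config = RunConfig(sim=SimConfig(seed=1))
    report = run_all(config)
    return config, report
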