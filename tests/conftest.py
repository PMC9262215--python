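import pytest

from cuboidms.isotope_model import AveragineRatioModel
from cuboidms.pipeline import run_pipeline
from cuboidms.raw_model import PipelineConfig, partition_points
from cuboidms.synthetic_data import SimulationConfig, simulate_run


@pytest.fixture(scope="session")
def model():
    return AveragineRatioModel()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_run():
    """A 30-peptide synthetic run with noise and detector clipping."""
    return simulate_run(SimulationConfig(n_peptides=30, random_seed=7))


@pytest.fixture(scope="session")
def small_result(small_run, config, model):
    points = partition_points(small_run.all_points())
    return run_pipeline(points, small_run.isolation_windows, config, model)


@pytest.fixture(scope="session")
def clean_run():
    """Noise-free, unclipped run for parameter-recovery checks."""
    return simulate_run(
        SimulationConfig(
            n_peptides=25,
            ms1_noise_per_frame=0.0,
            ms2_noise_per_frame=0.0,
            clip=False,
            random_seed=11,
        )
    )


@pytest.fixture(scope="session")
def clean_result(clean_run, config, model):
    points = partition_points(clean_run.all_points())
    return run_pipeline(points, clean_run.isolation_windows, config, model)
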