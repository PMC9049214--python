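import pytest

from abxaudit.pipeline import RunConfig, run_pipeline
from abxaudit.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled generator config: 5 institutions, 46 months.

    46 months (June 2017 - March 2021) keep >= 4 post-interruption
    months so the segmented fit is identified while the dataset stays
    around ten thousand visits.
    """
    return SimulationConfig(
        seed=7, months=46,
        institutions={("urban", "CHSC_TH"): 1, ("urban", "CHSS_VC"): 2,
                      ("rural", "CHSC_TH"): 1, ("rural", "CHSS_VC"): 1},
        monthly_visits={"CHSC_TH": 60, "CHSS_VC": 30},
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("synthetic")
    paths, ground_truth = simulate_dataset(small_config, outdir)
    return outdir, ground_truth


@pytest.fixture(scope="session")
def pipeline_bundle(tmp_path_factory, small_dataset):
    data_dir, ground_truth = small_dataset
    outdir = tmp_path_factory.mktemp("bundle")
    config = RunConfig.for_data_dir(data_dir, outdir=outdir,
                                    fit_or_model=False)
    bundle = run_pipeline(config)
    return bundle, ground_truth, config
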