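import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from erpathway.calibration import calibrate_model
from erpathway.pathway_model import TargetGeneSpec, build_model
from erpathway.simulate import GeneratorConfig, generate_calibration_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def std_gene():
    """An informative, symmetric gene: CPTs 0.95/0.05 and 0.9/0.1."""
    return TargetGeneSpec("G1", 0.95, 0.05, 0.9, 0.1)


@pytest.fixture
def symmetric_model():
    """Three symmetric genes, neutral prior: midpoint score is exactly 50."""
    genes = [TargetGeneSpec(f"G{i}", 0.95, 0.05, 0.9, 0.1) for i in range(1, 4)]
    return build_model(genes, prior_active=0.5)


def random_gene(rng, gene_id):
    p = rng.uniform(0.05, 0.95, size=4)
    return TargetGeneSpec(gene_id, *p)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def calibrated(default_config):
    """Calibration set and calibrated model under the default generator."""
    calib = generate_calibration_set(default_config)
    result = calibrate_model(calib)
    return calib, result
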