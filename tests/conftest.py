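import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from phosq import (  # noqa: E402
    SimConfig,
    fit_normalization,
    glog_transform,
    simulate_experiment,
)


def null_config(seed: int, n_proteins: int = 1667) -> SimConfig:
    """A configuration with every planted effect switched off."""
    return SimConfig(
        n_proteins=n_proteins,
        fraction_differential=0.0,
        pathway_n_proteins=0,
        n_motif_sites=0,
        protein_diff_fraction=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment (~1200 sites), shared across tests."""
    return simulate_experiment(SimConfig(n_proteins=400, seed=7))


@pytest.fixture(scope="session")
def glog_phospho(default_experiment):
    _, phospho, _, _, _, _ = default_experiment
    params = fit_normalization(phospho)
    return glog_transform(phospho, params)
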