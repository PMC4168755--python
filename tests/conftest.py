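import pytest
from hypothesis import HealthCheck, settings

from nmrtopo import pre_restraints as prem
from nmrtopo import synthetic_data as sd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_truth() -> sd.GroundTruth:
    """The five-helix, 125-residue, seven-label synthetic study configuration."""
    return sd.study_truth(seed=1)


@pytest.fixture(scope="session")
def pre_params() -> prem.PREParams:
    return prem.PREParams()


@pytest.fixture(scope="session")
def noise_free_restraints(study_truth, pre_params):
    """All seven sites' restraints from noise-free forward simulation."""
    restraints = []
    for site in study_truth.label_sites:
        pairs = sd.simulate_pre(study_truth, site, pre_params, 0.0,
                                seed=site.residue.index)
        built, _ = prem.build_restraints(
            prem.classify_pairs(pairs, site, pre_params), pre_params)
        restraints.extend(built)
    return restraints


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """A complete synthetic study directory at the default noise level."""
    out = tmp_path_factory.mktemp("study")
    sd.generate_study(out, seed=11)
    return out
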