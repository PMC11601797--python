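import warnings

import pytest

from htscurate.curation import run_curation_pipeline
from htscurate.synthetic import CampaignSpec, generate_library, simulate_screens

# RDKit-based filters are exercised on deliberately broken inputs; the
# toolkit reports problems through flags/reasons, not through warnings
# we want to fail on.
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def noiseless_spec():
    return CampaignSpec(
        n_compounds=400,
        true_hit_rate=0.01,
        primary_fp_rate=0.0,
        primary_fn_rate=0.0,
        counter_cross_react_rate=0.0,
        artifact_counts={"duplicates": 6, "mixtures": 5, "salts": 8,
                         "charged": 8, "pains_like": 5, "ro5_violators": 5},
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_campaign(noiseless_spec):
    return simulate_screens(generate_library(noiseless_spec))


@pytest.fixture(scope="session")
def curated_noiseless(noiseless_campaign):
    return run_curation_pipeline(noiseless_campaign.records,
                                 noiseless_campaign.hierarchy)


@pytest.fixture(scope="session")
def noisy_campaign():
    spec = CampaignSpec(n_compounds=600, seed=23)
    return simulate_screens(generate_library(spec))
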