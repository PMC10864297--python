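import pytest

from roambait import ScenarioParams, generate_trial_table


@pytest.fixture(scope="session")
def negativity_dataset():
    """A study-sized dataset with a strong planted negativity bias."""
    params = ScenarioParams(scenario="negativity_bias", n_per_group=40,
                            effect_scale=2.0, seed=7)
    return generate_trial_table(params)


@pytest.fixture(scope="session")
def null_dataset():
    params = ScenarioParams(scenario="null", n_per_group=40, seed=11)
    return generate_trial_table(params)
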