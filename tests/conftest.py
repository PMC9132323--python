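import pytest

from shapebias import stimuli


@pytest.fixture(scope="session")
def templates():
    return stimuli.make_templates(0)


@pytest.fixture(scope="session")
def small_manifests():
    """Small symbolic datasets per (experiment, variant), generated once."""
    cache = {}

    def get(experiment_id, variant, n_train=100, n_test=20, seed=11):
        key = (experiment_id, variant, n_train, n_test, seed)
        if key not in cache:
            cache[key] = stimuli.generate_dataset(
                experiment_id, variant, n_train=n_train,
                n_test_per_condition=n_test, seed=seed)
        return cache[key]

    return get
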