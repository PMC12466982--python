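import pytest

from hirukit.synthetic import default_config, generate_study


@pytest.fixture(scope="session")
def study_bundle():
    """One study-shaped synthetic bundle, shared read-only across tests."""
    return generate_study(default_config(master_seed=7))
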