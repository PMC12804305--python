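import pytest

from biodist import SynthConfig, analyze_study, generate_study


@pytest.fixture(scope="session")
def clean_study():
    """A two-group, zero-noise virtual study plus its ground truth."""
    bundle, truth = generate_study(
        SynthConfig(groups=("baseline", "block"), n_animals=3, seed=42))
    return bundle, truth


@pytest.fixture(scope="session")
def clean_results(clean_study):
    bundle, truth = clean_study
    return analyze_study(bundle), truth
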