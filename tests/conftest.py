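import warnings

import pytest

from respicard import pipeline, synthetic_data as sd

#: seed for the shared full-resolution study; fixed so the suite is reproducible
FULL_STUDY_SEED = 7


@pytest.fixture(scope="session")
def full_study():
    """32-fish factorial study at full trace resolution (optode noise 0.2% sat)."""
    design = sd.default_design(seed=FULL_STUDY_SEED, n_per_group=8)
    return sd.simulate_study(design)


@pytest.fixture(scope="session")
def full_analysis(full_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.analyze_study(full_study)
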