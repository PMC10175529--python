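import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from radrobust import StudyConfig
from radrobust import robustness_pipeline as rp


@pytest.fixture(scope="session")
def small_study():
    """A 4-platform, 2-type, 2-repeat study at default conditions."""
    cfg = StudyConfig(n_platforms=4)
    return rp.run_full_study(cfg, seed=7)


@pytest.fixture(scope="session")
def small_features(small_study):
    return small_study.features
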