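import numpy as np
import pytest

from figleaf.synthetic import SyntheticConfig, default_study_config


@pytest.fixture(scope="session")
def study_config() -> SyntheticConfig:
    return default_study_config(seed=0)


@pytest.fixture(scope="session")
def small_config(study_config) -> SyntheticConfig:
    """Four cultivars (two per lobe class), 8 leaves each — fast pipelines."""
    keep = {"BB", "PO", "CO", "PN"}
    cultivars = []
    for c in study_config.cultivars:
        if c.code in keep:
            c = SyntheticConfig.from_dict(
                {"cultivars": [dict(code=c.code, lobe_class=c.lobe_class,
                                    n_leaves=8,
                                    measurements={k: list(v) for k, v in
                                                  c.measurements.items()},
                                    trichome_lambda=c.trichome_lambda,
                                    density={k: list(v) for k, v in
                                             c.density.items()})]}).cultivars[0]
            cultivars.append(c)
    return SyntheticConfig(cultivars=cultivars, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
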