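import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aglmeta import MetaDataset, SyntheticConfig, simulate_effects

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset() -> MetaDataset:
    """25 effects in 12 articles; the metafor cross-check fixture."""
    cfg = SyntheticConfig(
        n_articles=12,
        studies_per_article=(1, 3),
        mu=0.8,
        tau2_article=0.2,
        tau2_study=0.1,
        seed=42,
    )
    return simulate_effects(cfg)


@pytest.fixture()
def flat_dataset() -> MetaDataset:
    """8 single-effect articles with equal variances, no heterogeneity."""
    g = np.array([0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6])
    frame = pd.DataFrame(
        {
            "article_id": [f"a{i}" for i in range(8)],
            "study_id": [f"a{i}_s1" for i in range(8)],
            "g": g,
            "v_g": np.full(8, 0.05),
            "n": np.full(8, 20),
        }
    )
    return MetaDataset(frame)
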