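import numpy as np
import pandas as pd
import pytest

from seamount_oasis import synthetic as syn


@pytest.fixture(scope="session")
def enriched_survey():
    """NB survey with a planted 20x compact kernel (R_true = 5 km)."""
    kernel = syn.EnrichmentKernel(baseline_mean=2.0, summit_multiplier=20.0,
                                  radius_true=5.0)
    cfg = syn.SurveyConfig(seed=42, n_samples=400, max_distance_km=20.0)
    return syn.gen_radial_survey(cfg, kernel, family="nb"), kernel


@pytest.fixture(scope="session")
def flat_survey():
    """Gaussian survey with no distance effect."""
    rng = np.random.default_rng(7)
    return pd.DataFrame({
        "distance_km": rng.uniform(0.0, 40.0, 300),
        "response": rng.normal(5.0, 1.0, 300),
    })


@pytest.fixture(scope="session")
def detection_log():
    """Short two-profile detection history with known departure days."""
    animals = pd.DataFrame({
        "tag_id": ["RES1", "RES2", "TRA1", "TRA2"],
        "profile": ["resident", "resident", "transient", "transient"],
        "departure_day": [np.inf, np.inf, 30.0, 90.0],
        "p_daily": [1.0, 0.95, 1.0, 0.9],
    })
    cfg = syn.DetectionConfig(seed=11, study_days=300, animals=animals)
    events, truth, receivers = syn.gen_detection_log(cfg)
    return events, truth, receivers


@pytest.fixture(scope="session")
def environment():
    return syn.gen_environment(syn.EnvironmentConfig(seed=5, n_scenes=2))
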