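import numpy as np
import pytest

from healthtrait.config import GeneratorConfig
from healthtrait.synthetic import generate_cohort
from healthtrait import irt, item_prep


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate cohort with the full default design (45 items, 6 waves)."""
    return generate_cohort(GeneratorConfig(n_persons=300, seed=11))


@pytest.fixture(scope="session")
def small_recovery_setup():
    """Unidimensional drift cohort plus a short M4 fit, shared across tests."""
    cfg = GeneratorConfig(
        n_persons=150, n_items=10, n_waves=4, n_varying_items=2,
        wave_drift_sd_a=0.12, wave_drift_sd_b=0.25, mcar_rate=0.05,
        wave_effect_sd=0.7, person_resid_sd=0.7,
        second_order_loadings=[1.0] * 5, covariate_effects={}, seed=21,
    )
    cohort = generate_cohort(cfg)
    panel, pw = item_prep.filter_personwave_irt(cohort.panel)
    spec = irt.MLIRTSpec(variance_config="M4", n_iter=600, burn_in=150, seed=5)
    post = irt.fit_mlirt(panel, cohort.catalog, spec, pw_mask=pw)
    return cohort, panel, post
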