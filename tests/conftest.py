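import numpy as np
import pandas as pd
import pytest

from btcoi import datagen, hurdle


@pytest.fixture(scope="session")
def survey():
    """Study-scale synthetic survey (n=564) with cost outcome columns."""
    cfg = datagen.default_config()
    return datagen.generate_survey(cfg, seed=42)


@pytest.fixture(scope="session")
def big_survey():
    """Large synthetic survey for moment/convergence checks."""
    cfg = datagen.default_config(n_farmers=20000)
    return datagen.generate_survey(cfg, seed=7)


@pytest.fixture(scope="session")
def model2_fit(survey):
    design = hurdle.model_design("II")
    return hurdle.fit_double_hurdle(survey, design), design


def simple_hurdle_data(seed, n=800, gamma=(0.4, -0.6, 0.8),
                       beta=(5.0, -1.2, 0.9), sigma=1.5):
    """Small generic double-hurdle dataset on an O(1) scale.

    Covariates: one standard normal, one Bernoulli(0.5). Returns
    (X DataFrame, qh, gamma, beta, sigma).
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "x1": rng.standard_normal(n),
        "d1": rng.binomial(1, 0.5, n).astype(float),
    })
    g = np.asarray(gamma)
    b = np.asarray(beta)
    idx1 = g[0] + X.to_numpy() @ g[1:]
    idx2 = b[0] + X.to_numpy() @ b[1:]
    dh, qh = datagen.simulate_health_outcome(idx1, idx2, sigma, rng)
    return X, qh, g, b, sigma
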