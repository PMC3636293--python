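import numpy as np
import pandas as pd
import pytest

from trialcea.costing import UnitPrice, UnitPriceTable
from trialcea.synthetic_trial import (
    TrialConfig,
    generate_trial,
    apply_missingness,
    COST_CATEGORIES,
)
from trialcea.utility_qaly import ValueSet, all_states, state_code


@pytest.fixture(scope="session")
def dutch_value_set():
    return ValueSet.dutch()


@pytest.fixture(scope="session")
def toy_value_set():
    """Additive toy tariff: 1.0 minus 0.1 per level above 1, any dimension."""
    mapping = {
        state_code(s): 1.0 - 0.1 * sum(v - 1 for v in s) for s in all_states()
    }
    return ValueSet(name="toy-additive", mapping=mapping)


@pytest.fixture(scope="session")
def default_prices():
    return UnitPriceTable.default()


@pytest.fixture(scope="session")
def flat_prices_2011():
    """Indexing-neutral price table (price year equals index year)."""
    return UnitPriceTable(
        prices={c: UnitPrice(c, 10.0, 2011) for c in COST_CATEGORIES},
        index_year=2011,
    )


@pytest.fixture(scope="session")
def small_config():
    return TrialConfig(arm_sizes=(30, 25, 20), seed=11)


@pytest.fixture(scope="session")
def small_trial(small_config):
    return generate_trial(small_config)


@pytest.fixture(scope="session")
def small_trial_missing(small_config, small_trial):
    return apply_missingness(small_trial, small_config)


@pytest.fixture(scope="session")
def full_trial():
    cfg = TrialConfig(seed=5)
    complete = generate_trial(cfg)
    return cfg, complete, apply_missingness(complete, cfg)


def make_analysis_frame(rng, n_per_arm=60, arms=("MTC", "MT", "UC"),
                        cost_means=(1500.0, 1000.0, 800.0),
                        abst_probs=(0.09, 0.15, 0.10),
                        qaly_means=(0.86, 0.83, 0.84)):
    """Small valued/imputed analysis frame with skewed costs."""
    rows = []
    for arm, cm, p, qm in zip(arms, cost_means, abst_probs, qaly_means):
        rows.append(pd.DataFrame({
            "arm": arm,
            "health_cost": rng.gamma(2.0, cm / 2.0, n_per_arm),
            "abstinent": (rng.random(n_per_arm) < p).astype(float),
            "qaly": np.clip(rng.normal(qm, 0.15, n_per_arm), 0, 1),
        }))
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "id", np.arange(1, len(df) + 1))
    return df


@pytest.fixture()
def analysis_frame():
    return make_analysis_frame(np.random.default_rng(17))
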