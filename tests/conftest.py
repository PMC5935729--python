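import numpy as np
import pandas as pd
import pytest

from sedch4 import SynthConfig, gen_eems, gen_incubation


@pytest.fixture(scope="session")
def eem_cube_small():
    """24-sample, 1%-noise five-component cube with stored true scores."""
    cfg = SynthConfig(seed=11, n_replicates=2, eem_noise=0.01, eem_inner_filter=False)
    return gen_eems(cfg)


@pytest.fixture(scope="session")
def eem_cube_noiseless():
    cfg = SynthConfig(seed=12, n_replicates=2, eem_noise=0.0, eem_inner_filter=False)
    return gen_eems(cfg)


@pytest.fixture(scope="session")
def incubation_noiseless():
    """Full jar design with no between-jar variation or measurement noise."""
    cfg = SynthConfig(seed=5, jar_cv=0.0, gas_noise=0.0)
    return gen_incubation(cfg)


@pytest.fixture(scope="session")
def production_table():
    """Per-jar CH4 rates with between-jar variation, as the ANOVA consumes."""
    from sedch4 import cumulative_production

    cfg = SynthConfig(seed=6, jar_cv=0.15)
    series, truth = gen_incubation(cfg)
    est = [cumulative_production(s) for s in series]
    return pd.DataFrame(
        {
            "jar_id": [e.jar_id for e in est],
            "treatment": [e.treatment for e in est],
            "om_frac": [e.om_frac for e in est],
            "spike": [e.spike for e in est],
            "gas": [e.gas for e in est],
            "rate_mg_m2": [e.rate_mg_m2 for e in est],
        }
    )
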