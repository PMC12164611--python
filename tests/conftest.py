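import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import coda24
from coda24.ingest import build_cohort

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def validation_cohort():
    """Single-outcome synthetic cohort with known planted parameters."""
    cfg = coda24.make_validation_config(n_per_sex=400)
    days, demo, truth = coda24.generate_cohort(cfg, seed=2024)
    records, day_excl, part_excl, flow = build_cohort(days, demo, cfg.filter)
    return {"cfg": cfg, "days": days, "demo": demo, "truth": truth,
            "records": records, "flow": flow}


@pytest.fixture(scope="session")
def panel_records():
    """Records with the full ten-outcome panel, moderate size."""
    cfg = coda24.GeneratorConfig(n_per_sex={"male": 500, "female": 500})
    days, demo, truth = coda24.generate_cohort(cfg, seed=99)
    records, *_ = build_cohort(days, demo, cfg.filter)
    return {"cfg": cfg, "records": records, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_compositions(rng, n, d=5, total=1440.0):
    """Strictly positive random compositions closed to `total`."""
    raw = rng.lognormal(mean=np.log([300, 300, 40, 15, 600][:d]), sigma=0.4,
                        size=(n, d))
    return raw * (total / raw.sum(axis=1, keepdims=True))
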