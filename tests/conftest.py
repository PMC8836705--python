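import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from episig import (SimConfig, filter_probes, iterate_matching,
                    simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Strong-signal cohort small enough for fast unit tests."""
    cfg = SimConfig(
        n_probes=3000, n_cases=12, n_control_pool=80, n_spiked_dmps=300,
        delta_beta_mean=0.18, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cc_setup(small_cohort):
    """Filtered beta restricted to cases + matched controls, with labels."""
    c = small_cohort
    beta_f, _ = filter_probes(c.beta, c.detection_p, c.manifest)
    cases = c.samples[c.samples["group"] == "case"]
    pool = c.samples[c.samples["group"] == "control_pool"]
    match = iterate_matching(cases, pool, beta_f, ratio=2)
    case_ids = sorted(cases.index)
    control_ids = match.selected_control_ids
    cols = case_ids + control_ids
    labels = pd.Series(["case"] * len(case_ids) + ["control"] * len(control_ids),
                       index=cols)
    return {
        "cohort": c,
        "beta": beta_f[cols],
        "beta_full": beta_f,
        "labels": labels,
        "case_ids": case_ids,
        "control_ids": control_ids,
        "match": match,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
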