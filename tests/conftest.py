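import numpy as np
import pandas as pd
import pytest

import nanosynergy as ns
from nanosynergy.defaults import default_design, default_true_params


@pytest.fixture(scope="session")
def four_drug_design():
    return default_design()


@pytest.fixture(scope="session")
def true_params():
    return default_true_params()


@pytest.fixture(scope="session")
def additive_screen(four_drug_design, true_params):
    """Noise-free Loewe-additive screen: the exact round-trip fixture."""
    cfg = ns.ScreenSimConfig(
        design=four_drug_design,
        true_params=true_params,
        interaction_gamma=1.0,
        replicates=1,
        noise_sd=0.0,
        seed=11,
    )
    return ns.simulate_screen(cfg)


@pytest.fixture(scope="session")
def synergistic_screen(four_drug_design, true_params):
    """Noise-free screen with a planted synergy of gamma = 0.2."""
    cfg = ns.ScreenSimConfig(
        design=four_drug_design,
        true_params=true_params,
        interaction_gamma=0.2,
        replicates=1,
        noise_sd=0.0,
        seed=11,
    )
    return ns.simulate_screen(cfg)


def make_viability_table(design, viability_by_condition, replicates=1):
    """Hand-build a ViabilityTable from {condition_id: viability or list}."""
    rows = []
    for cid, v in viability_by_condition.items():
        vals = np.atleast_1d(v)
        for rep, val in enumerate(np.resize(vals, replicates if len(vals) == 1 else len(vals)), 1):
            rows.append({"condition_id": cid, "replicate": rep, "viability": float(val)})
    return ns.ViabilityTable(records=pd.DataFrame(rows), design=design)
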