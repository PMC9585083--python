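import numpy as np
import pandas as pd
import pytest

from isopair import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    """Tiny paired count matrix with an obvious planted effect on gene g1."""
    sheet = pd.DataFrame(
        {
            "sample": ["P1_control", "P1_treated", "P2_control", "P2_treated"],
            "patient": ["P1", "P1", "P2", "P2"],
            "condition": ["control", "treated", "control", "treated"],
            "genotype": ["tri12", "tri12", "del13q", "del13q"],
        }
    )
    counts = pd.DataFrame(
        {
            "P1_control": [100, 50, 80],
            "P1_treated": [400, 50, 80],
            "P2_control": [120, 60, 90],
            "P2_treated": [480, 60, 90],
        },
        index=["g1", "g2", "g3"],
    )
    return counts, sheet


@pytest.fixture
def rnaseq_sim():
    cfg = synthetic.default_rnaseq_config(seed=7)
    return synthetic.simulate_paired_counts(cfg)


@pytest.fixture
def chip_sim():
    cfg = synthetic.default_chip_config(seed=7)
    return synthetic.simulate_peak_experiment(cfg, pc_effect_frac=0.02)
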