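import numpy as np
import pandas as pd
import pytest

from censq import CtMatrix, SimConfig, simulate_cohort


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A fast cohort: 60 targets, 42 samples, mostly expressed."""
    defaults = dict(
        n_targets=60, n_cnt=20, n_oma=12, n_die=10,
        frac_expressed=0.6, n_refs=3, n_de=5,
        effect_range=(1.5, 3.0), frac_hemolysed=0.05,
        qc_fail_rate=0.01, seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture()
def toy_matrix():
    """3 targets × 4 samples with hand-set values and passing QC."""
    values = pd.DataFrame(
        [[25.0, 26.0, 24.5, 25.5],
         [30.0, 31.0, np.nan, 30.5],
         [19.0, 20.0, 19.5, 18.5]],
        index=pd.Index(["miR-23a-3p", "miR-x", "miR-451a"], name="target_id"),
        columns=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    ones = pd.DataFrame(1.5, index=values.index, columns=values.columns)
    conf = pd.DataFrame(0.95, index=values.index, columns=values.columns)
    return CtMatrix(values=values, amp_score=ones, cq_confidence=conf)


@pytest.fixture()
def toy_samples():
    return pd.DataFrame(
        {"group": ["CNT", "CNT", "OMA", "DIE"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
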