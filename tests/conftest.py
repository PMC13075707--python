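import numpy as np
import pytest

from adscca import (SimConfig, SurvivalData, generate_paired_omics,
                    generate_survival)


@pytest.fixture
def small_dataset():
    """Paired matrices with a clear shared factor, desk scale."""
    cfg = SimConfig(n=60, p=30, q=30, s=5, signal=2.0, noise_sd=1.0,
                    seed=11)
    x, y, gt = generate_paired_omics(cfg)
    return cfg, x, y, gt


@pytest.fixture
def toy_survival():
    """Hand-built survival table: 6 subjects, 4 events, 2 censored."""
    return SurvivalData(
        [f"P{i}" for i in range(6)],
        np.array([2.0, 5.0, 3.5, 8.0, 1.0, 7.0]),
        np.array([1, 1, 0, 1, 1, 0]),
    )


@pytest.fixture
def random_survival():
    """Mid-size random survival data with ~30% censoring."""
    rng = np.random.default_rng(5)
    lp = rng.normal(size=80)
    return generate_survival(lp, 1.0, 0.3, seed=6,
                             sample_ids=[f"R{i}" for i in range(80)]), lp
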