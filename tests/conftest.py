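import numpy as np
import pandas as pd
import pytest

from repeatarch import RunConfig, SimConfig, simulate_all


def small_sim_config(seed=0, **overrides):
    """A reduced-scale cohort that keeps the study's structure."""
    defaults = dict(
        seed=seed,
        n_individuals=60,
        n_genes=400,
        elements_per_class=40,
        n_snps=400,
        single_copy_bp=60_000_000,
        n_chromosomes=4,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_all(small_sim_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, chrom_len=50_000, classes=None, chroms=("chrA",)):
    """Random possibly-overlapping labelled intervals for oracle tests."""
    from repeatarch import REPEAT_CLASSES

    classes = list(classes or REPEAT_CLASSES)
    starts = rng.integers(0, chrom_len - 30, n)
    lengths = rng.integers(1, 2_000, n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(list(chroms), n),
            "start": starts,
            "end": np.minimum(starts + lengths, chrom_len),
            "feature_class": rng.choice(classes, n),
            "feature_id": [f"f{i:04d}" for i in range(n)],
        }
    )
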