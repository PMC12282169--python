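import numpy as np
import pytest

from ribotile.synthetic_data import make_learning_set, sample_abundant_regions

# Standard study conditions: 8 samples (7 learning + 1 held-out), shared
# abundant rRNA core, rRNA fractions drawn in (0.32, 0.55), 150k reads of
# 150 nt per sample, regions extracted at the >500x depth threshold.
STANDARD_SEED = 42
STANDARD_N_READS = 150_000
STANDARD_READ_LENGTH = 150
STANDARD_MIN_DEPTH = 500.0


@pytest.fixture(scope="session")
def standard_learning_set():
    samples = make_learning_set(
        n_samples=8,
        rrna_frac_range=(0.32, 0.55),
        seed=STANDARD_SEED,
        n_reads=STANDARD_N_READS,
        read_length=STANDARD_READ_LENGTH,
    )
    regions = [sample_abundant_regions(s, min_depth=STANDARD_MIN_DEPTH) for s in samples]
    return samples, regions


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
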