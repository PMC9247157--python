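import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from chirplex.synth import SyntheticConfig, generate_bundle


def small_config(seed: int, **overrides) -> SyntheticConfig:
    """A fast fixture-bundle config for tests that need many seeds."""
    kwargs = dict(
        seed=seed, n_chroms=2, chrom_length=300_000, n_genes=20,
        peaks_per_replicate=100, n_noise_peaks=50, tts_target_fraction=0.4,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size bundle shared by read-only tests."""
    return generate_bundle(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_config(7))
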