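import numpy as np
import pytest

from seedtrace import FeatureTable, SyntheticSpec, TaxonomyMap, generate


@pytest.fixture
def tiny_table() -> FeatureTable:
    return FeatureTable(
        ["a", "b", "c"],
        ["s1", "s2"],
        np.array([[3, 5], [4, 6], [1, 2]]),
    )


@pytest.fixture
def tiny_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        {
            "a": ("Bacteria", "P1", "C1", "O1", "F1", "G1"),
            "b": ("Bacteria", "P1", "C1", "O1", "F1", "G1"),
            "c": ("Bacteria", "P1", "C1", "O1", "F2", "G2"),
        }
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A full but small synthetic study (fast to generate, reused read-only)."""
    spec = SyntheticSpec(
        n_seed_asvs=20,
        n_soil_asvs=60,
        genus_pool_size=40,
        depth=2000,
        n_blocks=3,
        rng_seed=42,
    )
    return generate(spec)


def random_count_table(rng: np.random.Generator, n_features: int, n_samples: int, depth: int = 2000) -> FeatureTable:
    base = rng.lognormal(0.0, 1.0, n_features)
    p = base / base.sum()
    counts = rng.multinomial(depth, p, size=n_samples).T
    return FeatureTable(
        [f"f{i}" for i in range(n_features)],
        [f"s{j}" for j in range(n_samples)],
        counts,
        allow_empty=True,
    )
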