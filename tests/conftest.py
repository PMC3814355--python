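import functools

import pytest

import codonlens as cl


@functools.lru_cache(maxsize=8)
def cached_genome(seed: int, s_max: float = None, n_genes: int = None):
    """Generate (and memoize) a synthetic genome for the test session."""
    kwargs = {}
    if s_max is not None:
        kwargs["s_max"] = s_max
    if n_genes is not None:
        kwargs["n_genes"] = n_genes
    return cl.generate_genome(cl.SyntheticGenomeConfig(**kwargs), seed)


@pytest.fixture(scope="session")
def small_genome():
    """A 400-gene genome with the default expression-linked bias."""
    return cached_genome(11, n_genes=400)


@pytest.fixture(scope="session")
def small_null_genome():
    """A 400-gene genome with selection switched off (pure GC-driven usage)."""
    return cached_genome(12, s_max=0.0, n_genes=400)
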