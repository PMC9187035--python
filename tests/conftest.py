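import numpy as np
import pytest

from coevnet import MSA, SequenceWeights, generate_msa


def random_msa(rng, L=6, N=12, gap_rate=0.1):
    """Small random alignment (gap-free query) for oracle comparisons."""
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    rows = []
    for n in range(N):
        row = [letters[rng.integers(0, 20)] for _ in range(L)]
        if n > 0:
            for k in range(L):
                if rng.random() < gap_rate:
                    row[k] = "-"
        rows.append("".join(row))
    return MSA(ids=[f"s{k}" for k in range(N)], sequences=rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20210624)


@pytest.fixture
def small_msa():
    return MSA(
        ids=["q", "h1", "h2", "h3"],
        sequences=["ACDE", "ACDG", "AC-E", "GCDE"],
    )


@pytest.fixture
def unit_weights():
    return SequenceWeights.uniform(4)


@pytest.fixture
def planted_msa():
    msa, truth = generate_msa(L=20, N=80, planted=[(3, 11, 1.0)], seed=7)
    return msa, truth
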