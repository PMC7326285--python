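import itertools

import numpy as np
import pytest

from introsweep import SiteTable, UnnormalizedSFS, neutral_spectrum


@pytest.fixture
def toy_spectrum():
    """n = 3 spectrum with hand-computable conditionals: S = (6, 3, 10)."""
    return UnnormalizedSFS(3, np.array([0.0, 6.0, 3.0, 10.0]))


@pytest.fixture
def neutral_bg():
    """Per-site neutral background, n = 10."""
    return neutral_spectrum(10, theta=0.002, D_o=0.0125)


@pytest.fixture
def small_table():
    """Three informative sites, n = 3, classes (1, 2, 3)."""
    return SiteTable(np.array([100, 200, 300]), np.array([1, 2, 3]), 3)


def enumerate_subsample(weights: np.ndarray, k: int) -> np.ndarray:
    """Brute-force oracle for the spectrum projection.

    For every frequency configuration (i derived among n), enumerate all
    C(n, k) subsets of lineages and count how many carry j derived copies;
    weights are averaged accordingly. Independent of the hypergeometric
    closed form used by the implementation.
    """
    n = len(weights) - 1
    out = np.zeros(k + 1)
    lineages = range(n)
    subsets = list(itertools.combinations(lineages, k))
    for i in range(1, n + 1):
        derived = set(range(i))  # first i lineages carry the derived allele
        for sub in subsets:
            j = sum(1 for s in sub if s in derived)
            out[j] += weights[i] / len(subsets)
    return out


@pytest.fixture
def subsample_oracle():
    return enumerate_subsample
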