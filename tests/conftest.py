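import numpy as np
import pytest

import hpdca
from hpdca import EncodedMSA
from hpdca.msa_io import ALPHABET


@pytest.fixture
def toy_msa():
    """Two short sequences with a gap; entries verified by hand."""
    return hpdca.encode_sequences(["A-C", "AAC"])


@pytest.fixture
def random_msa():
    """Uniform random alignment, L=6, q=4, M=200 (full-rank oracle scale)."""
    rng = np.random.default_rng(42)
    data = rng.integers(1, 5, size=(200, 6))
    return EncodedMSA(data, alphabet=ALPHABET[:4])


@pytest.fixture
def random_spectrum(random_msa):
    spectrum, freqs, weights = hpdca.pearson_spectrum(random_msa)
    return spectrum


def make_two_site_pattern(L, q, i, j, a, b, c=1.0, opposite=True, sign="repulsive"):
    """Pattern with components +c at (i,a) and ±c at (j,b), 1-based indices."""
    xi = np.zeros((L, q))
    xi[i - 1, a - 1] = c
    xi[j - 1, b - 1] = -c if opposite else c
    lam = 0.5 if sign == "repulsive" else 2.0
    return hpdca.Pattern(xi=xi, sign=sign, eigenvalue=lam)
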