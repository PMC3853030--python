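import itertools

import numpy as np
import pytest

from seqlev import _kernels
from seqlev.codes import BarcodeSet


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    _kernels.warmup()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def example_code4():
    """The worked-example length-4, dmin=3 Sequence-Levenshtein code."""
    return BarcodeSet(
        n=4,
        metric="sequence_levenshtein",
        dmin=3,
        barcodes=["TTCC", "ACAC", "CGAA", "TAGG"],
    )


def all_words(max_len: int, alphabet: str = "ACGT", min_len: int = 0):
    """Every word over ``alphabet`` with length in [min_len, max_len]."""
    out = []
    for length in range(min_len, max_len + 1):
        out.extend("".join(t) for t in itertools.product(alphabet, repeat=length))
    return out


def random_words(n_words: int, max_len: int, seed: int, min_len: int = 0):
    rng = np.random.default_rng(seed)
    words = []
    for _ in range(n_words):
        length = int(rng.integers(min_len, max_len + 1))
        words.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=length)))
    return words
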