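"""Nucleotide words over the quaternary DNA alphabet.

Barcodes and reads are plain Python strings over ``{A, C, G, T}``.  For the
dynamic-programming kernels they are encoded as ``uint8`` arrays with the
quaternary mapping A=0, C=1, G=2, T=3, which also fixes the lexicographic
order (A < C < G < T) used everywhere in the package.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_CODE = {base: i for i, base in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Raised for words containing characters outside {A, C, G, T}."""


def validate(seq: str, *, name: str = "sequence") -> str:
    """Uppercase ``seq`` and verify it only contains A/C/G/T.

    The empty word is valid.  IUPAC ambiguity codes (N, R, Y, ...) are
    rejected: the codes in this package are defined on the strict
    four-letter alphabet.
    """
    s = seq.upper()
    for ch in s:
        if ch not in _CODE:
            raise SequenceError(f"{name} contains non-ACGT character {ch!r}: {seq!r}")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a word as a uint8 array (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_CODE[ch] for ch in seq], dtype=np.uint8)
    except KeyError as exc:
        raise SequenceError(f"non-ACGT character {exc.args[0]!r} in {seq!r}") from None


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`; round-trips exactly."""
    return "".join(ALPHABET[int(v)] for v in arr)


def decode_rows(mat: np.ndarray) -> list[str]:
    """Decode each row of an encoded ``(N, n)`` matrix to a string."""
    return ["".join(ALPHABET[v] for v in row) for row in np.asarray(mat, dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; an involution on ACGT words."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_word(n: int, rng: np.random.Generator) -> str:
    """A uniform random word of length ``n``."""
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))
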