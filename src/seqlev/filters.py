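"""Chemical/sequence filters on candidate barcodes.

Before any distance constraint is applied, barcode candidates are screened
for properties that make them behave well as oligonucleotides: balanced GC
content (stable, uniform melting temperature), no homopolymer runs longer
than two bases (error-prone on several sequencing chemistries), and no
perfect self reverse-complementarity (which promotes hairpins/self-dimers).
The default policy keeps GC in [40%, 60%] inclusive, allows runs of at
most 2, and rejects self-reverse-complementary words.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

import numpy as np

from .sequences import decode_rows, reverse_complement, validate


class DegenerateInputError(ValueError):
    """Raised when a filter statistic is requested for the empty word."""


@dataclass(frozen=True)
class FilterPolicy:
    """Screening rules for barcode candidates.

    gc_min / gc_max
        Inclusive bounds on the G+C fraction.
    max_homopolymer_run
        Longest allowed block of identical consecutive bases.
    reject_self_reverse_complement
        Drop words equal to their own reverse complement (only possible
        for even lengths, so the check is a no-op for odd ``n``).
    """

    gc_min: float = 0.40
    gc_max: float = 0.60
    max_homopolymer_run: int = 2
    reject_self_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.max_homopolymer_run < 1:
            raise ValueError("max_homopolymer_run must be >= 1")


#: The screening rules used for the reference code sizes in this package.
DEFAULT_POLICY = FilterPolicy()

#: No screening at all (all 4^n words are eligible).
NO_FILTER = FilterPolicy(gc_min=0.0, gc_max=1.0, max_homopolymer_run=10**9,
                         reject_self_reverse_complement=False)


def gc_fraction(seq: str) -> float:
    """Fraction of G or C bases in a non-empty word."""
    seq = validate(seq)
    if not seq:
        raise DegenerateInputError("gc_fraction undefined for the empty word")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest block of identical consecutive bases."""
    seq = validate(seq)
    if not seq:
        raise DegenerateInputError("homopolymer run undefined for the empty word")
    return max(len(list(g)) for _, g in groupby(seq))


def passes_filters(seq: str, policy: FilterPolicy = DEFAULT_POLICY) -> bool:
    """True iff ``seq`` satisfies every rule of ``policy``."""
    seq = validate(seq)
    if not seq:
        raise DegenerateInputError("cannot filter the empty word")
    if not policy.gc_min <= gc_fraction(seq) <= policy.gc_max:
        return False
    if max_homopolymer_run(seq) > policy.max_homopolymer_run:
        return False
    if policy.reject_self_reverse_complement and seq == reverse_complement(seq):
        return False
    return True


def candidate_matrix(n: int, policy: FilterPolicy = DEFAULT_POLICY) -> np.ndarray:
    """All eligible length-``n`` words as an encoded ``(N, n)`` uint8 matrix.

    Rows are in lexicographic order over A < C < G < T.  The full 4^n
    space is generated and screened with vectorised numpy checks, so
    lengths up to ~12 are practical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    total = 4**n
    words = np.empty((total, n), dtype=np.uint8)
    codes = np.arange(total, dtype=np.int64)
    for col in range(n):
        words[:, col] = (codes >> (2 * (n - 1 - col))) & 3
    # GC content: C=1, G=2
    gc = ((words == 1) | (words == 2)).sum(axis=1)
    keep = (gc >= policy.gc_min * n - 1e-9) & (gc <= policy.gc_max * n + 1e-9)
    # homopolymer runs
    if n > 1 and policy.max_homopolymer_run < n:
        run = np.ones(total, dtype=np.int16)
        longest = np.ones(total, dtype=np.int16)
        for col in range(1, n):
            same = words[:, col] == words[:, col - 1]
            run = np.where(same, run + 1, 1).astype(np.int16)
            np.maximum(longest, run, out=longest)
        keep &= longest <= policy.max_homopolymer_run
    # perfect self reverse-complement (A<->T, C<->G after reversal)
    if policy.reject_self_reverse_complement and n % 2 == 0:
        rc = (3 - words)[:, ::-1]
        keep &= ~(words == rc).all(axis=1)
    return words[keep]


def enumerate_candidates(n: int, policy: FilterPolicy = DEFAULT_POLICY) -> list[str]:
    """All eligible length-``n`` barcodes, lexicographically sorted strings."""
    return decode_rows(candidate_matrix(n, policy))
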