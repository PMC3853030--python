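"""Mutation models and the three barcode-robustness simulation studies.

Simulation 1 embeds codewords of classic Levenshtein codes in random reads,
applies random indels and decodes at fixed length, quantifying how often
the unknown word boundary defeats classic codes (about 1/4 of single-indel
cases for dmin = 3 -- the probability that the adverse base slides in after
the boundary shift -- and about 1/16 for two indels at dmin = 5).

Simulation 2 is the exhaustive guarantee check for Sequence-Levenshtein
codes: every codeword, every corruption of at most k edits, and every
possible sample-sequence context filling the decode window must decode back
to the original codeword.

Simulation 3 is the stress test: every base of the barcode mutates
independently with probability p (substitution, insertion and deletion
equally likely; inserted bases uniform), the read is decoded best-effort,
and the fraction of correct assignments is recorded per (code, p).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codes import BarcodeSet, greedy_closure
from .decode import classic_decode_fixed_length, decode_read, sl_decode
from .filters import DEFAULT_POLICY, NO_FILTER, candidate_matrix
from .sequences import ALPHABET, random_word, validate

ALL_OPS = ("substitute", "insert", "delete")
INDEL_OPS = ("insert", "delete")


@dataclass(frozen=True)
class AppliedEdit:
    """One edit as actually applied, positioned on the word at that moment.

    Unlike :class:`seqlev.metrics.EditOp` (source coordinates of an optimal
    alignment), these record the sequential sampling process: ``position``
    is 1-based on the *current* word for substitute/delete, and the slot
    index 0..len for insert.
    """

    kind: str
    position: int
    base: str | None = None


def _other_bases(base: str) -> str:
    return ALPHABET.replace(base, "")


def mutate_exact(
    word: str,
    e: int,
    rng: np.random.Generator,
    operations: Sequence[str] = ALL_OPS,
) -> tuple[str, list[AppliedEdit]]:
    """Apply exactly ``e`` sequential random edits to ``word``.

    Each edit draws its type uniformly from ``operations`` (restricted to
    the types applicable to the current word: a deletion or substitution
    needs a non-empty word), its position uniformly on the current word,
    substituted bases uniformly from the 3 alternatives and inserted bases
    uniformly from all 4.  Returns the mutated word and the edits applied.
    """
    word = validate(word)
    edits: list[AppliedEdit] = []
    for _ in range(e):
        ops = [op for op in operations if op == "insert" or len(word) > 0]
        op = ops[int(rng.integers(0, len(ops)))]
        if op == "substitute":
            pos = int(rng.integers(0, len(word)))
            base = _other_bases(word[pos])[int(rng.integers(0, 3))]
            word = word[:pos] + base + word[pos + 1 :]
            edits.append(AppliedEdit("substitute", pos + 1, base))
        elif op == "delete":
            pos = int(rng.integers(0, len(word)))
            word = word[:pos] + word[pos + 1 :]
            edits.append(AppliedEdit("delete", pos + 1))
        else:
            pos = int(rng.integers(0, len(word) + 1))
            base = ALPHABET[int(rng.integers(0, 4))]
            word = word[:pos] + base + word[pos:]
            edits.append(AppliedEdit("insert", pos, base))
    return word, edits


def mutate_per_base(
    word: str,
    p: float,
    rng: np.random.Generator,
    operations: Sequence[str] = ALL_OPS,
) -> tuple[str, list[AppliedEdit]]:
    """Mutate each original base independently with probability ``p``.

    A mutating base is, with equal probability among ``operations``:
    substituted (uniform over the 3 other bases), deleted, or kept with a
    uniform random base inserted in front of it.  Inserted bases are not
    re-mutated, so the expected edit count is exactly ``p * len(word)``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    word = validate(word)
    out: list[str] = []
    edits: list[AppliedEdit] = []
    for i, base in enumerate(word):
        if rng.random() >= p:
            out.append(base)
            continue
        op = operations[int(rng.integers(0, len(operations)))]
        if op == "substitute":
            new = _other_bases(base)[int(rng.integers(0, 3))]
            out.append(new)
            edits.append(AppliedEdit("substitute", i + 1, new))
        elif op == "delete":
            edits.append(AppliedEdit("delete", i + 1))
        else:
            new = ALPHABET[int(rng.integers(0, 4))]
            out.append(new)
            out.append(base)
            edits.append(AppliedEdit("insert", i, new))
    return "".join(out), edits


def _single_edit_neighbourhood(word: str) -> set[str]:
    out: set[str] = set()
    for i, base in enumerate(word):
        for alt in _other_bases(base):
            out.add(word[:i] + alt + word[i + 1 :])
        out.add(word[:i] + word[i + 1 :])
    for i in range(len(word) + 1):
        for alt in ALPHABET:
            out.add(word[:i] + alt + word[i:])
    return out


def enumerate_corruptions(word: str, e: int) -> set[str]:
    """All words reachable from ``word`` by at most ``e`` edits.

    The unchanged word is included (0 edits).  Built by iterating the
    single-edit neighbourhood, so every member is within Levenshtein
    distance ``e`` of ``word``.
    """
    word = validate(word)
    current: set[str] = {word}
    for _ in range(e):
        nxt = set(current)
        for w in current:
            nxt |= _single_edit_neighbourhood(w)
        current = nxt
    return current


def _report_row(**kwargs) -> dict:
    trials = kwargs["trials"]
    kwargs.setdefault("n_ambiguous", 0)
    kwargs["failure_rate"] = 1.0 - kwargs["n_correct"] / trials if trials else np.nan
    return kwargs


def _append_sample(barcode_region: str, total_length: int, min_length: int,
                   rng: np.random.Generator) -> str:
    """Barcode region plus uniform random sample sequence.

    The sample fills the read up to ``total_length``; if heavy deletion
    left the read shorter than ``min_length`` (the longest decoder
    window), additional random bases are appended -- in a real read the
    sample sequence continues indefinitely.
    """
    fill = max(total_length - len(barcode_region), min_length - len(barcode_region), 0)
    return barcode_region + (random_word(fill, rng) if fill else "")


def simulation1(
    code_dl3: BarcodeSet,
    code_dl5: BarcodeSet,
    trials: int = 100_000,
    m: int | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Fixed-length decoding of classic Levenshtein codes under random indels.

    Three arms: the dmin=3 code under one random indel, and the dmin=5
    code under one and under two random indels.  Per trial a codeword is
    drawn uniformly, embedded in a random read of length ``m`` (default
    n + 6), mutated, and decoded with the n / n-1 / n+1 window procedure
    with random tie-breaking.  A trial fails when the decoded codeword is
    not the original.
    """
    if code_dl3.metric != "levenshtein" or code_dl3.dmin != 3:
        raise ValueError("code_dl3 must be a classic Levenshtein code with dmin=3")
    if code_dl5.metric != "levenshtein" or code_dl5.dmin != 5:
        raise ValueError("code_dl5 must be a classic Levenshtein code with dmin=5")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for code, e in ((code_dl3, 1), (code_dl5, 1), (code_dl5, 2)):
        total = m if m is not None else code.n + 6
        n_correct = n_wrong = n_ambiguous = 0
        for _ in range(trials):
            idx = int(rng.integers(0, len(code)))
            corrupted, _edits = mutate_exact(code.barcodes[idx], e, rng, INDEL_OPS)
            read = _append_sample(corrupted, total, code.n + 1, rng)
            res = classic_decode_fixed_length(read, code, rng)
            if res.matched_index == idx:
                n_correct += 1
            elif res.matched_index is None:
                n_ambiguous += 1
            else:
                n_wrong += 1
        rows.append(
            _report_row(
                scenario=1, label=f"dL{code.dmin}_e{e}", metric=code.metric, n=code.n,
                dmin=code.dmin, p_or_e=e, trials=trials, n_correct=n_correct,
                n_wrong=n_wrong, n_ambiguous=n_ambiguous, mean_mutations=float(e),
                rng_seed=rng_seed,
            )
        )
    return pd.DataFrame(rows)


def simulation2(
    code: BarcodeSet,
    k: int | None = None,
    max_codewords: int | None = None,
    max_contexts: int | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Exhaustive error-correction check for a Sequence-Levenshtein code.

    For every codeword, every corruption of at most ``k`` edits and every
    possible context filling the n + k decode window, assert that
    decoding recovers the original codeword uniquely.  Returns a
    one-row report whose ``n_wrong`` is the number of failures (0 for
    any valid code with dmin >= 2k + 1).  For large codes the check can
    be subsampled: ``max_codewords`` draws a random subset of codewords,
    ``max_contexts`` a random subset of the window-filling contexts per
    corruption (the corruption enumeration itself is always complete).
    """
    if code.metric != "sequence_levenshtein":
        raise ValueError("simulation2 expects a sequence_levenshtein code")
    k = code.k if k is None else k
    window = code.n + k
    rng = np.random.default_rng(rng_seed)
    indices: Iterable[int] = range(len(code))
    if max_codewords is not None and max_codewords < len(code):
        indices = sorted(rng.choice(len(code), size=max_codewords, replace=False))
    n_trials = n_correct = n_wrong = 0
    failures: list[tuple[str, str]] = []
    for idx in indices:
        word = code.barcodes[idx]
        for corrupted in enumerate_corruptions(word, k):
            pad = window - len(corrupted)
            contexts = (
                ["".join(t) for t in product(ALPHABET, repeat=pad)] if pad > 0 else [""]
            )
            if max_contexts is not None and len(contexts) > max_contexts:
                picks = rng.choice(len(contexts), size=max_contexts, replace=False)
                contexts = [contexts[int(i)] for i in picks]
            for ctx in contexts:
                read = corrupted + ctx
                res = sl_decode(read, code)
                n_trials += 1
                if res.status == "unique" and res.matched_index == idx:
                    n_correct += 1
                else:
                    n_wrong += 1
                    if len(failures) < 20:
                        failures.append((word, read))
    df = pd.DataFrame(
        [
            _report_row(
                scenario=2, label=f"n{code.n}_k{k}", metric=code.metric, n=code.n,
                dmin=code.dmin, p_or_e=k, trials=n_trials, n_correct=n_correct,
                n_wrong=n_wrong, mean_mutations=np.nan, rng_seed=rng_seed,
            )
        ]
    )
    df.attrs["failures"] = failures
    return df


def standard_comparison_codes(size: int = 48) -> list[tuple[str, BarcodeSet]]:
    """The six smallest codes supporting a ``size``-sample experiment.

    Classic Levenshtein dmin=3 (n=6) and dmin=5 (n=9), Sequence-Levenshtein
    dmin=3 (n=7) and dmin=5 (n=11), a linear (Hamming dmin=3) code of
    length 5 and a length-3 code with no correction at all (exact match
    only).  Each code is built by greedy closure and truncated to its
    first ``size`` codewords (any subset of a valid code is valid).  The
    chemical filters leave no eligible length-3 words (no GC fraction
    falls in [0.4, 0.6]), so the no-correction code -- and, if the
    filtered pool is too small, the linear code -- is drawn from the
    unfiltered pool.
    """
    specs = [
        ("lev_d3_n6", "levenshtein", 3, 6),
        ("seqlev_d3_n7", "sequence_levenshtein", 3, 7),
        ("lev_d5_n9", "levenshtein", 5, 9),
        ("seqlev_d5_n11", "sequence_levenshtein", 5, 11),
        ("linear_d3_n5", "hamming", 3, 5),
        ("none_n3", "hamming", 1, 3),
    ]
    out = []
    for label, metric, dmin, n in specs:
        code = greedy_closure([], candidate_matrix(n, DEFAULT_POLICY), dmin, metric)
        if len(code) < size:
            code = greedy_closure([], candidate_matrix(n, NO_FILTER), dmin, metric)
        if len(code) < size:
            raise ValueError(f"{label}: only {len(code)} barcodes available, need {size}")
        out.append(
            (label, BarcodeSet(n=n, metric=metric, dmin=dmin, barcodes=code.barcodes[:size]))
        )
    return out


def simulation3(
    codes: Sequence[tuple[str, BarcodeSet]],
    p_grid: Sequence[float] = (0.1, 0.3, 0.5),
    trials: int = 10_000,
    m: int | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Best-effort decoding success under per-base mutation probability p.

    ``codes`` is a list of ``(label, BarcodeSet)``.  Per (code, p) cell:
    draw a codeword, mutate every base independently with probability p,
    append clean random sample sequence up to read length ``m`` (default
    n + 6) and decode in best-effort mode (accept the nearest codeword
    even beyond the guarantee, random tie-breaks).  Reports the correct-
    assignment fraction and the observed mean mutation count, which
    should match p * n.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for label, code in codes:
        total = m if m is not None else code.n + 6
        max_dist = 0 if code.dmin <= 1 else None  # dmin=1: exact match only
        for p in p_grid:
            n_correct = n_wrong = n_ambiguous = 0
            edit_total = 0
            for _ in range(trials):
                idx = int(rng.integers(0, len(code)))
                corrupted, edits = mutate_per_base(code.barcodes[idx], p, rng)
                edit_total += len(edits)
                read = _append_sample(corrupted, total, code.n + 1, rng)
                if code.metric == "levenshtein":
                    res = classic_decode_fixed_length(read, code, rng, best_effort=True)
                else:
                    res = decode_read(read, code, max_distance=max_dist, rng=rng)
                if res.matched_index == idx:
                    n_correct += 1
                elif res.matched_index is None and res.status == "ambiguous":
                    n_ambiguous += 1
                else:  # wrong assignment, or rejected (no-correction codes)
                    n_wrong += 1
            rows.append(
                _report_row(
                    scenario=3, label=label, metric=code.metric, n=code.n,
                    dmin=code.dmin, p_or_e=p, trials=trials, n_correct=n_correct,
                    n_wrong=n_wrong, n_ambiguous=n_ambiguous,
                    mean_mutations=edit_total / trials, rng_seed=rng_seed,
                )
            )
    return pd.DataFrame(rows)
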