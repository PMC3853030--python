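"""Read decoding: boundary recovery, classic fixed-length failure modes,
Hamming decoding and FASTQ demultiplexing."""

import numpy as np
import pytest

from seqlev.codes import BarcodeSet, greedy_closure
from seqlev.decode import (
    EmptyCodeError,
    FastqRecord,
    TruncatedReadError,
    classic_decode_fixed_length,
    demultiplex,
    hamming_decode,
    sl_decode,
)
from seqlev.filters import candidate_matrix
from seqlev.metrics import levenshtein_distance, sl_traceback
from seqlev.sequences import ALPHABET, random_word


def test_sl_decode_worked_example(example_code4):
    res = sl_decode("TCCATGCATA", example_code4)
    assert (res.barcode, res.distance, res.boundary, res.status) == ("TTCC", 1, 3, "unique")


def test_sl_decode_uncorrupted_read(example_code4):
    res = sl_decode("TTCCATGCATA", example_code4)
    assert (res.barcode, res.distance, res.boundary, res.status) == ("TTCC", 0, 4, "unique")


def test_sl_decode_window_matches_full_read(example_code4):
    """For distances within the guarantee the n+k window changes nothing."""
    rng = np.random.default_rng(4)
    for _ in range(200):
        idx = int(rng.integers(0, 4))
        word = example_code4.barcodes[idx]
        pos = int(rng.integers(0, 4))
        corrupted = word[:pos] + word[pos + 1 :]  # one deletion
        read = corrupted + random_word(7, rng)
        a = sl_decode(read, example_code4)
        b = sl_decode(read, example_code4, window="full")
        assert (a.matched_index, a.status) == (b.matched_index, b.status)
        assert a.matched_index == idx


def test_sl_decode_rejects_and_flags_ambiguity():
    code = BarcodeSet(n=4, metric="sequence_levenshtein", dmin=3,
                      barcodes=["TTCC", "ACAC", "CGAA", "TAGG"])
    # a read far from everything is rejected at the default threshold k=1
    res = sl_decode("GGGGGGGGGG", code)
    assert res.status == "rejected" and res.matched_index is None
    # equidistant read against a deliberately tight (invalid-for-k) code
    pair = BarcodeSet(n=2, metric="sequence_levenshtein", dmin=1, barcodes=["AA", "CC"])
    res = sl_decode("ACGGGG", pair, max_distance=None)
    assert res.status == "ambiguous" and res.matched_index is None
    assert set(res.tied_indices) == {0, 1}
    rng = np.random.default_rng(0)
    res = sl_decode("ACGGGG", pair, max_distance=None, rng=rng)
    assert res.status == "ambiguous" and res.matched_index in (0, 1)


def test_sl_decode_errors(example_code4):
    with pytest.raises(TruncatedReadError):
        sl_decode("TC", example_code4)
    with pytest.raises(EmptyCodeError):
        sl_decode("TTCCAA", BarcodeSet(n=4, metric="sequence_levenshtein", dmin=3, barcodes=[]))


def test_boundary_explains_read_split(example_code4):
    """The recovered boundary always splits the read so that the matched
    barcode accounts for the prefix at exactly the achieved distance, and
    equals n + indel balance of the optimal edit script."""
    rng = np.random.default_rng(11)
    n = example_code4.n
    for _ in range(300):
        idx = int(rng.integers(0, 4))
        word = example_code4.barcodes[idx]
        op = rng.choice(["del", "ins", "sub", "none"])
        if op == "del":
            pos = int(rng.integers(0, n))
            corrupted = word[:pos] + word[pos + 1 :]
        elif op == "ins":
            pos = int(rng.integers(0, n + 1))
            corrupted = word[:pos] + ALPHABET[rng.integers(0, 4)] + word[pos:]
        elif op == "sub":
            pos = int(rng.integers(0, n))
            corrupted = word[:pos] + "ACGT"[rng.integers(0, 4)] + word[pos + 1 :]
        else:
            corrupted = word
        read = corrupted + random_word(6, rng)
        res = sl_decode(read, example_code4)
        assert res.matched_index == idx
        window = read[: n + example_code4.k]
        assert res.boundary == n + sl_traceback(res.barcode, window).indel_balance
        assert levenshtein_distance(res.barcode, read[: res.boundary]) == res.distance


def test_boundary_equals_applied_shift_when_unique(example_code4):
    """Where the applied corruption is the unique optimal explanation the
    boundary is exactly n + insertions - deletions (the worked-example deletion)."""
    res = sl_decode("TCCATGCATA", example_code4)  # del at position 2
    assert res.boundary == 3
    # substitutions never move the boundary
    res = sl_decode("TACC" + "GGGGGG", example_code4)
    assert res.barcode == "TTCC" and res.boundary == 4


# --- classic fixed-length decoding --------------------------------------


def test_classic_decode_reproduces_known_failure():
    """Deleting base 2 of CAGG and reading sample 'A...' yields CGGC...,
    which fixed-length decoding assigns to the wrong codeword CGTC."""
    code = BarcodeSet(n=4, metric="levenshtein", dmin=3, barcodes=["CAGG", "CGTC"])
    res = classic_decode_fixed_length("CGGCA", code)
    assert res.barcode == "CGTC" and res.distance == 1 and res.status == "unique"
    # the distances behind the failure
    assert levenshtein_distance("CGTC", "CGGC") == 1
    assert levenshtein_distance("CAGG", "CGGC") == 2


def test_classic_decode_uncorrupted_read():
    code = BarcodeSet(n=4, metric="levenshtein", dmin=3, barcodes=["CAGG", "CGTC"])
    res = classic_decode_fixed_length("CAGGTTTT", code)
    assert (res.barcode, res.distance, res.boundary, res.status) == ("CAGG", 0, 4, "unique")


def test_classic_decode_window_fallback_recovers_indel():
    """An interior deletion is only recognised at window n - 1."""
    code = greedy_closure([], candidate_matrix(6), 3, "levenshtein")
    word = code.barcodes[10]
    corrupted = word[:2] + word[3:]  # delete base 3
    rng = np.random.default_rng(1)
    read = corrupted + "T" * 6
    res = classic_decode_fixed_length(read, code, rng)
    if res.barcode == word:  # recovery happens via the n-1 window...
        assert res.boundary in (5, 6, 7)
    else:  # ...unless an adverse context produced a closer wrong codeword
        assert res.distance <= 1


def test_classic_decode_best_effort_always_assigns():
    code = BarcodeSet(n=4, metric="levenshtein", dmin=3, barcodes=["CAGG", "CGTC"])
    rng = np.random.default_rng(2)
    res = classic_decode_fixed_length("TTTTTTTT", code, rng, best_effort=True)
    assert res.matched_index is not None
    res = classic_decode_fixed_length("TTTTTTTT", code)
    assert res.status == "rejected"


# --- Hamming decoding ----------------------------------------------------


def test_hamming_decode_corrects_single_substitution():
    code = BarcodeSet(n=3, metric="hamming", dmin=3, barcodes=["ACT", "GTA", "TAG"])
    res = hamming_decode("ACGTTT", code)  # ACT with T->G at position 3
    assert (res.barcode, res.distance, res.boundary) == ("ACT", 1, 3)
    res = hamming_decode("ACTGGG", code)
    assert res.distance == 0
    # exhaustively: every single substitution of every codeword is corrected
    for word in code.barcodes:
        for pos in range(3):
            for base in "ACGT":
                if base == word[pos]:
                    continue
                mutated = word[:pos] + base + word[pos + 1 :]
                assert hamming_decode(mutated + "AAA", code).barcode == word


def test_hamming_decode_exact_match_mode():
    code = BarcodeSet(n=3, metric="hamming", dmin=1, barcodes=["ACT", "GTA"])
    assert hamming_decode("ACTAAA", code, max_distance=0).barcode == "ACT"
    assert hamming_decode("ACGAAA", code, max_distance=0).status == "rejected"


# --- demultiplexing -------------------------------------------------------


def _make_reads(code, n_reads, rng, errors=0):
    reads = []
    truth = []
    for i in range(n_reads):
        idx = int(rng.integers(0, len(code)))
        word = code.barcodes[idx]
        if errors:
            from seqlev.simulate import mutate_exact

            word, _ = mutate_exact(word, errors, rng)
        seq = word + random_word(8, rng)
        reads.append(FastqRecord(f"read{i}", seq, "I" * len(seq)))
        truth.append(idx)
    return reads, truth


def test_demultiplex_clean_reads_fully_assigned(tmp_path, example_code4):
    rng = np.random.default_rng(5)
    reads, truth = _make_reads(example_code4, 400, rng)
    summary = demultiplex(reads, example_code4, tmp_path)
    per_sample = summary[summary.sample_id != "undetermined"]
    assert int(per_sample.n_unique.sum()) == 400
    assert (per_sample.dropna().mean_boundary == example_code4.n).all()
    # conservation: counts sum to input reads
    assert int(summary[["n_unique", "n_ambiguous", "n_rejected"]].to_numpy().sum()) == 400
    # trimmed outputs exist and have barcode removed
    ids = example_code4.sample_ids()
    out = list((tmp_path / f"{ids[0]}.fastq").read_text().splitlines())
    assert len(out) % 4 == 0 and len(out[1]) == 8


def test_demultiplex_single_error_reads_all_correct(tmp_path, example_code4):
    """k=1 guarantee carries through the full demultiplexing path."""
    rng = np.random.default_rng(6)
    reads, truth = _make_reads(example_code4, 300, rng, errors=1)
    summary = demultiplex(reads, example_code4, tmp_path)
    assert int(summary[summary.sample_id != "undetermined"].n_unique.sum()) == 300
    # verify assignment correctness via per-sample counts
    import collections

    expected = collections.Counter(example_code4.sample_ids()[i] for i in truth)
    got = dict(zip(summary.sample_id, summary.n_unique))
    for sid, count in expected.items():
        assert got[sid] == count
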