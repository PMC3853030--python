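"""Hamming, Levenshtein and Sequence-Levenshtein distances.

The Sequence-Levenshtein distance is the core of this package.  A DNA
barcode sits at the start of a sequencing read, immediately followed by
sample sequence; an insertion or deletion inside the barcode shifts the
barcode/sample boundary, so the length of the received barcode is unknown
and the classic Levenshtein distance (which compares whole words of known
length) misjudges it.  The Sequence-Levenshtein distance d_SL(A, B) is the
minimum number of substitutions, insertions and deletions turning A into a
word A', followed by one *free* final step that either truncates A' to the
length of B or elongates A' with the missing bases of B.  Consequently
d_SL(A, B) = 0 whenever one word is a prefix of the other, and on the
quotient induced by that prefix equivalence d_SL is a true metric.

Operationally, with D the (|A|+1) x (|B|+1) Wagner-Fischer matrix of unit
edit costs,

    d_SL(A, B) = min( min_j D[|A|, j],  min_i D[i, |B|] )

the minimum over the last row (edit A into a prefix of B, elongate for
free) and the last column (edit a prefix of A into B, i.e. truncate A's
suffix for free).  All distances here use unit costs for the three edit
operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import validate


class LengthMismatchError(ValueError):
    """Hamming distance is undefined for words of different lengths."""


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which equal-length words ``a`` and ``b`` differ."""
    a = validate(a, name="a")
    b = validate(b, name="b")
    if len(a) != len(b):
        raise LengthMismatchError(
            f"Hamming distance needs equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


def levenshtein_matrix(a: str, b: str) -> np.ndarray:
    """Wagner-Fischer dynamic-programming matrix with unit costs.

    Cell ``[i, j]`` holds the Levenshtein distance between the length-i
    prefix of ``a`` and the length-j prefix of ``b``; row/column 0 encode
    edits against the empty word.
    """
    a = validate(a, name="a")
    b = validate(b, name="b")
    la, lb = len(a), len(b)
    D = np.empty((la + 1, lb + 1), dtype=np.int64)
    D[0, :] = np.arange(lb + 1)
    D[:, 0] = np.arange(la + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
                D[i - 1, j] + 1,
                D[i, j - 1] + 1,
            )
    return D


def levenshtein_distance(a: str, b: str) -> int:
    """Classic Levenshtein distance (bottom-right cell of the DP matrix)."""
    return int(levenshtein_matrix(a, b)[-1, -1])


def sequence_levenshtein_distance(a: str, b: str) -> int:
    """Sequence-Levenshtein distance: DP minimum over last row and column.

    Symmetric, bounded above by the classic Levenshtein distance, and zero
    exactly when one word is a prefix of the other (the empty word is a
    prefix of everything).
    """
    D = levenshtein_matrix(a, b)
    return int(min(D[-1, :].min(), D[:, -1].min()))


@dataclass(frozen=True)
class EditOp:
    """One edit operation, positioned in 1-based *source* coordinates.

    ``substitute``: replace the source base at ``position`` with ``base``.
    ``delete``: remove the source base at ``position``.
    ``insert``: place ``base`` immediately before source position
    ``position`` (``position = len(source) + 1`` appends at the end).
    """

    kind: str  # "substitute" | "insert" | "delete"
    position: int
    base: str | None = None

    def __str__(self) -> str:
        if self.kind == "substitute":
            return f'sub("{self.base}",{self.position})'
        if self.kind == "insert":
            return f'ins("{self.base}",{self.position})'
        return f"del({self.position})"


@dataclass(frozen=True)
class EditScript:
    """An optimal chain of edits realising a Sequence-Levenshtein distance.

    ``operations`` transform the source word; ``final_action`` then applies
    the free boundary step: ``"elongate"`` appends ``elongation`` (unmatched
    suffix of the target), ``"truncate"`` cuts the result to the target
    length, ``"none"`` means the edits alone reach the target.

    ``boundary_index`` records which DP boundary cell realised the
    distance: the last-row column index j (elongate/none) or the
    last-column row index i (truncate).  The indel balance
    ``n_insertions - n_deletions`` is what decoders use to recover the
    post-mutation barcode length.
    """

    operations: tuple[EditOp, ...]
    final_action: str  # "none" | "truncate" | "elongate"
    elongation: str = ""
    boundary_index: int = 0
    target_length: int = 0
    source: str = field(default="", repr=False)

    @property
    def n_substitutions(self) -> int:
        return sum(op.kind == "substitute" for op in self.operations)

    @property
    def n_insertions(self) -> int:
        return sum(op.kind == "insert" for op in self.operations)

    @property
    def n_deletions(self) -> int:
        return sum(op.kind == "delete" for op in self.operations)

    @property
    def cost(self) -> int:
        """Number of costed operations; the free final step is excluded."""
        return len(self.operations)

    @property
    def indel_balance(self) -> int:
        """insertions - deletions; shifts the barcode/sample boundary."""
        return self.n_insertions - self.n_deletions

    def apply(self, source: str) -> str:
        """Replay the script on ``source`` (then the free final step)."""
        source = validate(source, name="source")
        inserts: dict[int, list[str]] = {}
        subs: dict[int, str] = {}
        dels: set[int] = set()
        for op in self.operations:
            if op.kind == "insert":
                inserts.setdefault(op.position, []).append(op.base)  # type: ignore[arg-type]
            elif op.kind == "substitute":
                subs[op.position] = op.base  # type: ignore[assignment]
            else:
                dels.add(op.position)
        out: list[str] = []
        for pos in range(1, len(source) + 2):
            out.extend(inserts.get(pos, ()))
            if pos <= len(source) and pos not in dels:
                out.append(subs.get(pos, source[pos - 1]))
        word = "".join(out)
        if self.final_action == "elongate":
            return word + self.elongation
        if self.final_action == "truncate":
            return word[: self.target_length]
        return word

    def __str__(self) -> str:
        parts = [str(op) for op in self.operations]
        if self.final_action == "elongate":
            parts.append(f'elong("{self.elongation}")')
        elif self.final_action == "truncate":
            parts.append(f"trunc({self.target_length})")
        return ",".join(parts) if parts else "identity"


def _select_boundary_cell(D: np.ndarray) -> tuple[int, int]:
    """Pick the DP boundary cell realising d_SL, with deterministic ties.

    Among optimal last-row cells, prefer the column index j closest to
    |a| and, among equally close, the larger j: this minimises the net
    indel count of the reported script, so the recovered word boundary is
    the most conservative one.  The last column (truncation) is only used
    when no last-row cell attains the minimum.
    """
    la = D.shape[0] - 1
    lb = D.shape[1] - 1
    best = int(min(D[la, :].min(), D[:, lb].min()))
    row_js = [j for j in range(lb + 1) if D[la, j] == best]
    if row_js:
        j = min(row_js, key=lambda j: (abs(j - la), -j))
        return la, j
    col_is = [i for i in range(la + 1) if D[i, lb] == best]
    i = min(col_is, key=lambda i: (abs(i - lb), -i))
    return i, lb


def sl_traceback(a: str, b: str) -> EditScript:
    """One optimal edit script realising ``sequence_levenshtein_distance(a, b)``.

    The script's cost equals the distance, and replaying it on ``a``
    (including the free truncate/elongate step) yields ``b`` exactly.
    When several DP paths are optimal the diagonal (match/substitute) move
    is preferred, then deletion, then insertion.
    """
    a = validate(a, name="a")
    b = validate(b, name="b")
    D = levenshtein_matrix(a, b)
    ci, cj = _select_boundary_cell(D)
    ops: list[EditOp] = []
    i, j = ci, cj
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] and a[i - 1] == b[j - 1]:
            i, j = i - 1, j - 1
        elif i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + 1:
            ops.append(EditOp("substitute", i, b[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            ops.append(EditOp("delete", i))
            i -= 1
        else:
            ops.append(EditOp("insert", i + 1, b[j - 1]))
            j -= 1
    ops.reverse()
    la, lb = len(a), len(b)
    if ci == la and cj == lb:
        action, elong, boundary = "none", "", cj
    elif ci == la:
        action, elong, boundary = "elongate", b[cj:], cj
    else:
        action, elong, boundary = "truncate", "", ci
    return EditScript(
        operations=tuple(ops),
        final_action=action,
        elongation=elong,
        boundary_index=boundary,
        target_length=lb,
        source=a,
    )
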