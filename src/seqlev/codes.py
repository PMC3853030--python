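"""Barcode code construction: greedy closure and evolutionary seed search.

A *code* is a set of equal-length barcodes whose pairwise distances under a
chosen metric are all at least ``dmin``; with ``dmin = 2k + 1`` it corrects
``k`` errors under that metric.  No closed-form construction is known for
Levenshtein-type codes, so codes are built with a greedy closure
evolutionary algorithm: a small random *seed* of 2-4 mutually compatible
barcodes is completed by scanning the whole eligible candidate pool in
lexicographic order and accepting every barcode that keeps all pairwise
distances >= dmin.  The evolutionary layer searches over seeds, using the
size of a seed's closure as its fitness.

Error-correction bookkeeping in DNA context: a Sequence-Levenshtein code
with dmin = 2k + 1 corrects k errors even with sample sequence appended
after the barcode.  A classic Levenshtein code needs dmin = 4k + 1 for the
same guarantee when decoded at fixed length (dmin = 5 for one error,
dmin = 9 for two), and a Hamming code corrects substitutions only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels as K
from .filters import DEFAULT_POLICY, FilterPolicy, candidate_matrix, passes_filters
from .sequences import decode_rows, encode, validate

METRICS = ("hamming", "levenshtein", "sequence_levenshtein")


class InvalidSeedError(ValueError):
    """Seed barcodes do not satisfy the pairwise distance requirement."""


class NoCandidatesError(ValueError):
    """The filtered candidate pool is empty."""


def pair_distance(a: str, b: str, metric: str) -> int:
    """Distance between two words under a metric named in :data:`METRICS`."""
    return int(K.pair_distance(encode(validate(a)), encode(validate(b)), K.METRIC_CODES[metric]))


@dataclass
class BarcodeSet:
    """A barcode code: equal-length words with pairwise distance >= dmin.

    ``k = (dmin - 1) // 2`` errors are correctable under ``metric``;
    ``guaranteed_correction_dna`` is the stricter guarantee that survives
    when the barcode is embedded at the start of a longer read.
    """

    n: int
    metric: str
    dmin: int
    barcodes: list[str]
    ids: list[str] | None = None
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        self.barcodes = [validate(b, name="barcode") for b in self.barcodes]
        for b in self.barcodes:
            if len(b) != self.n:
                raise ValueError(f"barcode {b!r} does not have length n={self.n}")
        if self.ids is not None and len(self.ids) != len(self.barcodes):
            raise ValueError("ids and barcodes differ in length")

    def __len__(self) -> int:
        return len(self.barcodes)

    @property
    def k(self) -> int:
        """Errors correctable under the code's own metric (dmin = 2k + 1)."""
        return (self.dmin - 1) // 2

    @property
    def guaranteed_correction_dna(self) -> int:
        """Errors guaranteed correctable with the barcode embedded in a read.

        Sequence-Levenshtein codes keep their full capability; classic
        Levenshtein codes decoded at fixed length need dmin = 4k + 1; a
        Hamming code has no indel guarantee at all in context.
        """
        if self.metric == "sequence_levenshtein":
            return self.k
        if self.metric == "levenshtein":
            return (self.dmin - 1) // 4
        return 0

    @property
    def matrix(self) -> np.ndarray:
        """Barcodes encoded as a ``(size, n)`` uint8 matrix (cached)."""
        if self._matrix is None or len(self._matrix) != len(self.barcodes):
            self._matrix = (
                np.vstack([encode(b) for b in self.barcodes])
                if self.barcodes
                else np.empty((0, self.n), dtype=np.uint8)
            )
        return self._matrix

    def sample_ids(self) -> list[str]:
        """Explicit ids, or generated ``S001 ...`` labels."""
        if self.ids is not None:
            return list(self.ids)
        width = max(3, len(str(len(self.barcodes))))
        return [f"S{i + 1:0{width}d}" for i in range(len(self.barcodes))]


def code_rate(code: BarcodeSet) -> float:
    """Information rate log2(|C|) / log2(4^n) of a code."""
    if len(code) < 1:
        raise ValueError("code rate undefined for an empty code")
    return math.log2(len(code)) / (2 * code.n)


def _as_matrix(candidates: Sequence[str] | np.ndarray, n: int | None = None) -> np.ndarray:
    if isinstance(candidates, np.ndarray):
        return np.ascontiguousarray(candidates, dtype=np.uint8)
    if len(candidates) == 0:
        if n is None:
            raise ValueError("cannot infer barcode length from an empty candidate list")
        return np.empty((0, n), dtype=np.uint8)
    return np.vstack([encode(validate(c)) for c in candidates])


def check_seed(seed: Sequence[str], dmin: int, metric: str) -> None:
    """Raise :class:`InvalidSeedError` unless the seed is mutually compatible."""
    if not 1 <= len(seed):
        raise InvalidSeedError("seed must contain at least one barcode")
    for i, a in enumerate(seed):
        for b in seed[i + 1 :]:
            d = pair_distance(a, b, metric)
            if d < dmin:
                raise InvalidSeedError(
                    f"seed pair ({a!r}, {b!r}) has distance {d} < dmin={dmin}"
                )


def greedy_closure(
    seed: Sequence[str],
    candidates: Sequence[str] | np.ndarray,
    dmin: int,
    metric: str,
) -> BarcodeSet:
    """Complete a seed by lexicographic greedy scan of the candidate pool.

    Every candidate (in the given order) is accepted iff its distance to
    all previously accepted barcodes -- the seed first -- is >= dmin.
    Deterministic given its inputs; duplicates of accepted barcodes are
    rejected automatically (their distance is 0).
    """
    seed = [validate(s, name="seed barcode") for s in seed]
    if seed:
        check_seed(seed, dmin, metric)
    mcode = K.METRIC_CODES[metric]
    if seed:
        n = len(seed[0])
        cand_mat = _as_matrix(candidates, n=n)
    else:
        cand_mat = _as_matrix(candidates)
        n = cand_mat.shape[1]
    seed_mat = _as_matrix(seed, n=n) if seed else np.empty((0, n), dtype=np.uint8)
    mask = K.greedy_scan(cand_mat, seed_mat, dmin, mcode)
    accepted = list(seed) + decode_rows(cand_mat[np.asarray(mask, dtype=bool)])
    return BarcodeSet(n=n, metric=metric, dmin=dmin, barcodes=accepted)


@dataclass(frozen=True)
class EAConfig:
    """Knobs of the evolutionary seed search.

    The budget is expressed in greedy-closure evaluations (the dominant
    cost), which makes runs hardware-independent.  Mutation replaces one
    seed barcode with a random pool barcode that keeps the seed internally
    compatible; there is no crossover.  Steady-state replacement: each new
    child displaces the current worst individual if at least as fit, so
    the best closure found can only improve.
    """

    population_size: int = 50
    n_evaluations: int = 400
    seed_size_min: int = 2
    seed_size_max: int = 4
    rng_seed: int = 0
    tournament_size: int = 2
    mutation_attempts: int = 200

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.n_evaluations < 1:
            raise ValueError("population_size and n_evaluations must be >= 1")
        if not 1 <= self.seed_size_min <= self.seed_size_max:
            raise ValueError("need 1 <= seed_size_min <= seed_size_max")


def random_seed_rows(
    pool: np.ndarray, dmin: int, metric_code: int, size: int, rng: np.random.Generator
) -> list[int]:
    """Draw pool row indices forming a mutually compatible seed."""
    n_pool = len(pool)
    while True:
        rows = [int(r) for r in rng.choice(n_pool, size=size, replace=False)]
        if all(
            K.pair_at_least(pool[a], pool[b], dmin, metric_code)
            for i, a in enumerate(rows)
            for b in rows[i + 1 :]
        ):
            return rows


def evolutionary_search(
    n: int,
    k: int,
    metric: str,
    policy: FilterPolicy = DEFAULT_POLICY,
    config: EAConfig = EAConfig(),
    candidates: np.ndarray | None = None,
) -> BarcodeSet:
    """Largest code found by the greedy closure evolutionary algorithm.

    ``dmin = 2k + 1`` is derived from the requested correction capability.
    Reproducible given ``config.rng_seed``; the returned set is the best
    closure over all evaluated seeds.
    """
    dmin = 2 * k + 1
    mcode = K.METRIC_CODES[metric]
    pool = candidate_matrix(n, policy) if candidates is None else _as_matrix(candidates)
    if len(pool) == 0:
        raise NoCandidatesError(f"no length-{n} candidates pass the filter policy")
    rng = np.random.default_rng(config.rng_seed)

    def closure_size(rows: list[int]) -> int:
        return int(K.greedy_scan(pool, pool[rows], dmin, mcode).sum()) + len(rows)

    def seed_ok(rows: list[int]) -> bool:
        return all(
            K.pair_at_least(pool[a], pool[b], dmin, mcode)
            for i, a in enumerate(rows)
            for b in rows[i + 1 :]
        )

    pop_size = min(config.population_size, config.n_evaluations)
    population: list[list[int]] = []
    fitness: list[int] = []
    for _ in range(pop_size):
        size = int(rng.integers(config.seed_size_min, config.seed_size_max + 1))
        size = min(size, len(pool))
        rows = random_seed_rows(pool, dmin, mcode, size, rng)
        population.append(rows)
        fitness.append(closure_size(rows))
    evaluations = len(population)
    best_rows = population[int(np.argmax(fitness))]
    best_fit = max(fitness)

    while evaluations < config.n_evaluations:
        contenders = rng.integers(0, len(population), size=config.tournament_size)
        parent = max(contenders, key=lambda i: fitness[int(i)])
        child = list(population[int(parent)])
        pos = int(rng.integers(0, len(child)))
        for _ in range(config.mutation_attempts):
            child[pos] = int(rng.integers(0, len(pool)))
            if seed_ok(child):
                break
        else:  # pragma: no cover - pathological pools only
            child = population[int(parent)]
        fit = closure_size(child)
        evaluations += 1
        worst = int(np.argmin(fitness))
        if fit >= fitness[worst]:
            population[worst] = child
            fitness[worst] = fit
        if fit > best_fit:
            best_fit, best_rows = fit, child
    return greedy_closure(decode_rows(pool[best_rows]), pool, dmin, metric)


def verify_code(
    code: BarcodeSet, policy: FilterPolicy | None = None
) -> tuple[bool, list[tuple]]:
    """Brute-force check of all pairwise distances (and optional filters).

    Returns ``(ok, violations)``; each violation is either
    ``("distance", barcode_i, barcode_j, d)`` or ``("filter", barcode)``.
    Duplicates surface as distance-0 pairs.
    """
    violations: list[tuple] = []
    mcode = K.METRIC_CODES[code.metric]
    mat = code.matrix
    for i in range(len(mat)):
        for j in range(i + 1, len(mat)):
            if not K.pair_at_least(mat[i], mat[j], code.dmin, mcode):
                d = int(K.pair_distance(mat[i], mat[j], mcode))
                violations.append(("distance", code.barcodes[i], code.barcodes[j], d))
    if policy is not None:
        for b in code.barcodes:
            if not passes_filters(b, policy):
                violations.append(("filter", b))
    return (not violations, violations)
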