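"""Independent brute-force oracle: dense vectors, exhaustive pairwise
distances, and a direct line-by-line transcription of the conventional
and hierarchical scoring algorithms.

Deliberately shares no code with the package: words are tallied by
substring slicing, vectors are dense Python lists in lexicographic word
order (which coincides with 2-bit big-endian packing, A<C<G<T), and
nearest neighbors are found by scanning.  Intended for tiny inputs only.
"""

from __future__ import annotations

import itertools
import math

BASES = "ACGT"


def naive_count(sequence: str, n: int) -> tuple[dict[str, int], int, int]:
    """(word -> count, total, skipped) by direct substring tallying."""
    seq = sequence.upper()
    counts: dict[str, int] = {}
    total = skipped = 0
    for i in range(len(seq) - n + 1):
        w = seq[i : i + n]
        if any(ch not in BASES for ch in w):
            skipped += 1
            continue
        counts[w] = counts.get(w, 0) + 1
        total += 1
    return counts, total, skipped


def naive_dense(sequence: str, n: int, smoothed: bool = False) -> list[float]:
    """Dense frequency vector over all 4**n words in lexicographic order."""
    counts, total, _ = naive_count(sequence, n)
    words = ["".join(w) for w in itertools.product(BASES, repeat=n)]
    if smoothed:
        denom = total + 4 ** n
        return [(counts.get(w, 0) + 1) / denom for w in words]
    if total == 0:
        raise ValueError("no countable window")
    return [counts.get(w, 0) / total for w in words]


def naive_measure(measure: str, x: list[float], y: list[float]) -> float:
    if measure == "1":
        return sum(abs(a - b) for a, b in zip(x, y))
    if measure == "2":
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
    if measure == "inf":
        return max(abs(a - b) for a, b in zip(x, y))
    if measure == "kl":
        return sum(a * math.log(a / b) for a, b in zip(x, y) if a > 0)
    raise ValueError(measure)


def naive_nn(i: int, pool_ids: list[str], vectors: dict[str, list[float]],
             measure: str, candidates: list[int]) -> int:
    """Index of the nearest candidate to pool item i; ties to smallest ID."""
    best = None
    for j in candidates:
        if j == i:
            continue
        d = naive_measure(measure, vectors[pool_ids[i]], vectors[pool_ids[j]])
        if best is None or d < best[0] or (d == best[0] and pool_ids[j] < pool_ids[best[1]]):
            best = (d, j)
    assert best is not None
    return best[1]


def naive_conventional(records, vectors, level: int, measure: str):
    """records: list of (id, lineage) tuples; level: 1..7.  Returns (score, m)."""
    ids = [r[0] for r in records]
    score = 0
    m = 0
    for i, (rid, lin) in enumerate(records):
        others_same = any(
            r[1][level - 1] == lin[level - 1] for j, r in enumerate(records) if j != i
        )
        if not others_same:
            continue
        m += 1
        j = naive_nn(i, ids, vectors, measure, list(range(len(records))))
        if records[j][1][level - 1] == lin[level - 1]:
            score += 1
    return (score / m if m else None), m


def naive_hierarchical(records, vectors, level: int, measure: str):
    """Direct transcription of the recursive hierarchical score.

    Returns (score or None, m at the requested level).
    """
    if level == 1:
        return naive_conventional(records, vectors, 1, measure)
    ids = [r[0] for r in records]
    score = 0
    m = 0
    for i, (rid, lin) in enumerate(records):
        pruned = [
            j for j, r in enumerate(records) if r[1][level - 2] == lin[level - 2]
        ]
        unique_in_pruned = not any(
            records[j][1][level - 1] == lin[level - 1] for j in pruned if j != i
        )
        if len(pruned) > 1 and not unique_in_pruned:
            m += 1
            j = naive_nn(i, ids, vectors, measure, pruned)
            if records[j][1][level - 1] == lin[level - 1]:
                score += 1
    lower, _ = naive_hierarchical(records, vectors, level - 1, measure)
    if m == 0 or lower is None:
        return None, m
    return score / m * lower, m
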