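"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the null-table
distribution is enumerated from raw label shuffles, and dissimilarity /
entropy values are recomputed from first principles.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations

import numpy as np


def exact_label_shuffle_distribution(row_margins, col_margins):
    """Exact permutation distribution of 2-row tables with fixed margins.

    Enumerates every way of choosing which of the N individual visits carry
    the first row's label (a full label shuffle), and tallies the resulting
    first-row count vectors.  Returns {first_row_tuple: probability}.
    """
    cols = list(col_margins)
    visits = [j for j, c in enumerate(cols) for _ in range(c)]
    n_first = int(row_margins[0])
    assert sum(row_margins) == len(visits)
    tally: Counter = Counter()
    total = 0
    for chosen in combinations(range(len(visits)), n_first):
        row = [0] * len(cols)
        for i in chosen:
            row[visits[i]] += 1
        tally[tuple(row)] += 1
        total += 1
    return {k: v / total for k, v in tally.items()}


def total_variation(p: dict, q: dict) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


def empirical_first_row_distribution(draws: np.ndarray) -> dict:
    """Empirical distribution over first-row tuples from (n, S) draws."""
    draws = np.asarray(draws)
    n, s = draws.shape
    base = int(draws.max()) + 1
    radix = base ** np.arange(s - 1, -1, -1)
    codes = draws @ radix
    uniq, counts = np.unique(codes, return_counts=True)
    out = {}
    for code, c in zip(uniq, counts):
        row = []
        rem = int(code)
        for r in radix:
            row.append(rem // int(r))
            rem %= int(r)
        out[tuple(row)] = c / n
    return out


def morisita_horn_reference(x, y) -> float:
    """Direct transcription of the Morisita-Horn dissimilarity formula."""
    X, Y = sum(x), sum(y)
    cross = sum(a * b for a, b in zip(x, y))
    dx = sum(a * a for a in x) / X**2
    dy = sum(b * b for b in y) / Y**2
    return 1.0 - (2.0 * cross) / ((dx + dy) * X * Y)


def shannon_reference(counts) -> float:
    total = sum(counts)
    return -sum((c / total) * math.log(c / total) for c in counts if c > 0)


def durbin_watson_reference(e) -> float:
    e = list(e)
    num = sum((e[t] - e[t - 1]) ** 2 for t in range(1, len(e)))
    return num / sum(v * v for v in e)


def compositions(total: int, parts: int):
    """All strictly positive integer compositions of ``total`` into ``parts``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(1, total - parts + 2):
        for rest in compositions(total - first, parts - 1):
            yield (first,) + rest
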