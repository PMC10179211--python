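"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the code paths (and libraries) the package itself
uses: plain direct summation for the product-moment coefficient, explicit
mid-ranking for Spearman, and O(n²) pair enumeration with tie bookkeeping
for Kendall's tau-b.
"""

from __future__ import annotations

import math


def pearson_brute(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x)
    dy = sum((b - my) ** 2 for b in y)
    return num / math.sqrt(dx * dy)


def midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_brute(x, y) -> float:
    return pearson_brute(midranks(x), midranks(y))


def kendall_brute(x, y) -> float:
    """tau-b by explicit pair enumeration with tie correction."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (concordant - discordant) / denom


def _tie_term(values) -> float:
    from collections import Counter

    return sum(t * (t - 1) / 2 for t in Counter(values).values())


def manders_brute(x, y, threshold) -> float:
    return sum(a for a, b in zip(x, y) if b > threshold) / sum(x)
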