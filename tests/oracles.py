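"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: pair agreement is
enumerated pair by pair, set partitions are generated as restricted
growth strings, and pixel-set overlap is computed with literal Python
set arithmetic.
"""

from itertools import product

import numpy as np


def brute_rand_index(a, b):
    """RI by explicit enumeration of all object pairs."""
    a, b = list(a), list(b)
    n = len(a)
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a == same_b:
                agree += 1
    return agree / total if total else 1.0


def pair_counts(a, b):
    """(TP, TN, FP, FN) over all unordered object pairs."""
    tp = tn = fp = fn = 0
    n = len(a)
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            if sa and sb:
                tp += 1
            elif not sa and not sb:
                tn += 1
            elif sa:
                fp += 1
            else:
                fn += 1
    return tp, tn, fp, fn


def all_set_partitions(n):
    """Every partition of n objects, as restricted-growth label strings."""
    def grow(prefix, maxlab):
        if len(prefix) == n:
            yield list(prefix)
            return
        for lab in range(maxlab + 2):
            yield from grow(prefix + [lab], max(maxlab, lab))
    yield from grow([0], 0)


def all_two_cluster_labelings(n):
    """Every {0,1} labelling with the first object fixed to 0 (one per
    partition up to label permutation), including the one-cluster case."""
    for rest in product([0, 1], repeat=n - 1):
        yield [0, *rest]


def brute_set_jaccard(cells_a, cells_b, areas):
    """Jaccard of two v-cell sets via literal pixel-id set arithmetic."""
    pix, start = {}, 0
    for i, a in enumerate(areas):
        pix[i] = set(range(start, start + int(a)))
        start += int(a)
    cells_a, cells_b = list(cells_a), list(cells_b)
    set_a = set().union(*(pix[i] for i in cells_a)) if cells_a else set()
    set_b = set().union(*(pix[i] for i in cells_b)) if cells_b else set()
    union = set_a | set_b
    return len(set_a & set_b) / len(union) if union else 0.0
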