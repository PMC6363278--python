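"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results by exhaustive enumeration or
per-base counting, sharing no code with the implementations they check.
"""

import numpy as np

from ladkit.partition import CLASSES


def brute_force_best_segment(scores, lo, hi):
    """Exhaustive O(n^2) max-sum segment; ties -> longer, then leftmost."""
    best = None
    for i in range(lo, hi):
        s = 0.0
        for j in range(i, hi):
            s += scores[j]
            key = (s, j + 1 - i, -i)
            if best is None or key > best[0]:
                best = (key, i, j + 1)
    return best[0][0], best[1], best[2]


def brute_force_segments(scores, min_score):
    """Disjoint maximal-scoring segments by explicit recursion."""
    out = []

    def rec(lo, hi):
        if hi <= lo:
            return
        sc, i, j = brute_force_best_segment(scores, lo, hi)
        if sc < min_score:
            return
        out.append((i, j))
        rec(lo, i)
        rec(j, hi)

    rec(0, len(scores))
    return sorted(out)


def per_base_labels(partition, chrom):
    """Dense per-base class-index array for one chromosome."""
    length = partition.genome.length(chrom)
    labels = np.empty(length, dtype=np.int8)
    for c, start, end, label in partition.segments():
        if c == chrom:
            labels[start:end] = CLASSES.index(label)
    return labels


def per_base_fate_counts(ctrl, trt):
    """4x4 fate matrix by brute-force per-base comparison."""
    counts = np.zeros((4, 4), dtype=np.int64)
    for chrom, _ in ctrl.genome.chromosomes:
        lc = per_base_labels(ctrl, chrom)
        lt = per_base_labels(trt, chrom)
        np.add.at(counts, (lc, lt), 1)
    return counts


def per_base_jaccard(set1, set2, genome):
    """Jaccard of two coverage sets by dense boolean arrays."""
    inter = union = 0
    for chrom, length in genome.chromosomes:
        a = np.zeros(length, dtype=bool)
        b = np.zeros(length, dtype=bool)
        for c, s, e in set1:
            if c == chrom:
                a[s:e] = True
        for c, s, e in set2:
            if c == chrom:
                b[s:e] = True
        inter += int((a & b).sum())
        union += int((a | b).sum())
    return inter, union
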