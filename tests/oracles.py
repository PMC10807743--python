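"""Independent brute-force oracles used to freeze expected values.

Each oracle is a direct transcription of the defining formula or an
exhaustive enumeration, kept deliberately independent of the library code
paths it checks.
"""

from __future__ import annotations

import itertools
import math
from math import comb


def auroc_pairwise(scores, labels) -> float:
    """All positive-negative pairs; ties credit 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def fisher_two_sided(table) -> float:
    """Exhaustive fixed-margin enumeration; sums probabilities of tables no
    more probable than the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # P(top-left = x) under the hypergeometric
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(p for x in range(0, min(r1, c1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-12))


def bh_step_up(pvalues):
    """Benjamini-Hochberg by the defining step-up recursion."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj


def exons_overlap_bruteforce(gene_a, gene_b) -> bool:
    for ea in gene_a.exons:
        for eb in gene_b.exons:
            if (
                ea.chromosome == eb.chromosome
                and ea.start <= eb.end
                and eb.start <= ea.end
            ):
                return True
    return False


def merge_bruteforce(reference, target):
    """Which target gene ids survive an all-pairs overlap check."""
    added, excluded = [], []
    for t in target.genes:
        if any(exons_overlap_bruteforce(t, r) for r in reference.genes):
            excluded.append(t.gene_id)
        else:
            added.append(t.gene_id)
    return added, excluded


def kmer_valid_windows(sequence: str, k: int) -> int:
    """Number of length-k windows free of non-ACGT characters."""
    seq = sequence.upper()
    return sum(
        1
        for i in range(len(seq) - k + 1)
        if all(c in "ACGT" for c in seq[i : i + k])
    )


def signed_rank_exact_p(differences) -> float:
    """Exact two-sided paired signed-rank p by enumerating all 2^n sign
    assignments (tie-free differences)."""
    d = [x for x in differences if x != 0]
    n = len(d)
    ranks = _rank(list(map(abs, d)))
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    mean_w = sum(ranks) / 2
    dev_obs = abs(w_obs - mean_w)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= dev_obs - 1e-12:
            count += 1
    return count / 2**n


def rank_sum_exact_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = list(a) + list(b)
    ranks = _rank(pooled)
    na = len(a)
    w_obs = sum(ranks[:na])
    mean_w = na * (len(pooled) + 1) / 2
    dev_obs = abs(w_obs - mean_w)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        w = sum(ranks[i] for i in idx)
        total += 1
        if abs(w - mean_w) >= dev_obs - 1e-12:
            count += 1
    return count / total


def _rank(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for kk in range(i, j + 1):
            ranks[order[kk]] = avg
        i = j + 1
    return ranks


def pearson_textbook(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def nearest_distance_bruteforce(gene_span, marks) -> float:
    best = math.inf
    for m in marks:
        if m.chromosome != gene_span.chromosome:
            continue
        if gene_span.start <= m.end and m.start <= gene_span.end:
            return 0.0
        if m.start > gene_span.end:
            best = min(best, m.start - gene_span.end - 1)
        else:
            best = min(best, gene_span.start - m.end - 1)
    return best
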