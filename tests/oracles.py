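"""Brute-force reference computations, independent of the package internals."""

from itertools import combinations
from math import comb

import numpy as np


def wilcoxon_exact_two_sided(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments.

    Two-sided p is twice the smaller tail of the exact U distribution,
    clipped at 1 (the convention of the exact Mann-Whitney test).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    order = np.argsort(pooled)
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    all_ranks = np.arange(1, n + 1)
    for idx in combinations(range(n), n1):
        us.append(all_ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    lo = (us <= obs_u).mean()
    hi = (us >= obs_u).mean()
    return min(1.0, 2 * min(lo, hi))


def binomial_upper_tail(k, n, p0):
    """P(X >= k) for X ~ Binomial(n, p0), by direct summation."""
    return float(sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1)))


def auc_bruteforce(scores, responder_flags):
    """All-pairs AUC: wins + half-ties over responder x non-responder pairs."""
    scores = np.asarray(scores, float)
    flags = np.asarray(responder_flags, bool)
    pos, neg = scores[flags], scores[~flags]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def count_pairs_bruteforce(marked, universe):
    """Number of unordered pairs with >= 1 marked gene, by enumeration."""
    marked = set(marked)
    return sum(
        1 for a, b in combinations(sorted(universe), 2) if a in marked or b in marked
    )


def best_subset_accuracy(votes, responder_flags, seed_idx, call_threshold):
    """Best training accuracy over all candidate subsets containing the seed.

    ``votes`` is a (candidates x samples) boolean matrix; classification is
    score >= call_threshold.  Exponential in the candidate count; use only
    for <= ~12 candidates.
    """
    votes = np.asarray(votes, dtype=int)
    y = np.asarray(responder_flags, bool)
    others = [i for i in range(votes.shape[0]) if i != seed_idx]
    best = 0.0
    for r in range(len(others) + 1):
        for extra in combinations(others, r):
            idx = [seed_idx, *extra]
            scores = votes[idx].sum(axis=0)
            acc = ((scores >= call_threshold) == y).mean()
            best = max(best, acc)
    return best
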