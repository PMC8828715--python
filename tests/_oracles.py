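"""Independent brute-force oracles shared across test modules.

Each oracle re-derives a quantity by direct enumeration or a textbook
formula, deliberately avoiding the implementation path it checks.
"""

import itertools

import numpy as np
from sklearn.metrics import mutual_info_score

from radiofuse.selection import discretise_3state


def brute_force_glcm(levels, mask, n_bins, offsets):
    """Co-occurrence matrix by explicit voxel-pair enumeration."""
    counts = np.zeros((n_bins, n_bins))
    shape = levels.shape
    for idx in itertools.product(*(range(s) for s in shape)):
        if not mask[idx]:
            continue
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= n < s for n, s in zip(nb, shape)) and mask[nb]:
                counts[levels[idx], levels[nb]] += 1
    counts = counts + counts.T
    return counts / counts.sum()


def brute_force_mrmr(X, y, k):
    """Exhaustive greedy MID evaluation with sklearn MI as the oracle."""
    D = discretise_3state(X)
    p = X.shape[1]
    rel = [mutual_info_score(D[:, j], y) for j in range(p)]
    selected = [int(np.argmax(rel))]
    while len(selected) < k:
        best, best_score = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            red = np.mean([mutual_info_score(D[:, j], D[:, s])
                           for s in selected])
            score = rel[j] - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
    return selected


def brute_force_ks(genes, members):
    """Unweighted KS running-sum extreme by direct iteration."""
    n = len(genes)
    hits = [g in members for g in genes]
    nh = sum(hits)
    best, run = 0.0, 0.0
    for h in hits:
        run += 1 / nh if h else -1 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


def chi2_textbook(table):
    """Pearson's chi-squared from the definition."""
    table = np.asarray(table, dtype=float)
    row = table.sum(1, keepdims=True)
    col = table.sum(0, keepdims=True)
    expected = row * col / table.sum()
    return ((table - expected) ** 2 / expected).sum()
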