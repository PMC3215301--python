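"""Independent brute-force oracles used only by the test suite.

Deliberately naive: explicit Python loops over joint-distribution cells and
closed-form textbook formulas, sharing no code with the package internals.
"""

import math

import numpy as np


def oracle_entropy(probs, base=2.0):
    h = 0.0
    for p in probs:
        if p > 0:
            h -= p * math.log(p, base)
    return h


def oracle_mi_from_counts(counts, base=2.0):
    """I(X;C) by direct evaluation of H(C) - H(C|X) over the table cells."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p_c = [counts[:, c].sum() / n for c in range(counts.shape[1])]
    h_c = oracle_entropy(p_c, base)
    h_c_given_x = 0.0
    for g in range(counts.shape[0]):
        n_g = counts[g].sum()
        if n_g == 0:
            continue
        h_c_given_x += (n_g / n) * oracle_entropy(counts[g] / n_g, base)
    return h_c - h_c_given_x


def oracle_ig(col_a, col_b, y, base=2.0):
    """IG(A;B;C) from raw genotype columns by enumerating all joint cells."""
    pair = np.zeros((9, 2))
    a_tab = np.zeros((3, 2))
    b_tab = np.zeros((3, 2))
    for ga, gb, c in zip(col_a, col_b, y):
        pair[3 * ga + gb, c] += 1
        a_tab[ga, c] += 1
        b_tab[gb, c] += 1
    return (oracle_mi_from_counts(pair, base)
            - oracle_mi_from_counts(a_tab, base)
            - oracle_mi_from_counts(b_tab, base))


def oracle_loglog_slope(degrees, probs):
    """Closed-form OLS slope/intercept of log p on log d."""
    x = np.log(np.asarray(degrees, dtype=float))
    y = np.log(np.asarray(probs, dtype=float))
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean()


def oracle_mode_lowest(values):
    """Modal value of an integer list; ties break toward the lowest value."""
    best, best_n = None, -1
    for v in sorted(set(values)):
        n = sum(1 for x in values if x == v)
        if n > best_n:
            best, best_n = v, n
    return best
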