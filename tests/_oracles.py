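"""Independent brute-force oracles used by several test modules."""

from itertools import combinations

import numpy as np


def bh_bruteforce(p):
    """Step-up BH oracle: q_i = min over j >= rank(i) of m * p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def venn_bruteforce(sets):
    """Enumeration oracle: count each element's exact membership pattern."""
    names = sorted(sets)
    regions = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            key = "&".join(members)
            regions[key] = sum(
                1
                for x in set().union(*sets.values())
                if all(x in sets[m] for m in members)
                and not any(x in sets[o] for o in names if o not in members)
            )
    regions["__any2__"] = sum(
        1 for x in set().union(*sets.values()) if sum(x in s for s in sets.values()) >= 2
    )
    return regions


def ridge_bruteforce(Z, penalty):
    """Pairwise univariate ridge by explicit normal equations."""
    n, p = Z.shape
    coef = np.full((p, p), np.nan)
    r2 = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            x, y = Z[:, i], Z[:, j]
            b = float(x @ y / (x @ x + penalty))
            coef[i, j] = b
            resid = y - b * x
            r2[i, j] = 1.0 - float(resid @ resid) / n
    return coef, r2
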