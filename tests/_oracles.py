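"""Independent oracles used only by the tests.

These deliberately avoid the library's code paths: the permutation test
enumerates group relabellings by brute force, and the correlation oracle
evaluates the product-moment formula directly with compensated sums.
"""

import itertools
import math

import numpy as np


def permutation_t_pvalue(a, b) -> float:
    """Exhaustive two-sided permutation p for a two-sample mean difference.

    With the pooled sample fixed, |t| (pooled variance) is a monotone
    function of |mean(a) - mean(b)|, so enumerating absolute mean
    differences over all C(n1+n2, n1) relabellings yields the exact
    permutation distribution of the t test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n1 = a.size
    observed = abs(a.mean() - b.mean())
    hits = total = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(idx)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        hits += diff >= observed - 1e-12
        total += 1
    return hits / total


def pearson_direct(x, y) -> float:
    """Pearson r via the direct covariance formula with compensated sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = math.fsum(x) / n
    my = math.fsum(y) / n
    cov = math.fsum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = math.fsum((xi - mx) ** 2 for xi in x)
    vy = math.fsum((yi - my) ** 2 for yi in y)
    return cov / math.sqrt(vx * vy)
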