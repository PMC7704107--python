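"""Independent reference implementations used to cross-check the package.

These deliberately take different algorithmic routes from the library:
Hopcroft-Karp (scipy) for maximum bipartite matching and exhaustive
permutation search for the assignment problem.
"""

import itertools

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching


def brute_force_max_matching(t1, t2, delta):
    """Maximum bipartite matching size via Hopcroft-Karp."""
    t1, t2 = np.asarray(t1), np.asarray(t2)
    if t1.size == 0 or t2.size == 0:
        return 0
    feasible = np.abs(t1[:, None] - t2[None, :]) <= delta
    if not feasible.any():
        return 0
    match = maximum_bipartite_matching(csr_matrix(feasible), perm_type="column")
    return int(np.sum(match >= 0))


def brute_force_assignment(scores):
    """Best injective assignment total by exhaustive permutation search."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] > scores.shape[1]:
        scores = scores.T
    n_rows, n_cols = scores.shape
    best = 0.0
    rows = np.arange(n_rows)
    for cols in itertools.permutations(range(n_cols), n_rows):
        total = scores[rows, list(cols)].sum()
        if total > best:
            best = total
    return best
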