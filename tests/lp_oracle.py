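"""Brute-force LP oracle: vertex enumeration for small flux polytopes.

For {v : S v = 0, lb <= v <= ub} with finite bounds the optimum of a linear
objective is attained at a vertex, where (n - rank(S)) variables sit at a
bound. Enumerating all basic-variable subsets and bound assignments is
exponential but exact, and independent of any LP solver.
"""
import itertools

import numpy as np


def brute_force_max(S, lb, ub, c, tol=1e-9):
    """Maximum of c·v over {S v = 0, lb <= v <= ub}, or None if infeasible."""
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    best = None
    for basic in itertools.combinations(range(n), r):
        S_b = S[:, basic]
        if np.linalg.matrix_rank(S_b) < r:
            continue
        nonbasic = [j for j in range(n) if j not in basic]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in nonbasic]):
            v = np.zeros(n)
            v[nonbasic] = bounds_choice
            rhs = -S[:, nonbasic] @ v[nonbasic]
            sol, *_ = np.linalg.lstsq(S_b, rhs, rcond=None)
            v[list(basic)] = sol
            if np.max(np.abs(S @ v)) > tol * (1 + np.abs(v).max()):
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best


def random_bounded_network(rng, n_reactions=None, n_metabolites=None):
    """A random small stoichiometric system with finite bounds straddling 0."""
    n = int(rng.integers(4, 9)) if n_reactions is None else n_reactions
    m = int(rng.integers(2, max(3, n - 1))) if n_metabolites is None else n_metabolites
    S = np.zeros((m, n))
    while np.any(np.all(S == 0, axis=0)):
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        S[rng.random(S.shape) < 0.4] = 0.0
    lb = -rng.uniform(0.5, 2.0, size=n)
    ub = rng.uniform(0.5, 2.0, size=n)
    c = rng.normal(size=n)
    return S, lb, ub, c
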