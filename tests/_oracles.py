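"""Independent brute-force oracles used only by the tests.

The pFBA oracle enumerates candidate vertices of the flux polytope
{S·v = 0, lb ≤ v ≤ ub} extended with the |v| breakpoint hyperplanes
v_i = 0.  The minimum of the piecewise-linear convex total flux Σ|v| over a
bounded polytope is attained at a vertex of that hyperplane arrangement,
and every such vertex is the unique solution of S·v = 0 plus a set of
active constraints v_i ∈ {lb_i, 0, ub_i} completing the rank.  Exhaustive
enumeration of those active sets is exponential but exact, and entirely
independent of the LP solver path it audits.
"""

import itertools

import numpy as np

from symbiofba import stoichiometric_matrix


def pfba_vertex_oracle(model, fixed_demands=None, tol=1e-9):
    """Exact min Σ|v| over the flux polytope by active-set enumeration.

    Returns (best_total_flux, best_v) or raises if the polytope is empty.
    Only intended for models with at most ~8 reactions.
    """
    fixed_demands = fixed_demands or {}
    smat = stoichiometric_matrix(model)
    S = smat.matrix.toarray()
    n = S.shape[1]
    lb = np.empty(n)
    ub = np.empty(n)
    for j, rid in enumerate(smat.rxn_ids):
        rx = model.reactions[rid]
        lb[j], ub[j] = rx.lb, rx.ub
        if rid in fixed_demands:
            lb[j] = ub[j] = fixed_demands[rid]

    r0 = np.linalg.matrix_rank(S)
    k = n - r0
    best = None
    best_v = None
    for subset in itertools.combinations(range(n), k):
        value_choices = []
        for i in subset:
            vals = {lb[i], ub[i]}
            if lb[i] <= 0.0 <= ub[i]:
                vals.add(0.0)
            value_choices.append(sorted(vals))
        for choice in itertools.product(*value_choices):
            E = np.zeros((k, n))
            for row, i in enumerate(subset):
                E[row, i] = 1.0
            A = np.vstack([S, E])
            b = np.concatenate([np.zeros(S.shape[0]), np.asarray(choice)])
            if np.linalg.matrix_rank(A) < n:
                continue
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) > 1e-8:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            total = float(np.sum(np.abs(v)))
            if best is None or total < best - 1e-12:
                best = total
                best_v = v
    if best is None:
        raise AssertionError("vertex oracle found no feasible vertex")
    return best, dict(zip(smat.rxn_ids, best_v))
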