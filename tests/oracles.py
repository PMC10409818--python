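"""Independent reference implementations used to freeze expected values.

These deliberately avoid the package's own code paths: truth-table
enumeration for GPR semantics, plain scipy linprog feasibility checks for the
idle-enzyme minimum, and active-set enumeration for bounded least squares.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog


def gpr_truth_table_equal(expression: str, complexes, genes) -> bool:
    """Check that a DNF (list of gene sets) reproduces the expression's truth
    table over all assignments of the given genes."""
    genes = sorted(genes)
    for bits in itertools.product([False, True], repeat=len(genes)):
        env = dict(zip(genes, bits))
        expected = eval(expression, {"__builtins__": {}}, env)  # noqa: S307 - controlled tokens
        got = any(all(env[g] for g in cplx) for cplx in complexes)
        if bool(expected) != bool(got):
            return False
    return True


def _dense_matrices(network):
    met_ids = [m for m, _ in network.metabolites]
    idx = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(network.reactions)))
    for j, r in enumerate(network.reactions):
        for m, c in r.stoichiometry.items():
            S[idx[m], j] = c
    lb = np.array([r.lower_bound for r in network.reactions])
    ub = np.array([r.upper_bound for r in network.reactions])
    return S, lb, ub


def activity_pattern_feasible(network, enzyme_reactions, active_subset, threshold):
    """LP feasibility of forcing every enzyme in the subset to be active."""
    S, lb, ub = _dense_matrices(network)
    rxn_idx = {r.id: j for j, r in enumerate(network.reactions)}
    n = len(network.reactions)
    A_ub, b_ub = [], []
    for e in active_subset:
        row = np.zeros(n)
        for rid in enzyme_reactions[e]:
            row[rxn_idx[rid]] = -1.0
        A_ub.append(row)
        b_ub.append(-threshold)
    res = linprog(
        np.zeros(n),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    return res.status == 0


def brute_force_min_idle(network, enzyme_reactions, threshold=1e-6) -> int:
    """Minimum idle count by exhaustive enumeration over enzyme subsets."""
    enzymes = sorted(enzyme_reactions)
    best_active = 0
    for size in range(len(enzymes), -1, -1):
        if size <= best_active:
            break
        for subset in itertools.combinations(enzymes, size):
            if activity_pattern_feasible(network, enzyme_reactions, subset, threshold):
                best_active = size
                break
    return len(enzymes) - best_active


def min_total_flux_at_pattern(network, enzyme_reactions, active_subset, threshold):
    """LP oracle: minimal total flux supporting a fixed activity pattern."""
    S, lb, ub = _dense_matrices(network)
    rxn_idx = {r.id: j for j, r in enumerate(network.reactions)}
    n = len(network.reactions)
    A_ub, b_ub = [], []
    for e in active_subset:
        row = np.zeros(n)
        for rid in enzyme_reactions[e]:
            row[rxn_idx[rid]] = -1.0
        A_ub.append(row)
        b_ub.append(-threshold)
    res = linprog(
        np.ones(n),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    assert res.status == 0
    return float(res.fun)


def bounded_lsq_oracle(E, v, eps):
    """Global optimum of min ||E k - v||^2 s.t. k >= eps by active-set
    enumeration (assumes full-rank free subsystems)."""
    E = np.asarray(E, dtype=float)
    v = np.asarray(v, dtype=float)
    n = E.shape[1]
    best = None
    for fixed in itertools.chain.from_iterable(
        itertools.combinations(range(n), r) for r in range(n + 1)
    ):
        fixed = set(fixed)
        free = [i for i in range(n) if i not in fixed]
        k = np.full(n, eps)
        resid_target = v - E[:, sorted(fixed)] @ np.full(len(fixed), eps)
        if free:
            sol, *_ = np.linalg.lstsq(E[:, free], resid_target, rcond=None)
            if np.any(sol < eps - 1e-9):
                continue
            k[free] = sol
        ssr = float(np.sum((E @ k - v) ** 2))
        if best is None or ssr < best[0] - 1e-15:
            best = (ssr, k)
    return best
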