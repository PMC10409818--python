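"""Thin LP/MILP layer over scipy's HiGHS interface.

All flux problems in the package reduce to

    optimize  c @ v
    s.t.      S @ v = 0
              lb <= v <= ub
              (optional extra linear rows)

Networks are small enough that dense construction per solve is fine; sparse
matrices are used for the stoichiometry itself.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .errors import InfeasibleModelError, SolverError


def stoichiometry_matrix(reactions: Sequence, met_ids: Sequence[str]) -> sp.csr_matrix:
    """Sparse metabolite x reaction matrix from Reaction-like objects."""
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(reactions):
        for met, coef in rxn.stoichiometry.items():
            rows.append(met_index[met])
            cols.append(j)
            data.append(float(coef))
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(reactions))
    )


@dataclass
class OptResult:
    fluxes: dict[str, float]
    objective_value: float
    raw: np.ndarray


def _bound_arrays(reactions) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in reactions], dtype=float)
    ub = np.array([r.upper_bound for r in reactions], dtype=float)
    return lb, ub


def solve_lp(
    reactions: Sequence,
    met_ids: Sequence[str],
    objective: Mapping[str, float],
    sense: str = "max",
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
    extra_rows: Sequence[tuple[Mapping[str, float], float, float]] = (),
    ub_cap: float | None = None,
) -> OptResult:
    """Solve an FBA-style LP over a reaction list.

    ``objective`` maps reaction ids to coefficients; ``sense`` is ``"max"`` or
    ``"min"``. ``bound_overrides`` temporarily replaces (lb, ub) per reaction;
    ``extra_rows`` adds (coefficient map, lower, upper) inequality rows;
    ``ub_cap`` caps all upper bounds.
    """
    rxn_index = {r.id: j for j, r in enumerate(reactions)}
    S = stoichiometry_matrix(reactions, met_ids)
    lb, ub = _bound_arrays(reactions)
    if ub_cap is not None:
        ub = np.minimum(ub, ub_cap)
    if bound_overrides:
        for rid, (lo, hi) in bound_overrides.items():
            j = rxn_index[rid]
            lb[j], ub[j] = lo, hi
    c = np.zeros(len(reactions))
    for rid, coef in objective.items():
        c[rxn_index[rid]] += coef
    A_ub, b_ub = [], []
    for coefs, row_lb, row_ub in extra_rows:
        row = np.zeros(len(reactions))
        for rid, coef in coefs.items():
            row[rxn_index[rid]] = coef
        if np.isfinite(row_ub):
            A_ub.append(row)
            b_ub.append(row_ub)
        if np.isfinite(row_lb):
            A_ub.append(-row)
            b_ub.append(-row_lb)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleModelError(f"LP infeasible: {res.message}")
    if not res.success:
        raise SolverError(f"LP failed (status {res.status}): {res.message}")
    fluxes = {r.id: float(res.x[j]) for j, r in enumerate(reactions)}
    return OptResult(fluxes=fluxes, objective_value=float(c @ res.x), raw=res.x)


def solve_milp(
    c: np.ndarray,
    integrality: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    constraints: list[LinearConstraint],
    mip_rel_gap: float = 0.0,
) -> np.ndarray:
    """Minimize c @ x subject to linear constraints; returns the solution."""
    res = milp(
        c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"mip_rel_gap": mip_rel_gap},
    )
    if res.status == 2:
        raise InfeasibleModelError(f"MILP infeasible: {res.message}")
    if not res.success:
        raise SolverError(f"MILP failed (status {res.status}): {res.message}")
    return res.x
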