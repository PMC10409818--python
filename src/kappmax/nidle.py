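"""Idle-enzyme-minimizing flux estimation (MILP) plus a pFBA baseline.

Given a growth- and uptake-constrained irreversible network and the set of
enzymes with measured abundance, stage 1 finds a steady-state flux maximizing
the number of measured enzymes whose catalyzable reactions carry flux at or
above an activity threshold; stage 2 fixes that count and picks the
flux-minimal (parsimonious) distribution among the optima.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint

from . import _opt
from .errors import InfeasibleModelError
from .model_io import IrreversibleNetwork, IsoenzymeSet

#: Default flux (mmol/gDW/h) above which an enzyme counts as active.
DEFAULT_ACTIVITY_THRESHOLD = 1e-6
#: Default cap on any single irreversible flux inside the MILP.
DEFAULT_BIG_M = 1000.0


def enzyme_key(complex_genes: frozenset[str]) -> str:
    """Stable textual id for an enzyme (single gene or complex)."""
    return ":".join(sorted(complex_genes))


def measured_enzyme_map(
    iso_sets_irrev: dict[str, IsoenzymeSet],
    measured_proteins: set[str],
) -> dict[str, set[str]]:
    """Map each fully measured enzyme to the reactions it can catalyze.

    An enzyme is one complex from a reaction's isoenzyme set; a complex counts
    as measured only if every subunit is measured. Both directions of a split
    reversible pair contribute, because ``iso_sets_irrev`` is keyed by
    irreversible reaction ids.
    """
    out: dict[str, set[str]] = {}
    for rid, iso in iso_sets_irrev.items():
        for cplx in iso.complexes:
            if cplx and cplx <= measured_proteins:
                out.setdefault(enzyme_key(cplx), set()).add(rid)
    return out


@dataclass
class NidleSolution:
    flux: dict[str, float]
    active: dict[str, int]
    idle_count: int
    objective_value: float
    total_flux: float


def count_idle_enzymes(
    flux: dict[str, float],
    measured_enzymes: dict[str, set[str]],
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> int:
    """Number of measured enzymes whose catalyzable-reaction flux sum is below
    the activity threshold (small numeric slack applied)."""
    idle = 0
    for _, rxns in sorted(measured_enzymes.items()):
        total = sum(flux.get(r, 0.0) for r in rxns)
        if total < activity_threshold * (1.0 - 1e-3):
            idle += 1
    return idle


def _check_steady_state(network: IrreversibleNetwork, x: np.ndarray, tol: float = 1e-6):
    S = _opt.stoichiometry_matrix(network.reactions, network.metabolite_ids())
    residual = np.abs(S @ x).max() if S.shape[0] else 0.0
    if residual > tol:
        raise InfeasibleModelError(
            f"steady-state residual {residual:.2e} exceeds tolerance {tol:.0e}"
        )


def solve_nidle(
    irrev_network: IrreversibleNetwork,
    measured_enzymes: dict[str, set[str]],
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    big_M: float = DEFAULT_BIG_M,
    parsimonious: bool = True,
) -> NidleSolution:
    """Two-stage MILP: maximize active measured enzymes, then minimize total flux.

    Variables are non-negative fluxes v and binary indicators y per measured
    enzyme with sum_{r in R(e)} v_r >= threshold * y_e. Stage 2 fixes sum(y) at
    its stage-1 optimum and minimizes sum(v); it can be disabled with
    ``parsimonious=False`` for compatibility with single-stage formulations.
    """
    rxns = irrev_network.reactions
    met_ids = irrev_network.metabolite_ids()
    n = len(rxns)
    enzymes = sorted(measured_enzymes)
    m = len(enzymes)
    rxn_index = {r.id: j for j, r in enumerate(rxns)}

    lb = np.zeros(n + m)
    ub = np.ones(n + m)
    for j, r in enumerate(rxns):
        if r.lower_bound < 0:
            raise ValueError("solve_nidle requires an irreversible network")
        lb[j] = r.lower_bound
        ub[j] = min(r.upper_bound, big_M)
    integrality = np.concatenate([np.zeros(n), np.ones(m)])

    S = _opt.stoichiometry_matrix(rxns, met_ids)
    S_full = sp.hstack([S, sp.csr_matrix((S.shape[0], m))], format="csr")
    constraints = [LinearConstraint(S_full, 0.0, 0.0)]
    if m:
        # activity rows are scaled by 1/threshold so the solver's absolute
        # feasibility tolerance cannot satisfy an indicator with ~zero flux
        rows, cols, data = [], [], []
        for i, e in enumerate(enzymes):
            for rid in sorted(measured_enzymes[e]):
                rows.append(i)
                cols.append(rxn_index[rid])
                data.append(1.0 / activity_threshold)
            rows.append(i)
            cols.append(n + i)
            data.append(-1.0)
        A_act = sp.csr_matrix((data, (rows, cols)), shape=(m, n + m))
        constraints.append(LinearConstraint(A_act, 0.0, np.inf))

    # stage 1: maximize number of active measured enzymes
    c1 = np.concatenate([np.zeros(n), -np.ones(m)])
    try:
        x1 = _opt.solve_milp(c1, integrality, lb, ub, constraints)
    except InfeasibleModelError as exc:
        biomass = irrev_network.biomass_reaction_id
        window = ""
        if biomass is not None:
            b = irrev_network.reaction(biomass)
            window = (
                f"; biomass '{biomass}' window [{b.lower_bound:.4g}, {b.upper_bound:.4g}]"
                " is a likely binding constraint"
            )
        raise InfeasibleModelError(f"NIDLE stage 1 infeasible{window}") from exc
    n_active = int(round(-float(c1 @ x1)))

    x = x1
    if parsimonious and m:
        sum_y = sp.csr_matrix(
            (np.ones(m), (np.zeros(m, dtype=int), np.arange(n, n + m))),
            shape=(1, n + m),
        )
        constraints2 = constraints + [LinearConstraint(sum_y, n_active, np.inf)]
        c2 = np.concatenate([np.ones(n), np.zeros(m)])
        x = _opt.solve_milp(c2, integrality, lb, ub, constraints2)

    # re-solve a pure LP at the fixed activity pattern: tighter tolerances
    # than the MIP, and it guarantees active enzymes truly meet the threshold
    y = np.round(x[n:]).astype(int) if m else np.zeros(0, dtype=int)
    res = _opt.solve_lp(
        rxns,
        met_ids,
        {r.id: 1.0 for r in rxns} if parsimonious else {},
        sense="min",
        extra_rows=[
            (
                {rid: 1.0 for rid in sorted(measured_enzymes[e])},
                activity_threshold,
                np.inf,
            )
            for e, flag in zip(enzymes, y)
            if flag
        ],
        ub_cap=big_M,
    )
    v = res.raw[: len(rxns)]
    _check_steady_state(irrev_network, v)
    flux = {r.id: max(float(v[j]), 0.0) for j, r in enumerate(rxns)}
    active = {}
    for e in enzymes:
        total = sum(flux[r] for r in measured_enzymes[e])
        active[e] = int(total >= activity_threshold * (1.0 - 1e-3))
    idle_count = m - sum(active.values())
    return NidleSolution(
        flux=flux,
        active=active,
        idle_count=idle_count,
        objective_value=float(n_active),
        total_flux=float(np.sum(v)),
    )


def solve_pfba(irrev_network: IrreversibleNetwork) -> dict[str, float]:
    """Minimize total flux subject to steady state and the current bounds."""
    res = _opt.solve_lp(
        irrev_network.reactions,
        irrev_network.metabolite_ids(),
        {r.id: 1.0 for r in irrev_network.reactions},
        sense="min",
    )
    return {rid: max(v, 0.0) for rid, v in res.fluxes.items()}


def solve_fba(network, objective_id: str | None = None) -> tuple[float, dict[str, float]]:
    """Maximize the biomass (or given) reaction flux; returns (optimum, fluxes)."""
    objective_id = objective_id or network.biomass_reaction_id
    if objective_id is None:
        raise ValueError("no objective reaction specified")
    res = _opt.solve_lp(
        network.reactions, network.metabolite_ids(), {objective_id: 1.0}, sense="max"
    )
    return res.objective_value, res.fluxes
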