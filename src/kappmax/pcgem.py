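"""Enzyme-constrained model construction and prediction.

A PcGEM augments an irreversible network with enzyme pseudometabolites:
reactions with isoenzymes are split into one arm per isoenzyme, each arm
consuming its enzyme species at 1/k_cat (in hours); enzyme species are drawn
from a shared protein pool at molecular-weight cost, and the pool exchange is
bounded by f * sigma * P_total. On top of that sit sigma fitting, the
control-coefficient k_cat correction, substitution of in vivo maximum
apparent rates, and growth / enzyme-usage prediction.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _opt
from .errors import InfeasibleModelError
from .kcat_db import KcatEntry
from .model_io import IrreversibleNetwork, IsoenzymeSet, Reaction
from .nidle import enzyme_key

SECONDS_PER_HOUR = 3600.0
POOL_MET = "prot_pool"
POOL_REACTION = "prot_pool_exchange"


def _prot_met(gene: str) -> str:
    return f"prot_{gene}"


def _draw_reaction(gene: str) -> str:
    return f"draw_prot_{gene}"


@dataclass
class PcGEM:
    model_id: str
    metabolites: list[tuple[str, str]]
    reactions: list[Reaction]
    enzymes: dict[str, float]                      # gene -> MW g/mmol
    coefficients: dict[tuple[str, str], float]     # (arm id, gene) -> 1/k_cat in h
    arm_map: dict[str, list[str]]                  # original reaction -> arm ids
    arm_complex: dict[str, frozenset[str]]         # arm id -> catalyzing complex
    arm_ec: dict[str, list[str]]                   # arm id -> EC numbers
    biomass_reaction_id: str | None
    f: float
    sigma: float
    p_total: float
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def metabolite_ids(self) -> list[str]:
        return [m for m, _ in self.metabolites]

    def reaction(self, rid: str) -> Reaction:
        if len(self._index) != len(self.reactions):
            self._index = {r.id: j for j, r in enumerate(self.reactions)}
        return self.reactions[self._index[rid]]

    @property
    def pool_bound(self) -> float:
        return self.f * self.sigma * self.p_total

    def set_sigma(self, sigma: float) -> None:
        self.sigma = sigma
        self.reaction(POOL_REACTION).upper_bound = self.pool_bound

    def set_coefficient(self, arm_id: str, gene: str, coeff_h: float) -> None:
        if not coeff_h > 0:
            raise ValueError("catalytic coefficient must be > 0")
        self.coefficients[(arm_id, gene)] = coeff_h
        self.reaction(arm_id).stoichiometry[_prot_met(gene)] = -coeff_h

    def kcat_per_s(self, arm_id: str, gene: str) -> float:
        return 1.0 / (self.coefficients[(arm_id, gene)] * SECONDS_PER_HOUR)

    def constrained_genes(self) -> list[str]:
        return sorted({g for _, g in self.coefficients})

    def copy(self) -> "PcGEM":
        return PcGEM(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            enzymes=dict(self.enzymes),
            coefficients=dict(self.coefficients),
            arm_map={k: list(v) for k, v in self.arm_map.items()},
            arm_complex=dict(self.arm_complex),
            arm_ec={k: list(v) for k, v in self.arm_ec.items()},
            biomass_reaction_id=self.biomass_reaction_id,
            f=self.f,
            sigma=self.sigma,
            p_total=self.p_total,
        )

    def net_arm_flux(self, fluxes: dict[str, float]) -> dict[str, float]:
        """Sum arm fluxes back to the underlying irreversible reactions."""
        return {
            orig: sum(fluxes.get(a, 0.0) for a in arms)
            for orig, arms in self.arm_map.items()
        }


def build_pcgem(
    irrev_network: IrreversibleNetwork,
    iso_sets: dict[str, IsoenzymeSet],
    kcat_map: dict[str, float],
    mw_map: dict[str, float],
    p_total: float,
    f: float = 1.0,
    sigma: float = 1.0,
    nutrient_uptakes: tuple[str, ...] = (),
) -> PcGEM:
    """GECKO-style augmentation of an irreversible network.

    ``kcat_map`` holds one k_cat (1/s) per reaction id; reactions without an
    entry (or without a GPR) are left unconstrained. ``mw_map`` gives
    molecular weights in g/mmol for every gene that ends up constrained.
    ``nutrient_uptakes`` are opened to 1000 mmol/gDW/h.
    """
    if not p_total > 0:
        raise ValueError("p_total must be > 0")
    reactions: list[Reaction] = []
    coefficients: dict[tuple[str, str], float] = {}
    arm_map: dict[str, list[str]] = {}
    arm_complex: dict[str, frozenset[str]] = {}
    arm_ec: dict[str, list[str]] = {}
    used_genes: set[str] = set()

    for r in irrev_network.reactions:
        if r.lower_bound < 0:
            raise ValueError("build_pcgem requires an irreversible network")
        iso = iso_sets.get(r.id)
        kcat = kcat_map.get(r.id)
        if iso is None or not iso.complexes or kcat is None or r.id == irrev_network.biomass_reaction_id:
            reactions.append(r.copy())
            arm_map[r.id] = [r.id]
            continue
        if not kcat > 0:
            raise ValueError(f"k_cat for reaction '{r.id}' must be > 0")
        coeff_h = 1.0 / (kcat * SECONDS_PER_HOUR)
        arms = []
        for idx, cplx in enumerate(iso.complexes):
            arm = r.copy()
            if len(iso.complexes) > 1:
                arm.id = f"{r.id}__iso{idx + 1}"
            for gene in sorted(cplx):
                if gene not in mw_map:
                    raise KeyError(f"missing molecular weight for enzyme '{gene}'")
                arm.stoichiometry[_prot_met(gene)] = -coeff_h
                coefficients[(arm.id, gene)] = coeff_h
                used_genes.add(gene)
            arm_complex[arm.id] = cplx
            arm_ec[arm.id] = list(r.ec_numbers)
            arms.append(arm.id)
            reactions.append(arm)
        arm_map[r.id] = arms

    metabolites = list(irrev_network.metabolites)
    for gene in sorted(used_genes):
        metabolites.append((_prot_met(gene), "enzyme"))
        reactions.append(
            Reaction(
                id=_draw_reaction(gene),
                stoichiometry={POOL_MET: -mw_map[gene], _prot_met(gene): 1.0},
                lower_bound=0.0,
                upper_bound=np.inf,
            )
        )
    metabolites.append((POOL_MET, "enzyme"))
    reactions.append(
        Reaction(
            id=POOL_REACTION,
            stoichiometry={POOL_MET: 1.0},
            lower_bound=0.0,
            upper_bound=f * sigma * p_total,
        )
    )

    model = PcGEM(
        model_id=f"{irrev_network.model_id}_pc",
        metabolites=metabolites,
        reactions=reactions,
        enzymes={g: mw_map[g] for g in sorted(used_genes)},
        coefficients=coefficients,
        arm_map=arm_map,
        arm_complex=arm_complex,
        arm_ec=arm_ec,
        biomass_reaction_id=irrev_network.biomass_reaction_id,
        f=f,
        sigma=sigma,
        p_total=p_total,
    )
    for rid in nutrient_uptakes:
        model.reaction(rid).upper_bound = 1000.0
    return model


# ---------------------------------------------------------------------------
# f factor
# ---------------------------------------------------------------------------

def compute_f_factor(
    abundance_table,
    mw_map: dict[str, float],
    model_enzyme_ids: set[str],
) -> float:
    """Mass fraction of the measured proteome covered by model enzymes.

    Uses the average abundance over conditions, restricted to proteins
    quantified in every condition and with a known molecular weight.
    """
    conditions = abundance_table.conditions()
    if not conditions:
        raise ValueError("empty abundance table")
    total = 0.0
    model_mass = 0.0
    for pid in abundance_table.proteins():
        values = [abundance_table.amol(pid, c) for c in conditions]
        if any(v is None for v in values):
            continue  # proteins with missing conditions are excluded from both sums
        if pid not in mw_map:
            continue
        mass = float(np.mean(values)) * mw_map[pid]
        total += mass
        if pid in model_enzyme_ids:
            model_mass += mass
    if total <= 0:
        raise ValueError("no completely quantified proteins with molecular weights")
    return model_mass / total


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def predict_growth(model) -> float:
    """LP maximum of the biomass flux; works on plain networks and PcGEMs."""
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    res = _opt.solve_lp(
        model.reactions,
        model.metabolite_ids(),
        {model.biomass_reaction_id: 1.0},
        sense="max",
    )
    return res.objective_value


def fit_sigma(
    pcgem: PcGEM,
    measured_growth: float,
    tol: float = 1e-4,
    max_iter: int = 60,
    lo: float = 1e-4,
) -> float:
    """Bisection on sigma until predicted growth matches the measurement.

    If the measured growth is unreachable even at sigma = 1, a warning is
    issued and 1.0 returned. The passed model is left at its original sigma.
    """
    if not measured_growth > 0:
        raise ValueError("measured growth must be > 0")
    probe = pcgem.copy()
    probe.set_sigma(1.0)
    top = predict_growth(probe)
    if top < measured_growth * (1.0 - tol):
        warnings.warn(
            f"measured growth {measured_growth:.4g} unreachable at sigma=1 "
            f"(predicted {top:.4g}); returning sigma=1",
            stacklevel=2,
        )
        return 1.0
    a, b = lo, 1.0
    sigma = 1.0
    for _ in range(max_iter):
        sigma = 0.5 * (a + b)
        probe.set_sigma(sigma)
        mu = predict_growth(probe)
        if abs(mu - measured_growth) / measured_growth <= tol:
            return sigma
        if mu > measured_growth:
            b = sigma
        else:
            a = sigma
    return sigma


@dataclass(frozen=True)
class KcatReplacement:
    gene: str
    old_kcat_per_s: float
    new_kcat_per_s: float
    growth_before: float
    growth_after: float


def correct_kcats(
    pcgem: PcGEM,
    measured_growth: float,
    kcat_entries: list[KcatEntry],
    probe_factor: float = 10.0,
    max_iter: int = 100,
) -> tuple[PcGEM, list[KcatReplacement]]:
    """Objective-control-coefficient style relaxation of over-constraining k_cats.

    Each round scores every constrained enzyme by the growth gained when its
    k_cat is probed at ``probe_factor`` times the current value, then replaces
    the top scorer's k_cat with the maximum entry value for the ECs of the
    reactions it catalyzes (across all organisms). Stops when the measured
    growth is reached, no probe helps, a replacement source is missing, or the
    iteration cap is hit.
    """
    model = pcgem.copy()
    replacements: list[KcatReplacement] = []
    ec_max: dict[str, float] = {}
    for e in kcat_entries:
        ec_max[e.ec_number] = max(ec_max.get(e.ec_number, 0.0), e.value)
    replaced: set[str] = set()

    for _ in range(max_iter):
        current = predict_growth(model)
        if current >= measured_growth * (1.0 - 1e-9):
            return model, replacements
        genes = [g for g in model.constrained_genes() if g not in replaced]
        if not genes:
            warnings.warn("no further enzymes to relax; measured growth not reached",
                          stacklevel=2)
            return model, replacements
        best_gene, best_gain = None, 0.0
        for gene in genes:
            coords = [(a, g) for (a, g) in model.coefficients if g == gene]
            saved = {c: model.coefficients[c] for c in coords}
            for a, g in coords:
                model.set_coefficient(a, g, saved[(a, g)] / probe_factor)
            gain = predict_growth(model) - current
            for a, g in coords:
                model.set_coefficient(a, g, saved[(a, g)])
            if gain > best_gain + 1e-12:
                best_gene, best_gain = gene, gain
        if best_gene is None:
            warnings.warn("no k_cat probe increases growth; correction stopped",
                          stacklevel=2)
            return model, replacements
        coords = [(a, g) for (a, g) in model.coefficients if g == best_gene]
        ecs = sorted({ec for a, _ in coords for ec in model.arm_ec.get(a, [])})
        candidates = [ec_max[ec] for ec in ecs if ec in ec_max]
        if not candidates:
            warnings.warn(
                f"no database entries for ECs of enzyme '{best_gene}'; correction stopped",
                stacklevel=2,
            )
            return model, replacements
        new_kcat = max(candidates)
        old_kcat = model.kcat_per_s(*coords[0])
        for a, g in coords:
            model.set_coefficient(a, g, 1.0 / (new_kcat * SECONDS_PER_HOUR))
        replaced.add(best_gene)
        replacements.append(
            KcatReplacement(
                gene=best_gene,
                old_kcat_per_s=old_kcat,
                new_kcat_per_s=new_kcat,
                growth_before=current,
                growth_after=predict_growth(model),
            )
        )
    warnings.warn("k_cat correction iteration cap reached", stacklevel=2)
    return model, replacements


def substitute_kappmax(
    pcgem: PcGEM, enzyme_kappmax_map: dict[str, float]
) -> PcGEM:
    """Replace catalytic coefficients with in vivo maximum apparent rates.

    Map keys are enzyme ids (gene, or colon-joined complex); values in 1/s.
    Every catalytic coefficient of a mapped enzyme becomes 1/(k * 3600) h;
    unmapped enzymes keep their current values.
    """
    for key, value in enzyme_kappmax_map.items():
        if not value > 0:
            raise ValueError(f"non-positive kapp_max for enzyme '{key}'")
    model = pcgem.copy()
    for key, value in enzyme_kappmax_map.items():
        coeff = 1.0 / (value * SECONDS_PER_HOUR)
        genes = set(key.split(":"))
        if len(genes) == 1:
            gene = next(iter(genes))
            coords = [(a, g) for (a, g) in model.coefficients if g == gene]
        else:
            coords = [
                (a, g)
                for (a, g) in model.coefficients
                if model.arm_complex.get(a) == frozenset(genes)
            ]
        for a, g in coords:
            model.set_coefficient(a, g, coeff)
    return model


@dataclass
class UsagePrediction:
    usages: dict[str, float]  # gene -> mmol/gDW
    growth_fixed: float
    pool_used: float


def predict_enzyme_usage(
    pcgem: PcGEM, observed_growth: float, growth_fraction: float = 0.99
) -> UsagePrediction:
    """Fix biomass at ``growth_fraction`` of the observation, minimize pool draw."""
    if pcgem.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    target = growth_fraction * observed_growth
    try:
        res = _opt.solve_lp(
            pcgem.reactions,
            pcgem.metabolite_ids(),
            {POOL_REACTION: 1.0},
            sense="min",
            bound_overrides={pcgem.biomass_reaction_id: (target, target)},
        )
    except InfeasibleModelError as exc:
        raise InfeasibleModelError(
            f"usage prediction infeasible at biomass {target:.4g} "
            f"(pool bound {pcgem.pool_bound:.4g}); either the growth target or "
            "the enzyme pool is too restrictive"
        ) from exc
    usages = {
        gene: max(res.fluxes.get(_draw_reaction(gene), 0.0), 0.0)
        for gene in pcgem.enzymes
    }
    return UsagePrediction(
        usages=usages,
        growth_fixed=target,
        pool_used=res.fluxes.get(POOL_REACTION, 0.0),
    )


@dataclass(frozen=True)
class UsageMetrics:
    spearman_rho: float
    p_value: float
    rmse_log10: float
    n: int


def evaluate_usage(
    predicted: dict[str, float], measured: dict[str, float], min_n: int = 3
) -> UsageMetrics:
    """Spearman rho and RMSE of log10 predicted vs measured enzyme levels.

    Enzymes missing from either side or with a non-positive value on either
    side are dropped before the log transform.
    """
    shared = sorted(
        k
        for k in set(predicted) & set(measured)
        if predicted[k] > 0 and measured[k] > 0
    )
    if len(shared) < min_n:
        raise ValueError(
            f"need >= {min_n} enzymes with positive predicted and measured values, "
            f"got {len(shared)}"
        )
    x = np.log10([predicted[k] for k in shared])
    y = np.log10([measured[k] for k in shared])
    rho, p = stats.spearmanr(x, y)
    rmse = math.sqrt(float(np.mean((x - y) ** 2)))
    return UsageMetrics(
        spearman_rho=float(rho), p_value=float(p), rmse_log10=rmse, n=len(shared)
    )
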