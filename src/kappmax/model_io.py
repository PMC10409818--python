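"""Read, curate, and transform constraint-based metabolic models.

The central structures are a plain :class:`MetabolicNetwork` (stoichiometry,
bounds, GPR strings, annotations) and its :class:`IrreversibleNetwork`
counterpart in which every reversible reaction is split into a forward and a
backward component. SBML I/O is delegated to cobrapy/libsbml; everything
downstream operates on these lightweight dataclasses.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CurationError, GEMParseError, GPRParseError

_VALID_TROPHIC_MODES = {"mixotrophic", "heterotrophic", "autotrophic"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    subsystem: str = ""
    ec_numbers: list[str] = field(default_factory=list)
    gpr: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            subsystem=self.subsystem,
            ec_numbers=list(self.ec_numbers),
            gpr=self.gpr,
        )


@dataclass
class MetabolicNetwork:
    model_id: str
    metabolites: list[tuple[str, str]]
    reactions: list[Reaction]
    genes: list[str]
    biomass_reaction_id: str | None = None

    def metabolite_ids(self) -> list[str]:
        return [m for m, _ in self.metabolites]

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(reaction_id)

    def has_reaction(self, reaction_id: str) -> bool:
        return any(r.id == reaction_id for r in self.reactions)

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            biomass_reaction_id=self.biomass_reaction_id,
        )

    def validate(self) -> None:
        met_ids = self.metabolite_ids()
        if len(set(met_ids)) != len(met_ids):
            raise ValueError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValueError("duplicate reaction ids")
        declared = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - declared
            if missing:
                raise ValueError(
                    f"reaction '{r.id}' references undeclared metabolites {sorted(missing)}"
                )
            if r.lower_bound > r.upper_bound:
                raise ValueError(f"reaction '{r.id}' has lower_bound > upper_bound")


@dataclass
class IrreversibleNetwork(MetabolicNetwork):
    #: original reaction id -> (forward id, backward id or None)
    reversible_map: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def copy(self) -> "IrreversibleNetwork":
        return IrreversibleNetwork(
            model_id=self.model_id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            biomass_reaction_id=self.biomass_reaction_id,
            reversible_map=dict(self.reversible_map),
        )

    def net_flux(self, fluxes: dict[str, float]) -> dict[str, float]:
        """Map a flux vector on split reactions back to original net values."""
        net = {}
        for orig, (fwd, bwd) in self.reversible_map.items():
            v = fluxes.get(fwd, 0.0)
            if bwd is not None:
                v -= fluxes.get(bwd, 0.0)
            net[orig] = v
        return net


@dataclass(frozen=True)
class IsoenzymeSet:
    """Disjunctive-normal-form view of a GPR: each complex is a gene-id set."""

    reaction_id: str
    complexes: tuple[frozenset[str], ...]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return frozenset(out)

    def is_complex_reaction(self) -> bool:
        """True if any catalyzing unit needs more than one gene product."""
        return any(len(c) > 1 for c in self.complexes)


@dataclass
class ConditionSpec:
    condition_id: str
    strain: str
    trophic_mode: str
    growth_rate: float
    relative_cell_volume: float = 1.0
    uptake_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trophic_mode not in _VALID_TROPHIC_MODES:
            raise ValueError(
                f"trophic_mode must be one of {sorted(_VALID_TROPHIC_MODES)}"
            )
        if not self.growth_rate > 0:
            raise ValueError("growth_rate must be > 0")
        if not self.relative_cell_volume > 0:
            raise ValueError("relative_cell_volume must be > 0")


# ---------------------------------------------------------------------------
# GPR normalization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or"}


def _tokenize_gpr(expression: str) -> list[str]:
    return _TOKEN_RE.findall(expression)


class _GprParser:
    """Recursive-descent parser producing a DNF directly.

    Grammar: expr := term ('or' term)* ; term := factor ('and' factor)* ;
    factor := GENE | '(' expr ')'. A DNF is a list of frozensets of genes.
    """

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of GPR expression")
        self.pos += 1
        return tok

    def parse(self) -> list[frozenset[str]]:
        dnf = self.parse_or()
        if self.peek() is not None:
            raise GPRParseError(f"unexpected token '{self.peek()}' in GPR")
        return dnf

    def parse_or(self) -> list[frozenset[str]]:
        dnf = self.parse_and()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            dnf = dnf + self.parse_and()
        return dnf

    def parse_and(self) -> list[frozenset[str]]:
        dnf = self.parse_factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            rhs = self.parse_factor()
            dnf = [a | b for a in dnf for b in rhs]
        return dnf

    def parse_factor(self) -> list[frozenset[str]]:
        tok = self.next()
        if tok == "(":
            inner = self.parse_or()
            if self.peek() != ")":
                raise GPRParseError("unbalanced parentheses in GPR")
            self.next()
            return inner
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GPRParseError(f"unexpected token '{tok}' in GPR")
        return [frozenset([tok])]


def normalize_gpr(gpr_expression: str, reaction_id: str = "") -> IsoenzymeSet:
    """Expand a boolean GPR into a deduplicated, sorted list of complexes."""
    tokens = _tokenize_gpr(gpr_expression or "")
    if not tokens:
        raise GPRParseError("empty GPR expression")
    dnf = _GprParser(tokens).parse()
    unique = sorted(set(dnf), key=lambda s: tuple(sorted(s)))
    return IsoenzymeSet(reaction_id=reaction_id, complexes=tuple(unique))


def isoenzyme_sets(network: MetabolicNetwork) -> dict[str, IsoenzymeSet]:
    """Per-reaction isoenzyme sets; reactions without GPR map to empty sets."""
    out = {}
    for r in network.reactions:
        if r.gpr.strip():
            out[r.id] = normalize_gpr(r.gpr, r.id)
        else:
            out[r.id] = IsoenzymeSet(reaction_id=r.id, complexes=())
    return out


def irreversible_isoenzyme_sets(
    iso_sets: dict[str, IsoenzymeSet], irrev: IrreversibleNetwork
) -> dict[str, IsoenzymeSet]:
    """Propagate original-reaction isoenzyme sets to split reaction ids."""
    out = {}
    for orig, (fwd, bwd) in irrev.reversible_map.items():
        iso = iso_sets.get(orig)
        if iso is None:
            continue
        out[fwd] = IsoenzymeSet(reaction_id=fwd, complexes=iso.complexes)
        if bwd is not None:
            out[bwd] = IsoenzymeSet(reaction_id=bwd, complexes=iso.complexes)
    return out


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------

def _prevalidate_sbml(source: str | Path) -> None:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(source))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise GEMParseError(
                f"SBML parse error at line {err.getLine()}: {err.getMessage()}"
            )
    model = doc.getModel()
    if model is None:
        raise GEMParseError("SBML document contains no model element")
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        plug = rxn.getPlugin("fbc")
        if plug is not None:
            if not plug.isSetLowerFluxBound() or not plug.isSetUpperFluxBound():
                raise GEMParseError(
                    f"reaction '{rxn.getId()}' is missing fbc flux bounds"
                )


def _ec_list(annotation_value) -> list[str]:
    if annotation_value is None:
        return []
    if isinstance(annotation_value, str):
        return [annotation_value]
    return [str(v) for v in annotation_value]


def load_gem(sbml_source: str | Path) -> MetabolicNetwork:
    """Load an SBML (L3+FBC preferred) model into a MetabolicNetwork."""
    path = Path(sbml_source)
    if not path.exists():
        raise GEMParseError(f"no such SBML file: {path}")
    _prevalidate_sbml(path)
    from cobra.io import read_sbml_model

    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:  # cobra raises CobraSBMLError subclasses
        raise GEMParseError(f"could not read SBML model: {exc}") from exc

    group_subsystem: dict[str, str] = {}
    for grp in getattr(cm, "groups", []):
        for member in grp.members:
            group_subsystem.setdefault(member.id, grp.name or grp.id)

    reactions = []
    for r in cm.reactions:
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                subsystem=r.subsystem or group_subsystem.get(r.id, ""),
                ec_numbers=_ec_list(r.annotation.get("ec-code")),
                gpr=r.gene_reaction_rule or "",
            )
        )
    biomass = None
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(cm)
        if coeffs:
            biomass = sorted(coeffs, key=lambda rx: rx.id)[0].id
    except Exception:
        biomass = None
    if biomass is None:
        for r in cm.reactions:
            if "biomass" in r.id.lower():
                biomass = r.id
                break
    network = MetabolicNetwork(
        model_id=cm.id or path.stem,
        metabolites=[(m.id, m.compartment or "") for m in cm.metabolites],
        reactions=reactions,
        genes=sorted(g.id for g in cm.genes),
        biomass_reaction_id=biomass,
    )
    network.validate()
    return network


def to_cobra(network: MetabolicNetwork):
    """Convert to a cobrapy model (used for SBML serialization)."""
    import cobra
    from cobra.core import Group

    cm = cobra.Model(network.model_id)
    mets = {
        mid: cobra.Metabolite(mid, compartment=comp or "c")
        for mid, comp in network.metabolites
    }
    cobra_rxns = []
    for r in network.reactions:
        rx = cobra.Reaction(r.id)
        rx.lower_bound = r.lower_bound
        rx.upper_bound = r.upper_bound
        cobra_rxns.append(rx)
    cm.add_reactions(cobra_rxns)
    subsystems: dict[str, list] = {}
    for r, rx in zip(network.reactions, cobra_rxns):
        rx.add_metabolites({mets[mid]: coef for mid, coef in r.stoichiometry.items()})
        if r.gpr:
            rx.gene_reaction_rule = r.gpr
        if r.ec_numbers:
            rx.annotation["ec-code"] = list(r.ec_numbers)
        if r.subsystem:
            rx.subsystem = r.subsystem
            subsystems.setdefault(r.subsystem, []).append(rx)
    for i, (name, members) in enumerate(sorted(subsystems.items())):
        grp = Group(f"group_{i}", name=name, members=members, kind="partonomy")
        cm.add_groups([grp])
    if network.biomass_reaction_id and any(
        r.id == network.biomass_reaction_id for r in network.reactions
    ):
        cm.objective = network.biomass_reaction_id
    return cm


def save_gem(network: MetabolicNetwork, path: str | Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(network), str(path))


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurationRule:
    reaction_id: str
    stoichiometry: dict[str, float] | None = None
    gpr: str | None = None
    lower_bound: float | None = None
    upper_bound: float | None = None


#: Default rule set: replace the catalase formula with 2 h2o2[c] -> 2 h2o[c] + o2[c].
DEFAULT_CURATION_RULES = (
    CurationRule(
        reaction_id="CAT",
        stoichiometry={"h2o2[c]": -2.0, "h2o[c]": 2.0, "o2[c]": 1.0},
    ),
)

_COMPARTMENT_SUFFIX_RE = re.compile(r"\[(\w+)\]$")


def apply_curation(
    network: MetabolicNetwork, curation_rules: list[CurationRule] | tuple
) -> MetabolicNetwork:
    """Apply declarative reaction replacements; all other reactions untouched."""
    present = {r.id for r in network.reactions}
    missing = [rule.reaction_id for rule in curation_rules if rule.reaction_id not in present]
    if missing:
        raise CurationError(
            f"curation rules reference absent reactions: {sorted(missing)}"
        )
    out = network.copy()
    declared = set(out.metabolite_ids())
    for rule in curation_rules:
        rxn = out.reaction(rule.reaction_id)
        if rule.stoichiometry is not None:
            rxn.stoichiometry = dict(rule.stoichiometry)
            for mid in rule.stoichiometry:
                if mid not in declared:
                    m = _COMPARTMENT_SUFFIX_RE.search(mid)
                    out.metabolites.append((mid, m.group(1) if m else ""))
                    declared.add(mid)
        if rule.gpr is not None:
            rxn.gpr = rule.gpr
        if rule.lower_bound is not None:
            rxn.lower_bound = rule.lower_bound
        if rule.upper_bound is not None:
            rxn.upper_bound = rule.upper_bound
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Reversible splitting
# ---------------------------------------------------------------------------

def split_reversible(network: MetabolicNetwork) -> IrreversibleNetwork:
    """Split every reaction with a negative lower bound into _f/_b components.

    Forward bounds become (0, original upper); backward bounds become
    (0, -original lower) with negated stoichiometry. Flux-cone equivalent to
    the original network.
    """
    reactions: list[Reaction] = []
    rev_map: dict[str, tuple[str, str | None]] = {}
    for r in network.reactions:
        if r.lower_bound < 0:
            fwd = r.copy()
            fwd.id = f"{r.id}_f"
            fwd.lower_bound = 0.0
            fwd.upper_bound = max(r.upper_bound, 0.0)
            bwd = r.copy()
            bwd.id = f"{r.id}_b"
            bwd.stoichiometry = {m: -c for m, c in r.stoichiometry.items()}
            bwd.lower_bound = 0.0
            bwd.upper_bound = -r.lower_bound
            reactions.extend([fwd, bwd])
            rev_map[r.id] = (fwd.id, bwd.id)
        else:
            reactions.append(r.copy())
            rev_map[r.id] = (r.id, None)
    biomass = network.biomass_reaction_id
    if biomass is not None and biomass in rev_map:
        biomass = rev_map[biomass][0]
    out = IrreversibleNetwork(
        model_id=network.model_id,
        metabolites=list(network.metabolites),
        reactions=reactions,
        genes=list(network.genes),
        biomass_reaction_id=biomass,
        reversible_map=rev_map,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Acetate-uptake regression and condition bounds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcetateBound:
    prediction: float
    standard_error: float
    upper_bound: float
    slope: float
    intercept: float


def fit_acetate_bound(
    growth_uptake_pairs,
    target_growth: float,
    extrapolation_factor: float = 2.0,
) -> AcetateBound:
    """OLS of uptake on growth; returns prediction + SE of the mean response.

    ``growth_uptake_pairs`` is an iterable of (growth_rate, uptake_rate). The
    returned ``upper_bound`` is prediction + SE at ``target_growth``.
    """
    pairs = [(float(x), float(y)) for x, y in growth_uptake_pairs]
    if len(pairs) < 3:
        raise ValueError("need at least 3 (growth, uptake) pairs")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in growth rates")
    span = x.max() - x.min()
    half_extra = (extrapolation_factor - 1.0) * span / 2.0
    if not (x.min() - half_extra <= target_growth <= x.max() + half_extra):
        raise ValueError(
            f"target growth {target_growth} outside allowed extrapolation range "
            f"[{x.min() - half_extra}, {x.max() + half_extra}]"
        )
    n = len(x)
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    fitted = intercept + slope * x
    sse = float(np.sum((y - fitted) ** 2))
    pred = intercept + slope * target_growth
    if n > 2:
        s2 = sse / (n - 2)
        se = math.sqrt(s2 * (1.0 / n + (target_growth - xbar) ** 2 / sxx))
    else:  # unreachable given the n >= 3 guard; kept for clarity
        se = 0.0
    return AcetateBound(
        prediction=pred,
        standard_error=se,
        upper_bound=pred + se,
        slope=slope,
        intercept=intercept,
    )


def apply_condition_bounds(
    irrev_network: IrreversibleNetwork,
    condition: ConditionSpec,
    acetate_policy: str = "none",
    *,
    acetate_reaction_id: str | None = None,
    growth_uptake_pairs=None,
    max_measured_uptake: float | None = None,
    growth_tol: float = 0.01,
) -> IrreversibleNetwork:
    """Constrain an irreversible network to one experimental condition.

    The biomass flux is windowed to [mu(1-tol), mu(1+tol)]; uptake overrides
    replace upper bounds; the acetate bound follows the selected policy.
    """
    if acetate_policy not in {"regression", "fixed_max", "none"}:
        raise ValueError(f"unknown acetate_policy '{acetate_policy}'")
    out = irrev_network.copy()
    for rid, ub in condition.uptake_overrides.items():
        if not out.has_reaction(rid):
            raise KeyError(f"uptake override for absent reaction '{rid}'")
        rxn = out.reaction(rid)
        rxn.upper_bound = float(ub)
        rxn.lower_bound = min(rxn.lower_bound, rxn.upper_bound)
    if acetate_policy != "none":
        if acetate_reaction_id is None:
            raise ValueError("acetate_reaction_id required for this policy")
        if not out.has_reaction(acetate_reaction_id):
            raise KeyError(f"acetate reaction '{acetate_reaction_id}' not in model")
        rxn = out.reaction(acetate_reaction_id)
        if acetate_policy == "regression":
            if growth_uptake_pairs is None:
                raise ValueError("growth_uptake_pairs required for regression policy")
            rxn.upper_bound = fit_acetate_bound(
                growth_uptake_pairs, condition.growth_rate
            ).upper_bound
        else:
            if max_measured_uptake is None:
                raise ValueError("max_measured_uptake required for fixed_max policy")
            rxn.upper_bound = float(max_measured_uptake)
        rxn.lower_bound = min(rxn.lower_bound, rxn.upper_bound)
    if out.biomass_reaction_id is None:
        raise ValueError("network has no biomass reaction to constrain")
    biomass = out.reaction(out.biomass_reaction_id)
    mu = condition.growth_rate
    biomass.lower_bound = mu * (1.0 - growth_tol)
    biomass.upper_bound = mu * (1.0 + growth_tol)
    return out


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def read_growth_uptake_pairs(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return list(zip(df["growth_rate"].astype(float), df["uptake_rate"].astype(float)))


def read_condition_table(path: str | Path) -> list[ConditionSpec]:
    df = pd.read_csv(path, sep="\t", comment="#")
    conditions = []
    for _, row in df.iterrows():
        overrides = {}
        raw = row.get("uptake_overrides", "")
        if isinstance(raw, str) and raw.strip():
            for part in raw.split(";"):
                rid, _, val = part.partition("=")
                overrides[rid.strip()] = float(val)
        conditions.append(
            ConditionSpec(
                condition_id=str(row["condition_id"]),
                strain=str(row.get("strain", "")),
                trophic_mode=str(row["trophic_mode"]),
                growth_rate=float(row["growth_rate"]),
                relative_cell_volume=float(row.get("relative_cell_volume", 1.0)),
                uptake_overrides=overrides,
            )
        )
    return conditions


def write_condition_table(conditions: list[ConditionSpec], path: str | Path) -> None:
    rows = []
    for c in conditions:
        rows.append(
            {
                "condition_id": c.condition_id,
                "strain": c.strain,
                "trophic_mode": c.trophic_mode,
                "growth_rate": c.growth_rate,
                "relative_cell_volume": c.relative_cell_volume,
                "uptake_overrides": ";".join(
                    f"{k}={v}" for k, v in sorted(c.uptake_overrides.items())
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
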