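"""Toy networks with ground-truth kinetics and emulated proteomics data.

Everything the pipeline consumes (SBML model, per-replicate abundance TSVs,
condition metadata, turnover-number snapshot) can be generated here with a
known ground truth, fully determined by the generation parameters and a seed.
Noiseless datasets satisfy E = v / (saturation * k_true * 3600) in mmol/gDW
with k_true in 1/s, so every estimation stage can be checked for exact
recovery.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kcat_db import KcatEntry
from .model_io import (
    ConditionSpec,
    IrreversibleNetwork,
    IsoenzymeSet,
    MetabolicNetwork,
    Reaction,
    apply_condition_bounds,
    irreversible_isoenzyme_sets,
    isoenzyme_sets,
    split_reversible,
    write_condition_table,
)
from .nidle import solve_pfba
from .proteomics import AbundanceEntry, RawAbundanceSample, invert_abundance_units

SECONDS_PER_HOUR = 3600.0
_SUBSYSTEMS = ("Glycolysis", "Lipid", "Transport, mitochondrial")


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def generate_toy_network(
    n_linear: int,
    n_branches: int = 0,
    n_isoenzyme_reactions: int = 0,
    n_complex_reactions: int = 0,
    seed: int = 0,
) -> tuple[MetabolicNetwork, dict[str, IsoenzymeSet]]:
    """Deterministic source -> ... -> biomass toy network.

    The backbone is a linear chain of ``n_linear`` single-enzyme reactions
    (the first one reversible); ``n_branches`` >= 2 adds alternative routes
    (one direct reaction vs two-reaction detours) between two backbone nodes;
    isoenzyme steps carry a two-gene OR rule, complex steps a two-gene AND
    rule. The terminal metabolite feeds a gene-free biomass reaction.
    """
    if n_linear < 1:
        raise ValueError("need n_linear >= 1 to connect source and biomass")
    if min(n_branches, n_isoenzyme_reactions, n_complex_reactions) < 0:
        raise ValueError("all size arguments must be >= 0")
    if n_branches == 1:
        raise ValueError("branching needs >= 2 alternative routes (or 0)")

    metabolites: list[tuple[str, str]] = [("m0", "c")]
    reactions: list[Reaction] = [
        Reaction("EX_src", {"m0": 1.0}, 0.0, 1000.0, subsystem="Exchange")
    ]
    ec_counter = 0

    def next_ec() -> str:
        nonlocal ec_counter
        ec_counter += 1
        return f"1.1.1.{ec_counter}"

    def subsystem() -> str:
        return _SUBSYSTEMS[ec_counter % len(_SUBSYSTEMS)]

    current = "m0"
    node = 0

    def new_met() -> str:
        nonlocal node
        node += 1
        mid = f"m{node}"
        metabolites.append((mid, "c"))
        return mid

    for i in range(1, n_linear + 1):
        nxt = new_met()
        reactions.append(
            Reaction(
                f"r_lin{i}",
                {current: -1.0, nxt: 1.0},
                -1000.0 if i == 1 else 0.0,
                1000.0,
                subsystem=subsystem(),
                ec_numbers=[next_ec()],
                gpr=f"g_lin{i}",
            )
        )
        current = nxt

    if n_branches >= 2:
        target = new_met()
        reactions.append(
            Reaction(
                "r_br1",
                {current: -1.0, target: 1.0},
                0.0,
                1000.0,
                subsystem=subsystem(),
                ec_numbers=[next_ec()],
                gpr="g_br1",
            )
        )
        for b in range(2, n_branches + 1):
            mid = new_met()
            reactions.append(
                Reaction(
                    f"r_br{b}_1",
                    {current: -1.0, mid: 1.0},
                    0.0,
                    1000.0,
                    subsystem=subsystem(),
                    ec_numbers=[next_ec()],
                    gpr=f"g_br{b}_1",
                )
            )
            reactions.append(
                Reaction(
                    f"r_br{b}_2",
                    {mid: -1.0, target: 1.0},
                    0.0,
                    1000.0,
                    subsystem=subsystem(),
                    ec_numbers=[next_ec()],
                    gpr=f"g_br{b}_2",
                )
            )
        current = target

    for i in range(1, n_isoenzyme_reactions + 1):
        nxt = new_met()
        reactions.append(
            Reaction(
                f"r_iso{i}",
                {current: -1.0, nxt: 1.0},
                0.0,
                1000.0,
                subsystem=subsystem(),
                ec_numbers=[next_ec()],
                gpr=f"g_iso{i}_1 or g_iso{i}_2",
            )
        )
        current = nxt

    for i in range(1, n_complex_reactions + 1):
        nxt = new_met()
        reactions.append(
            Reaction(
                f"r_cpx{i}",
                {current: -1.0, nxt: 1.0},
                0.0,
                1000.0,
                subsystem=subsystem(),
                ec_numbers=[next_ec()],
                gpr=f"g_cpx{i}_1 and g_cpx{i}_2",
            )
        )
        current = nxt

    reactions.append(Reaction("BIOMASS", {current: -1.0}, 0.0, 1000.0))
    genes = sorted(
        {g for r in reactions if r.gpr for g in r.gpr.replace("(", " ").replace(")", " ").split() if g not in {"and", "or"}}
    )
    network = MetabolicNetwork(
        model_id=f"toy_{n_linear}_{n_branches}_{n_isoenzyme_reactions}_{n_complex_reactions}",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_reaction_id="BIOMASS",
    )
    network.validate()
    return network, isoenzyme_sets(network)


# ---------------------------------------------------------------------------
# Kinetics and conditions
# ---------------------------------------------------------------------------

@dataclass
class ToyKinetics:
    k_true: dict[str, float]       # gene -> 1/s
    mw: dict[str, float]           # gene -> g/mmol
    saturation: dict[str, float]   # condition -> (0, 1]
    conditions: list[ConditionSpec]

    def __post_init__(self):
        for g, k in self.k_true.items():
            if not k > 0:
                raise ValueError(f"k_true for '{g}' must be > 0")
        for c, s in self.saturation.items():
            if not 0 < s <= 1:
                raise ValueError(f"saturation for '{c}' must be in (0, 1]")


def make_kinetics(
    network: MetabolicNetwork,
    n_conditions: int = 3,
    seed: int = 0,
    k_log10_range: tuple[float, float] = (0.0, 2.0),
    mw_range: tuple[float, float] = (20.0, 60.0),
    mu_range: tuple[float, float] = (0.05, 0.25),
    saturation_range: tuple[float, float] = (0.3, 1.0),
    full_saturation: bool = False,
) -> ToyKinetics:
    """Sample ground-truth kinetics and condition specs for a toy network.

    The first condition always has saturation 1 so that the max over
    conditions recovers k_true; ``full_saturation`` forces saturation 1
    everywhere (the noiseless-recovery setting).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(network.genes)
    k_true = {g: float(10 ** rng.uniform(*k_log10_range)) for g in genes}
    mw = {g: float(rng.uniform(*mw_range)) for g in genes}
    conditions = []
    saturation = {}
    for j in range(n_conditions):
        cid = f"c{j + 1}"
        conditions.append(
            ConditionSpec(
                condition_id=cid,
                strain="toy",
                trophic_mode="mixotrophic",
                growth_rate=float(rng.uniform(*mu_range)),
                relative_cell_volume=1.0 if j == 0 else float(rng.uniform(0.8, 1.2)),
            )
        )
        if full_saturation or j == 0:
            saturation[cid] = 1.0
        else:
            saturation[cid] = float(rng.uniform(*saturation_range))
    return ToyKinetics(k_true=k_true, mw=mw, saturation=saturation, conditions=conditions)


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    network: MetabolicNetwork
    irrev: IrreversibleNetwork
    iso_sets: dict[str, IsoenzymeSet]
    kinetics: ToyKinetics
    conditions: list[ConditionSpec]
    samples: list[RawAbundanceSample]
    truth_flux_irrev: dict[str, dict[str, float]]     # condition -> irrev rxn -> v
    truth_load: dict[str, dict[str, float]]           # condition -> orig rxn -> |v|
    truth_abundance: dict[tuple[str, str], float]     # (gene, condition) -> mmol/gDW
    truth_kapp: dict[tuple[str, str], float]          # (gene, condition) -> 1/s
    background_proteins: list[str] = field(default_factory=list)

    def condition(self, condition_id: str) -> ConditionSpec:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)


def simulate_dataset(
    network: MetabolicNetwork,
    kinetics: ToyKinetics,
    noise_cv: float = 0.0,
    ambiguity_fraction: float = 0.0,
    missing_replicate_prob: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    n_background_proteins: int = 0,
) -> SyntheticDataset:
    """Emulate per-replicate absolute proteomics for every condition.

    Per condition the ground-truth flux is the parsimonious distribution at
    the specified growth rate; enzyme abundances follow
    E = load / (saturation * k_true * 3600) with the load split over expressed
    isoenzymes by per-(reaction, condition) Dirichlet weights. Abundances are
    converted to amol/cell, replicated with mean-preserving lognormal noise of
    the given CV, partially merged into ambiguous shared-peptide entries, and
    replicates are dropped at the given probability (always keeping two).
    """
    rng = np.random.default_rng(seed)
    iso_sets = isoenzyme_sets(network)
    irrev = split_reversible(network)
    truth_flux_irrev: dict[str, dict[str, float]] = {}
    truth_load: dict[str, dict[str, float]] = {}
    truth_abundance: dict[tuple[str, str], float] = {}
    truth_kapp: dict[tuple[str, str], float] = {}

    for cond in kinetics.conditions:
        bounded = apply_condition_bounds(irrev, cond, growth_tol=0.0)
        flux = solve_pfba(bounded)
        truth_flux_irrev[cond.condition_id] = flux
        loads = {}
        sat = kinetics.saturation[cond.condition_id]
        for orig, (fwd, bwd) in irrev.reversible_map.items():
            load = flux.get(fwd, 0.0) + (flux.get(bwd, 0.0) if bwd else 0.0)
            loads[orig] = load
        truth_load[cond.condition_id] = loads
        for rid in sorted(loads):
            iso = iso_sets.get(rid)
            load = loads[rid]
            if iso is None or not iso.complexes or load <= 0:
                continue
            complexes = list(iso.complexes)
            if len(complexes) == 1:
                weights = [1.0]
            else:
                weights = rng.dirichlet(np.ones(len(complexes)) * 5.0).tolist()
            for cplx, w in zip(complexes, weights):
                for gene in sorted(cplx):
                    contribution = w * load / (sat * kinetics.k_true[gene] * SECONDS_PER_HOUR)
                    key = (gene, cond.condition_id)
                    truth_abundance[key] = truth_abundance.get(key, 0.0) + contribution
        for gene in sorted(network.genes):
            key = (gene, cond.condition_id)
            if key in truth_abundance:
                truth_kapp[key] = sat * kinetics.k_true[gene]

    background = [f"bg{i + 1}" for i in range(n_background_proteins)]
    bg_amol = {b: float(10 ** rng.uniform(0.0, 2.0)) for b in background}

    sigma_ln = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    samples: list[RawAbundanceSample] = []
    for cond in kinetics.conditions:
        cid = cond.condition_id
        keep = [rng.random() >= missing_replicate_prob for _ in range(n_replicates)]
        while sum(keep) < min(2, n_replicates):
            keep[keep.index(False)] = True
        proteins = sorted(g for (g, c) in truth_abundance if c == cid)
        for rep in range(1, n_replicates + 1):
            entries = []
            for gene in proteins:
                amol = invert_abundance_units(truth_abundance[(gene, cid)], cond)
                factor = (
                    math.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln))
                    if sigma_ln > 0
                    else 1.0
                )
                entries.append(AbundanceEntry(frozenset([gene]), amol * factor))
            for b in background:
                factor = (
                    math.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln))
                    if sigma_ln > 0
                    else 1.0
                )
                entries.append(AbundanceEntry(frozenset([b]), bg_amol[b] * factor))
            if ambiguity_fraction > 0 and len(entries) >= 2:
                n_pairs = int(ambiguity_fraction * len(entries) / 2)
                if n_pairs:
                    order = rng.permutation(len(entries))
                    merged = []
                    for p in range(n_pairs):
                        ia, ib = int(order[2 * p]), int(order[2 * p + 1])
                        a, b = entries[ia], entries[ib]
                        merged.append(
                            (ib, AbundanceEntry(a.proteins | b.proteins, a.value + b.value))
                        )
                    for ib, new_entry in merged:
                        entries[ib] = new_entry
            if keep[rep - 1]:
                samples.append(
                    RawAbundanceSample(condition_id=cid, replicate=rep, entries=entries)
                )

    return SyntheticDataset(
        network=network,
        irrev=irrev,
        iso_sets=iso_sets,
        kinetics=kinetics,
        conditions=list(kinetics.conditions),
        samples=samples,
        truth_flux_irrev=truth_flux_irrev,
        truth_load=truth_load,
        truth_abundance=truth_abundance,
        truth_kapp=truth_kapp,
        background_proteins=background,
    )


# ---------------------------------------------------------------------------
# Perturbed turnover-number snapshot
# ---------------------------------------------------------------------------

def perturb_kcat_table(
    network: MetabolicNetwork,
    kinetics: ToyKinetics,
    target_median_lfd: float = -1.4,
    spread_sd: float = 0.0,
    seed: int = 0,
    organism: str = "Chlamydomonas reinhardtii",
    taxon: str = "Viridiplantae",
) -> list[KcatEntry]:
    """Reference table = truth perturbed by 10^(-target_median_lfd + noise).

    With kapp_max recovering k_true, the median log10-fold difference of
    kapp_max vs these entries is ``target_median_lfd``. Entry metadata cycles
    through four configurations so every tier of the matching cascade is
    exercised.
    """
    if spread_sd < 0:
        raise ValueError("spread_sd must be >= 0")
    rng = np.random.default_rng(seed)
    iso_sets = isoenzyme_sets(network)
    entries: list[KcatEntry] = []
    i = 0
    for r in sorted(network.reactions, key=lambda r: r.id):
        if not r.ec_numbers or not r.gpr:
            continue
        substrates = sorted(m for m, c in r.stoichiometry.items() if c < 0)
        genes = sorted(iso_sets[r.id].genes)
        for gene in genes:
            value = kinetics.k_true[gene] * 10 ** (
                -target_median_lfd + (rng.normal(0.0, spread_sd) if spread_sd > 0 else 0.0)
            )
            mode = i % 4
            i += 1
            entries.append(
                KcatEntry(
                    ec_number=r.ec_numbers[0],
                    organism=organism if mode < 2 else "Arabidopsis thaliana",
                    lineage_tags=frozenset({taxon}),
                    substrate=substrates[0] if (mode % 2 == 0 and substrates) else "unmatched_substrate",
                    value=float(value),
                )
            )
    return entries


# ---------------------------------------------------------------------------
# Fixture materialization
# ---------------------------------------------------------------------------

def write_dataset(
    dataset: SyntheticDataset,
    outdir: str | Path,
    kcat_entries: list[KcatEntry] | None = None,
) -> Path:
    """Write the SBML/TSV artifact set the pipeline consumes; returns outdir."""
    from .kcat_db import write_kcat_table
    from .model_io import save_gem
    from .proteomics import write_replicate_tsv

    outdir = Path(outdir)
    (outdir / "abundance").mkdir(parents=True, exist_ok=True)
    save_gem(dataset.network, outdir / "model.xml")
    write_condition_table(dataset.conditions, outdir / "conditions.tsv")
    for s in dataset.samples:
        write_replicate_tsv(
            s, outdir / "abundance" / f"{s.condition_id}_rep{s.replicate}.tsv"
        )
    pd.DataFrame(
        [{"gene": g, "mw_g_per_mmol": m} for g, m in sorted(dataset.kinetics.mw.items())]
    ).to_csv(outdir / "mw.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene": g, "condition": c, "kapp_true_per_s": v}
            for (g, c), v in sorted(dataset.truth_kapp.items())
        ]
    ).to_csv(outdir / "truth_kapp.tsv", sep="\t", index=False)
    if kcat_entries is not None:
        write_kcat_table(kcat_entries, outdir / "kcat_table.tsv")
    return outdir


def make_standard_fixtures(outdir: str | Path, seed: int = 0) -> Path:
    """Materialize the standard benchmark dataset (model, proteomics, k_cats)."""
    network, _ = generate_toy_network(4, 2, 1, 1, seed=seed)
    kinetics = make_kinetics(network, n_conditions=4, seed=seed)
    dataset = simulate_dataset(
        network,
        kinetics,
        noise_cv=0.1,
        ambiguity_fraction=0.1,
        missing_replicate_prob=0.1,
        n_replicates=3,
        seed=seed,
        n_background_proteins=3,
    )
    entries = perturb_kcat_table(
        network, kinetics, target_median_lfd=-1.4, spread_sd=0.5, seed=seed
    )
    return write_dataset(dataset, outdir, entries)
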