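# kappmax

Estimate **in vivo maximum apparent catalytic rates** (k_app^max) of enzymes
from absolute proteomics and physiological data using constraint-based
modeling, and re-parameterize **protein-constrained genome-scale metabolic
models** (pcGEMs) with those estimates to predict growth and enzyme usage.

The workflow:

1. **model_io** — load an SBML model (L3 + FBC2), apply declarative curation
   rules (the default set fixes the catalase stoichiometry), expand GPR rules
   to disjunctive normal form (isoenzymes vs complexes), split reversible
   reactions, and constrain the model to a measured condition (growth window,
   uptake overrides, regression-based acetate bound).
2. **proteomics** — resolve shared-peptide (non-proteotypic) protein-group
   quantifications by iterative subtraction, median-aggregate replicates
   (proteins seen in <2 replicates are dropped), and convert amol/cell to
   mmol/gDW via a 48,000 pg reference cell dry weight scaled by relative cell
   volume.
3. **nidle** — estimate condition-specific fluxes with a two-stage MILP that
   first minimizes the number of *idle* enzymes (measured but flux-less) and
   then picks the parsimonious optimum; a pFBA baseline is included.
4. **kapp** — apparent catalytic rates: flux/abundance for single-enzyme
   reactions, a bounded least-squares (or L1) decomposition over standard
   conditions for reactions with multiple expressed isoenzymes, per-reaction
   maxima with provenance, enzyme-level maxima, and clustering-prep transforms
   (pseudocount, log10, row centering, NA-safe distances, single linkage).
5. **kcat_db** — assign literature turnover numbers from a local TSV snapshot
   through a four-tier organism/taxon x substrate matching cascade (max value
   at the first nonempty tier) and quantify in vivo vs in vitro discrepancy
   (median log10-fold difference, Spearman rank correlation with exact
   permutation p-values at small n).
6. **pcgem** — GECKO-style enzyme-constrained models: per-isoenzyme reaction
   arms, enzyme pseudometabolites drawn from a pool bounded by
   f·sigma·P_total, the enzyme mass fraction f from complete-coverage
   proteins, sigma fitting by bisection, a control-coefficient heuristic that
   relaxes over-constraining k_cat values, substitution of k_app^max
   estimates, and growth / enzyme-usage prediction (biomass fixed at 0.99 of
   the observation, pool draw minimized).
7. **synthetic_data** — deterministic toy networks with ground-truth kinetics
   and emulated proteomics (lognormal noise, shared-peptide ambiguity, missing
   replicates) plus perturbed turnover-number snapshots, so every stage can be
   validated for exact recovery without external data.
8. **pipeline / cli** — end-to-end orchestration from a YAML config with
   config-hash provenance on every artifact.

## Test

```bash
python -m pytest -q
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py`, which checks the acceptance criteria: MILP
optimality against brute-force enumeration, exact parameter recovery on
noiseless synthetic data, aggregation invariants, pcGEM closed forms, the
k_cat correction heuristic, and the end-to-end head-to-head in which
k_app^max-substituted models beat models parameterized from a perturbed
turnover-number table on enzyme-usage prediction.

## CLI

```bash
# materialize the standard synthetic benchmark (SBML + TSVs + config.yaml)
kappmax make-fixtures --out fixtures --seed 1

# custom dataset
kappmax simulate --out sim --n-linear 6 --n-conditions 4 --noise-cv 0.1

# stages
kappmax estimate-kapp --config fixtures/config.yaml
kappmax build-pcgem   --config fixtures/config.yaml
kappmax predict       --config fixtures/config.yaml
kappmax run           --config fixtures/config.yaml
```

Inputs: SBML model; per-replicate abundance TSVs
(`protein_ids<TAB>amol_per_cell`, semicolon-joined ids for shared peptides)
named `<condition>_rep<k>.tsv`; condition metadata TSV; turnover-number TSV
(`ec_number, organism, lineage_tags, substrate, kcat_per_s, source_flag`);
molecular-weight TSV. Outputs: flux, abundance, k_app, k_app^max, match, and
usage TSVs plus `metrics.json`, each carrying the run's config hash.

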