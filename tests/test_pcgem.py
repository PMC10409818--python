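import math

import numpy as np
import pytest

from kappmax.errors import InfeasibleModelError
from kappmax.kcat_db import KcatEntry
from kappmax.model_io import (
    MetabolicNetwork,
    Reaction,
    irreversible_isoenzyme_sets,
    isoenzyme_sets,
    split_reversible,
)
from kappmax.nidle import solve_fba
from kappmax.pcgem import (
    POOL_REACTION,
    build_pcgem,
    compute_f_factor,
    correct_kcats,
    evaluate_usage,
    fit_sigma,
    predict_enzyme_usage,
    predict_growth,
    substitute_kappmax,
)
from kappmax.proteomics import AbundanceTable


def prepared(network):
    irrev = split_reversible(network)
    iso = irreversible_isoenzyme_sets(isoenzyme_sets(network), irrev)
    return irrev, iso


def single_pathway_pcgem(linear_pathway, k=5.0, m=40.0, f=0.4, sigma=0.7, p=0.3):
    irrev, iso = prepared(linear_pathway)
    return build_pcgem(irrev, iso, {"r1": k}, {"g1": m}, p, f, sigma)


class TestBuildPcgem:
    def test_flux_capped_by_enzyme(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway)
        mu = predict_growth(pc)
        # v <= k * e with e drawn from the pool: biomass = 2v
        e_max = pc.pool_bound / 40.0
        assert mu <= 2.0 * (5.0 * 3600.0) * e_max + 1e-9

    def test_isoenzyme_arms_sum_to_net(self):
        net = MetabolicNetwork(
            "m", [("a", "c"), ("b", "c")],
            [
                Reaction("EX", {"a": 1.0}, 0, 1000),
                Reaction("r1", {"a": -1.0, "b": 1.0}, 0, 1000, gpr="g1 or g2"),
                Reaction("BIOMASS", {"b": -1.0}, 0, 1000),
            ],
            ["g1", "g2"], "BIOMASS",
        )
        irrev, iso = prepared(net)
        pc = build_pcgem(irrev, iso, {"r1": 2.0}, {"g1": 30.0, "g2": 50.0}, 0.5)
        assert pc.arm_map["r1"] == ["r1__iso1", "r1__iso2"]
        _, flux = solve_fba(pc)
        net_flux = pc.net_arm_flux(flux)
        assert math.isclose(
            net_flux["r1"], flux["r1__iso1"] + flux["r1__iso2"], rel_tol=1e-9
        )
        assert math.isclose(net_flux["r1"], flux["BIOMASS"], rel_tol=1e-6)

    def test_complex_draws_each_subunit(self):
        net = MetabolicNetwork(
            "m", [("a", "c"), ("b", "c")],
            [
                Reaction("EX", {"a": 1.0}, 0, 1000),
                Reaction("r1", {"a": -1.0, "b": 1.0}, 0, 1000, gpr="g1 and g2"),
                Reaction("BIOMASS", {"b": -1.0}, 0, 1000),
            ],
            ["g1", "g2"], "BIOMASS",
        )
        irrev, iso = prepared(net)
        pc = build_pcgem(irrev, iso, {"r1": 2.0}, {"g1": 30.0, "g2": 50.0}, 0.5)
        stoich = pc.reaction("r1").stoichiometry
        coeff = 1.0 / (2.0 * 3600.0)
        assert stoich["prot_g1"] == pytest.approx(-coeff)
        assert stoich["prot_g2"] == pytest.approx(-coeff)

    def test_nutrient_uptakes_opened(self, linear_pathway):
        irrev, iso = prepared(linear_pathway)
        irrev.reaction("EX").upper_bound = 5.0
        pc = build_pcgem(
            irrev, iso, {"r1": 5.0}, {"g1": 40.0}, 0.3, nutrient_uptakes=("EX",)
        )
        assert pc.reaction("EX").upper_bound == 1000.0

    def test_missing_mw_raises(self, linear_pathway):
        irrev, iso = prepared(linear_pathway)
        with pytest.raises(KeyError):
            build_pcgem(irrev, iso, {"r1": 5.0}, {}, 0.3)

    def test_nonpositive_kcat_raises(self, linear_pathway):
        irrev, iso = prepared(linear_pathway)
        with pytest.raises(ValueError):
            build_pcgem(irrev, iso, {"r1": 0.0}, {"g1": 40.0}, 0.3)

    def test_unparameterized_reaction_unconstrained(self, linear_pathway):
        irrev, iso = prepared(linear_pathway)
        pc = build_pcgem(irrev, iso, {}, {"g1": 40.0}, 0.3)
        assert "prot_g1" not in pc.reaction("r1").stoichiometry
        base_opt, _ = solve_fba(split_reversible(linear_pathway))
        assert predict_growth(pc) == pytest.approx(base_opt)  # plain FBA optimum


class TestPredictGrowth:
    def test_single_pathway_closed_form(self, linear_pathway):
        k, m, f, sigma, p = 5.0, 40.0, 0.4, 0.7, 0.3
        pc = single_pathway_pcgem(linear_pathway, k, m, f, sigma, p)
        expected = 2.0 * (k * 3600.0) * f * sigma * p / m  # biomass yield b = 2
        assert math.isclose(predict_growth(pc), expected, rel_tol=1e-6)

    def test_vanishing_pool_gives_zero_growth(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway)
        pc.set_sigma(1e-12)
        assert predict_growth(pc) <= 1e-6

    def test_infinite_kcat_recovers_fba(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway, k=1e9)
        base_opt, _ = solve_fba(split_reversible(linear_pathway))
        assert math.isclose(predict_growth(pc), base_opt, rel_tol=1e-4)

    @pytest.mark.parametrize("param", ["kcat", "sigma", "f", "p_total"])
    def test_monotone_in_parameters(self, linear_pathway, param):
        base = single_pathway_pcgem(linear_pathway)
        mu0 = predict_growth(base)
        bumped = single_pathway_pcgem(
            linear_pathway,
            k=5.0 * (2 if param == "kcat" else 1),
            sigma=min(1.0, 0.7 * (1.3 if param == "sigma" else 1)),
            f=0.4 * (1.5 if param == "f" else 1),
            p=0.3 * (1.5 if param == "p_total" else 1),
        )
        assert predict_growth(bumped) >= mu0 - 1e-9


class TestFitSigma:
    def test_linear_toy_closed_form(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway, sigma=1.0)
        mu_at_one = predict_growth(pc)
        sigma_true = 0.37
        sigma = fit_sigma(pc, sigma_true * mu_at_one)
        assert math.isclose(sigma, sigma_true, abs_tol=1e-3)

    def test_measured_equals_sigma_one(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway, sigma=1.0)
        assert fit_sigma(pc, predict_growth(pc)) == pytest.approx(1.0, abs=1e-3)

    def test_unreachable_returns_one_with_warning(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway, sigma=1.0)
        with pytest.warns(UserWarning, match="unreachable"):
            assert fit_sigma(pc, 10 * predict_growth(pc)) == 1.0

    def test_invalid_measurement(self, linear_pathway):
        with pytest.raises(ValueError):
            fit_sigma(single_pathway_pcgem(linear_pathway), 0.0)

    def test_does_not_mutate_model(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway, sigma=0.7)
        fit_sigma(pc, 0.5 * predict_growth(pc))
        assert pc.sigma == 0.7


def bottleneck_model():
    """Two-step chain where gB's k_cat is 10x too small."""
    net = MetabolicNetwork(
        "bottle", [("a", "c"), ("b", "c"), ("c_", "c")],
        [
            Reaction("EX", {"a": 1.0}, 0, 1000),
            Reaction("rA", {"a": -1.0, "b": 1.0}, 0, 1000, gpr="gA",
                     ec_numbers=["1.1.1.1"]),
            Reaction("rB", {"b": -1.0, "c_": 1.0}, 0, 1000, gpr="gB",
                     ec_numbers=["2.2.2.2"]),
            Reaction("BIOMASS", {"c_": -1.0}, 0, 1000),
        ],
        ["gA", "gB"], "BIOMASS",
    )
    irrev, iso = prepared(net)
    pc = build_pcgem(
        irrev, iso, {"rA": 1000.0, "rB": 1.0}, {"gA": 40.0, "gB": 40.0}, 0.4
    )
    entries = [
        KcatEntry("2.2.2.2", "Zea mays", frozenset({"Viridiplantae"}), "b", 10.0),
        KcatEntry("1.1.1.1", "Zea mays", frozenset({"Viridiplantae"}), "a", 1000.0),
    ]
    return pc, entries


class TestCorrectKcats:
    def test_single_bottleneck_fixed_in_one_replacement(self):
        pc, entries = bottleneck_model()
        measured = 300.0
        assert predict_growth(pc) < measured
        corrected, log = correct_kcats(pc, measured, entries)
        assert len(log) == 1
        assert log[0].gene == "gB"
        assert log[0].new_kcat_per_s == 10.0
        assert predict_growth(corrected) >= measured

    def test_already_feasible_unchanged(self):
        pc, entries = bottleneck_model()
        corrected, log = correct_kcats(pc, 1.0, entries)
        assert log == []
        assert corrected.coefficients == pc.coefficients

    def test_no_entries_stops_with_warning(self):
        pc, _ = bottleneck_model()
        with pytest.warns(UserWarning):
            _, log = correct_kcats(pc, 300.0, [])
        assert log == []


class TestSubstituteKappmax:
    def test_empty_map_is_identity(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway)
        out = substitute_kappmax(pc, {})
        assert out.coefficients == pc.coefficients

    def test_all_reactions_of_enzyme_updated(self):
        net = MetabolicNetwork(
            "m", [("a", "c"), ("b", "c"), ("c_", "c")],
            [
                Reaction("EX", {"a": 1.0}, 0, 1000),
                Reaction("r1", {"a": -1.0, "b": 1.0}, 0, 1000, gpr="g1"),
                Reaction("r2", {"b": -1.0, "c_": 1.0}, 0, 1000, gpr="g1"),
                Reaction("BIOMASS", {"c_": -1.0}, 0, 1000),
            ],
            ["g1"], "BIOMASS",
        )
        irrev, iso = prepared(net)
        pc = build_pcgem(irrev, iso, {"r1": 99.0, "r2": 7.0}, {"g1": 40.0}, 0.4)
        out = substitute_kappmax(pc, {"g1": 2.0})
        assert out.coefficients[("r1", "g1")] == pytest.approx(1.0 / 7200.0)
        assert out.coefficients[("r2", "g1")] == pytest.approx(1.0 / 7200.0)

    def test_substituting_identical_values_keeps_predictions(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway, k=5.0)
        out = substitute_kappmax(pc, {"g1": 5.0})
        assert predict_growth(out) == pytest.approx(predict_growth(pc), rel=1e-9)

    def test_nonpositive_rejected(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway)
        with pytest.raises(ValueError):
            substitute_kappmax(pc, {"g1": 0.0})


class TestPredictEnzymeUsage:
    def test_usage_equals_flux_over_kcat(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway, k=5.0)
        mu = 10.0
        pred = predict_enzyme_usage(pc, mu)
        v = 0.99 * mu / 2.0  # biomass yield 2 per unit r1 flux
        assert pred.growth_fixed == pytest.approx(0.99 * mu)
        assert pred.usages["g1"] == pytest.approx(v / (5.0 * 3600.0), rel=1e-9)

    def test_doubling_kcat_halves_pool_usage(self, linear_pathway):
        mu = 10.0
        pool1 = predict_enzyme_usage(single_pathway_pcgem(linear_pathway, k=5.0), mu)
        pool2 = predict_enzyme_usage(single_pathway_pcgem(linear_pathway, k=10.0), mu)
        assert pool2.pool_used == pytest.approx(pool1.pool_used / 2.0, rel=1e-9)

    def test_pool_budget_respected(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway)
        pred = predict_enzyme_usage(pc, predict_growth(pc))
        total_mass = sum(pc.enzymes[g] * u for g, u in pred.usages.items())
        assert total_mass <= pc.pool_bound + 1e-9

    def test_infeasible_growth_raises(self, linear_pathway):
        pc = single_pathway_pcgem(linear_pathway)
        with pytest.raises(InfeasibleModelError, match="pool"):
            predict_enzyme_usage(pc, 100 * predict_growth(pc))


class TestComputeFFactor:
    def table(self, rows):
        t = AbundanceTable()
        for pid, cond, amol in rows:
            t.amol_per_cell[(pid, cond)] = amol
            t.mmol_per_gdw[(pid, cond)] = amol  # scale irrelevant for the ratio
        return t

    def test_all_model_enzymes(self):
        t = self.table([("P1", "c1", 2.0), ("P1", "c2", 4.0)])
        assert compute_f_factor(t, {"P1": 40.0}, {"P1"}) == 1.0

    def test_equal_mass_split(self):
        t = self.table(
            [("P1", "c1", 2.0), ("P1", "c2", 2.0), ("P2", "c1", 4.0), ("P2", "c2", 4.0)]
        )
        assert compute_f_factor(t, {"P1": 40.0, "P2": 20.0}, {"P1"}) == pytest.approx(0.5)

    def test_incomplete_protein_excluded(self):
        t = self.table(
            [("P1", "c1", 2.0), ("P1", "c2", 2.0), ("P2", "c1", 100.0)]  # P2 missing c2
        )
        assert compute_f_factor(t, {"P1": 40.0, "P2": 20.0}, {"P1"}) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compute_f_factor(self.table([]), {}, set())


class TestEvaluateUsage:
    def test_identity(self):
        vals = {"g1": 1.0, "g2": 2.0, "g3": 3.0}
        m = evaluate_usage(vals, vals)
        assert m.spearman_rho == pytest.approx(1.0)
        assert m.rmse_log10 == pytest.approx(0.0, abs=1e-12)

    def test_rank_reversal(self):
        pred = {"g1": 1.0, "g2": 2.0, "g3": 3.0}
        meas = {"g1": 3.0, "g2": 2.0, "g3": 1.0}
        assert evaluate_usage(pred, meas).spearman_rho == pytest.approx(-1.0)

    def test_tenfold_offset(self):
        meas = {"g1": 1.0, "g2": 2.0, "g3": 3.0}
        pred = {g: 10 * v for g, v in meas.items()}
        m = evaluate_usage(pred, meas)
        assert m.spearman_rho == pytest.approx(1.0)
        assert m.rmse_log10 == pytest.approx(1.0)

    def test_zero_values_dropped_and_min_n(self):
        pred = {"g1": 1.0, "g2": 0.0, "g3": 3.0}
        meas = {"g1": 1.0, "g2": 2.0, "g3": 3.0}
        with pytest.raises(ValueError):
            evaluate_usage(pred, meas)


def test_true_kcat_substitution_reproduces_generating_usages():
    """With saturation 1 and true rates substituted, predicted usage at the
    generating growth rate equals the generating abundances."""
    from kappmax.synthetic_data import generate_toy_network, make_kinetics, simulate_dataset

    net, iso = generate_toy_network(3, 0, 1, 0, seed=7)
    kin = make_kinetics(net, n_conditions=2, seed=7, full_saturation=True)
    ds = simulate_dataset(net, kin, seed=7)
    irrev = ds.irrev
    iso_irrev = irreversible_isoenzyme_sets(iso, irrev)
    kcat_map = {}
    for rid, s in iso_irrev.items():
        genes = sorted(s.genes)
        if genes:
            kcat_map[rid] = max(kin.k_true[g] for g in genes)
    pc = build_pcgem(irrev, iso_irrev, kcat_map, kin.mw, p_total=10.0)
    ez = {g: kin.k_true[g] for g in net.genes}
    pc = substitute_kappmax(pc, ez)
    cond = kin.conditions[0]
    pred = predict_enzyme_usage(pc, cond.growth_rate, growth_fraction=1.0)
    for gene, usage in pred.usages.items():
        truth = ds.truth_abundance.get((gene, cond.condition_id), 0.0)
        if truth > 0 and len(iso_irrev) and usage > 0:
            # single-enzyme steps must match exactly; isoenzyme steps may split
            iso_genes = {g for s in iso_irrev.values() for g in s.genes}
            multi = {
                g
                for s in iso_irrev.values()
                if len(s.complexes) > 1
                for g in s.genes
            }
            if gene not in multi:
                assert usage == pytest.approx(truth, rel=1e-6)
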