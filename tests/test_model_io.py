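import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kappmax.errors import CurationError, GEMParseError, GPRParseError
from kappmax.model_io import (
    DEFAULT_CURATION_RULES,
    ConditionSpec,
    CurationRule,
    MetabolicNetwork,
    Reaction,
    apply_condition_bounds,
    apply_curation,
    fit_acetate_bound,
    isoenzyme_sets,
    load_gem,
    normalize_gpr,
    save_gem,
    split_reversible,
)
from oracles import gpr_truth_table_equal


def two_reaction_network() -> MetabolicNetwork:
    return MetabolicNetwork(
        model_id="mini",
        metabolites=[("a", "c"), ("b", "c")],
        reactions=[
            Reaction("EX_a", {"a": 1.0}, -5.0, 10.0, subsystem="Exchange"),
            Reaction(
                "r1", {"a": -1.0, "b": 1.0}, 0.0, 20.0,
                subsystem="Core", ec_numbers=["1.2.3.4"], gpr="g1 or g2",
            ),
        ],
        genes=["g1", "g2"],
        biomass_reaction_id=None,
    )


# ---------------------------------------------------------------------------
# SBML round trip
# ---------------------------------------------------------------------------

class TestLoadGem:
    def test_roundtrip_preserves_structure(self, tmp_path):
        net = two_reaction_network()
        path = tmp_path / "mini.xml"
        save_gem(net, path)
        loaded = load_gem(path)
        assert {r.id for r in loaded.reactions} == {"EX_a", "r1"}
        r1 = loaded.reaction("r1")
        assert r1.stoichiometry == {"a": -1.0, "b": 1.0}
        assert (r1.lower_bound, r1.upper_bound) == (0.0, 20.0)
        assert normalize_gpr(r1.gpr).complexes == normalize_gpr("g1 or g2").complexes
        assert r1.ec_numbers == ["1.2.3.4"]
        assert r1.subsystem == "Core"
        ex = loaded.reaction("EX_a")
        assert (ex.lower_bound, ex.upper_bound) == (-5.0, 10.0)

    def test_reaction_without_gpr_gets_empty_isoenzyme_set(self, tmp_path):
        net = two_reaction_network()
        net.reaction("r1").gpr = ""
        path = tmp_path / "m.xml"
        save_gem(net, path)
        iso = isoenzyme_sets(load_gem(path))
        assert iso["r1"].complexes == ()

    def test_truncated_file_raises(self, tmp_path):
        net = two_reaction_network()
        path = tmp_path / "m.xml"
        save_gem(net, path)
        truncated = tmp_path / "broken.xml"
        truncated.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(GEMParseError):
            load_gem(truncated)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(GEMParseError):
            load_gem(tmp_path / "nope.xml")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

class TestApplyCuration:
    def cat_network(self) -> MetabolicNetwork:
        return MetabolicNetwork(
            model_id="cat",
            metabolites=[("h2o2[c]", "c"), ("h2o[c]", "c"), ("o2[c]", "c")],
            reactions=[
                Reaction("CAT", {"h2o2[c]": -1.0, "h2o[c]": 1.0}, 0.0, 1000.0),
                Reaction("other", {"h2o[c]": -1.0}, 0.0, 1.0),
            ],
            genes=[],
        )

    def test_default_cat_rule(self):
        out = apply_curation(self.cat_network(), DEFAULT_CURATION_RULES)
        assert out.reaction("CAT").stoichiometry == {
            "h2o2[c]": -2.0, "h2o[c]": 2.0, "o2[c]": 1.0,
        }
        # untouched reaction is identical
        assert out.reaction("other").stoichiometry == {"h2o[c]": -1.0}

    def test_empty_rule_list_is_identity(self):
        net = self.cat_network()
        out = apply_curation(net, [])
        assert [r.stoichiometry for r in out.reactions] == [
            r.stoichiometry for r in net.reactions
        ]

    def test_absent_reaction_raises_with_id(self):
        with pytest.raises(CurationError, match="NOPE"):
            apply_curation(self.cat_network(), [CurationRule("NOPE", gpr="g")])

    def test_idempotent(self):
        once = apply_curation(self.cat_network(), DEFAULT_CURATION_RULES)
        twice = apply_curation(once, DEFAULT_CURATION_RULES)
        assert once.reaction("CAT").stoichiometry == twice.reaction("CAT").stoichiometry


# ---------------------------------------------------------------------------
# GPR normalization
# ---------------------------------------------------------------------------

class TestNormalizeGpr:
    def test_simple_or(self):
        assert normalize_gpr("g1 or g2").complexes == (
            frozenset({"g1"}), frozenset({"g2"}),
        )

    def test_distribution(self):
        # oracle: truth-table enumeration
        expr = "g1 and (g2 or g3)"
        iso = normalize_gpr(expr)
        assert set(iso.complexes) == {frozenset({"g1", "g2"}), frozenset({"g1", "g3"})}
        assert gpr_truth_table_equal(expr, iso.complexes, ["g1", "g2", "g3"])

    def test_duplicate_removed(self):
        assert normalize_gpr("(g1 or g1)").complexes == (frozenset({"g1"}),)

    @pytest.mark.parametrize("bad", ["", "   ", "(g1 or g2", "g1 or", "and g1", "()"])
    def test_malformed_raises(self, bad):
        with pytest.raises(GPRParseError):
            normalize_gpr(bad)

    @st.composite
    def gpr_exprs(draw, max_depth=3):
        genes = [f"g{i}" for i in range(1, 7)]
        def expr(depth):
            if depth == 0 or draw(st.booleans()):
                return draw(st.sampled_from(genes))
            op = draw(st.sampled_from([" and ", " or "]))
            n = draw(st.integers(2, 3))
            parts = [expr(depth - 1) for _ in range(n)]
            return "(" + op.join(parts) + ")"
        return expr(max_depth)

    @settings(max_examples=200, deadline=None)
    @given(gpr_exprs())
    def test_dnf_matches_truth_table(self, expr):
        iso = normalize_gpr(expr)
        genes = sorted({t for t in expr.replace("(", " ").replace(")", " ").split()
                        if t not in {"and", "or"}})
        assert gpr_truth_table_equal(expr, iso.complexes, genes)

    def test_deterministic_ordering(self):
        a = normalize_gpr("g2 or g1 or (g3 and g1)")
        b = normalize_gpr("(g1 and g3) or g1 or g2")
        assert a.complexes == b.complexes


# ---------------------------------------------------------------------------
# Reversible splitting
# ---------------------------------------------------------------------------

class TestSplitReversible:
    def make(self, lb, ub):
        return MetabolicNetwork(
            "m", [("a", "c"), ("b", "c")],
            [Reaction("r", {"a": -1.0, "b": 1.0}, lb, ub)], [],
        )

    def test_split_bounds(self):
        irrev = split_reversible(self.make(-10, 20))
        f = irrev.reaction("r_f")
        b = irrev.reaction("r_b")
        assert (f.lower_bound, f.upper_bound) == (0.0, 20.0)
        assert (b.lower_bound, b.upper_bound) == (0.0, 10.0)
        assert b.stoichiometry == {"a": 1.0, "b": -1.0}
        assert irrev.reversible_map["r"] == ("r_f", "r_b")

    def test_forward_only_untouched(self):
        irrev = split_reversible(self.make(0, 5))
        assert [r.id for r in irrev.reactions] == ["r"]
        assert irrev.reversible_map["r"] == ("r", None)

    def test_backward_only(self):
        irrev = split_reversible(self.make(-3, 0))
        f = irrev.reaction("r_f")
        b = irrev.reaction("r_b")
        assert (f.lower_bound, f.upper_bound) == (0.0, 0.0)
        assert (b.lower_bound, b.upper_bound) == (0.0, 3.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=3))
    def test_flux_cone_equivalence(self, vals):
        """Any flux within original bounds maps to a feasible split flux with
        the same net value, and the split flux maps back."""
        net = MetabolicNetwork(
            "m", [("a", "c"), ("b", "c"), ("x", "c")],
            [
                Reaction("r1", {"a": 1.0}, -10.0, 10.0),
                Reaction("r2", {"a": -1.0, "b": 1.0}, -10.0, 10.0),
                Reaction("r3", {"b": -1.0}, -10.0, 10.0),
            ], [],
        )
        v = dict(zip(["r1", "r2", "r3"], vals))
        # project onto the steady-state line (r1 = r2 = r3 for this chain)
        common = float(np.mean(vals))
        v = {k: common for k in v}
        irrev = split_reversible(net)
        split_flux = {}
        for orig, (fwd, bwd) in irrev.reversible_map.items():
            split_flux[fwd] = max(v[orig], 0.0)
            if bwd is not None:
                split_flux[bwd] = max(-v[orig], 0.0)
        for r in irrev.reactions:
            assert r.lower_bound - 1e-9 <= split_flux[r.id] <= r.upper_bound + 1e-9
        back = irrev.net_flux(split_flux)
        assert all(math.isclose(back[k], v[k], abs_tol=1e-9) for k in v)


# ---------------------------------------------------------------------------
# Acetate regression
# ---------------------------------------------------------------------------

class TestFitAcetateBound:
    def test_collinear_points(self):
        res = fit_acetate_bound([(0.05, 1), (0.10, 2), (0.15, 3)], 0.10)
        assert math.isclose(res.prediction, 2.0, abs_tol=1e-12)
        assert math.isclose(res.standard_error, 0.0, abs_tol=1e-9)
        assert math.isclose(res.upper_bound, 2.0, abs_tol=1e-9)

    def test_matches_statsmodels_prediction_se(self):
        import statsmodels.api as sm

        pairs = [(0.05, 1.0), (0.10, 2.0), (0.15, 3.5)]
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        frame = fit.get_prediction(np.array([[1.0, 0.10]])).summary_frame()
        expected = float(frame["mean"].iloc[0]) + float(frame["mean_se"].iloc[0])
        res = fit_acetate_bound(pairs, 0.10)
        assert math.isclose(res.upper_bound, expected, rel_tol=1e-10)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_acetate_bound([(0.1, 1), (0.2, 2)], 0.15)

    def test_zero_growth_variance(self):
        with pytest.raises(ValueError):
            fit_acetate_bound([(0.1, 1), (0.1, 2), (0.1, 3)], 0.1)

    def test_extrapolation_guard(self):
        pairs = [(0.05, 1), (0.10, 2), (0.15, 3)]
        with pytest.raises(ValueError, match="extrapolation"):
            fit_acetate_bound(pairs, 0.5)
        # within 2x the span is allowed
        fit_acetate_bound(pairs, 0.19)


# ---------------------------------------------------------------------------
# Condition bounds
# ---------------------------------------------------------------------------

class TestApplyConditionBounds:
    def condition(self, **kw):
        defaults = dict(
            condition_id="c1", strain="wt", trophic_mode="mixotrophic",
            growth_rate=0.1, relative_cell_volume=1.0,
        )
        defaults.update(kw)
        return ConditionSpec(**defaults)

    def test_biomass_window(self, diamond_network):
        irrev = split_reversible(diamond_network)
        out = apply_condition_bounds(irrev, self.condition())
        b = out.reaction("sink")
        assert math.isclose(b.lower_bound, 0.099)
        assert math.isclose(b.upper_bound, 0.101)

    def test_policy_none_only_touches_biomass(self, diamond_network):
        irrev = split_reversible(diamond_network)
        out = apply_condition_bounds(irrev, self.condition())
        for rid in ("src", "r1", "r2", "r3"):
            orig = irrev.reaction(rid)
            new = out.reaction(rid)
            assert (orig.lower_bound, orig.upper_bound) == (new.lower_bound, new.upper_bound)

    def test_uptake_override_and_absent_id(self, diamond_network):
        irrev = split_reversible(diamond_network)
        cond = self.condition(uptake_overrides={"src": 3.0})
        out = apply_condition_bounds(irrev, cond)
        assert out.reaction("src").upper_bound == 3.0
        with pytest.raises(KeyError):
            apply_condition_bounds(
                irrev, self.condition(uptake_overrides={"missing": 1.0})
            )

    def test_regression_policy_sets_fitted_bound(self, diamond_network):
        irrev = split_reversible(diamond_network)
        pairs = [(0.05, 1.0), (0.10, 2.0), (0.15, 3.0)]
        out = apply_condition_bounds(
            irrev, self.condition(), acetate_policy="regression",
            acetate_reaction_id="src", growth_uptake_pairs=pairs,
        )
        expected = fit_acetate_bound(pairs, 0.1).upper_bound
        assert math.isclose(out.reaction("src").upper_bound, expected)

    def test_fixed_max_policy(self, diamond_network):
        irrev = split_reversible(diamond_network)
        out = apply_condition_bounds(
            irrev, self.condition(trophic_mode="heterotrophic"),
            acetate_policy="fixed_max", acetate_reaction_id="src",
            max_measured_uptake=4.2,
        )
        assert out.reaction("src").upper_bound == 4.2

    def test_idempotent(self, diamond_network):
        irrev = split_reversible(diamond_network)
        cond = self.condition(uptake_overrides={"src": 3.0})
        once = apply_condition_bounds(irrev, cond)
        twice = apply_condition_bounds(once, cond)
        for r1, r2 in zip(once.reactions, twice.reactions):
            assert (r1.lower_bound, r1.upper_bound) == (r2.lower_bound, r2.upper_bound)

    def test_invalid_condition_fields(self):
        with pytest.raises(ValueError):
            self.condition(growth_rate=0.0)
        with pytest.raises(ValueError):
            self.condition(trophic_mode="phototastic")
        with pytest.raises(ValueError):
            self.condition(relative_cell_volume=-1.0)
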