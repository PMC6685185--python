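"""FBA, medium application and single-omission performance metrics."""

import math

import pytest

from gsmcompare.performance_eval import (
    FBAError,
    Medium,
    MediumComponent,
    apply_medium,
    fba,
    performance_metrics,
    single_omission,
)

from conftest import build_network, toy_chain


class TestFBA:
    def test_uptake_limited_chain(self):
        net = toy_chain()
        medium = Medium("m", [MediumComponent("s", "EX_s_e", 10.0)])
        assert fba(apply_medium(net, medium)).objective_value == pytest.approx(10.0)

    def test_two_to_one_yield_halves_growth(self):
        net = toy_chain(yield_coeff=2.0)
        medium = Medium("m", [MediumComponent("s", "EX_s_e", 10.0)])
        assert fba(apply_medium(net, medium)).objective_value == pytest.approx(5.0)

    def test_blocked_biomass_gives_zero(self):
        net = build_network(
            {
                "EX_s_e": ({"s_e": -1.0}, -10, 1000, ""),
                "T_s": ({"s_e": -1.0, "s_c": 1.0}, 0, 1000, ""),
                # biomass needs q_c which nothing produces
                "biomass": ({"s_c": -1.0, "q_c": -1.0}, 0, 1000, ""),
            },
            objective="biomass",
        )
        assert fba(net).objective_value == pytest.approx(0.0)

    def test_missing_objective_raises(self):
        with pytest.raises(FBAError):
            fba(toy_chain(), objective="nope")

    def test_unbounded_objective_raises(self):
        net = build_network(
            {
                "make": ({"a_c": 1.0}, 0, math.inf, ""),
                "burn": ({"a_c": -1.0}, 0, math.inf, ""),
            },
            objective="make",
        )
        with pytest.raises(FBAError):
            fba(net)

    def test_invariant_under_duplicating_a_non_objective_reaction(self):
        net = toy_chain()
        medium = Medium("m", [MediumComponent("s", "EX_s_e", 10.0)])
        base = fba(apply_medium(net, medium)).objective_value
        dup = net.copy()
        r = dup.reactions["CONV"].copy()
        r.id = "CONV_copy"
        dup.add_reaction(r)
        again = fba(apply_medium(dup, medium)).objective_value
        assert again == pytest.approx(base)

    def test_agrees_with_cobrapy_on_synthetic_reference(self, tmp_path):
        """Independent solver route: the same model through cobrapy."""
        cobra = pytest.importorskip("cobra")
        from gsmcompare.model_io import write_network
        from gsmcompare.synthetic_data import (
            GeneratorConfig,
            generate_reference,
            reference_medium,
        )

        net = generate_reference(GeneratorConfig(seed=8))
        constrained = apply_medium(net, reference_medium())
        mine = fba(constrained).objective_value

        path = tmp_path / "ref.xml"
        write_network(constrained, path)
        model = cobra.io.read_sbml_model(str(path))
        theirs = model.optimize().objective_value
        assert mine == pytest.approx(theirs, rel=1e-6)


class TestApplyMedium:
    def test_listed_exchange_opened_others_closed(self):
        net = build_network(
            {
                "EX_glc_e": ({"glc_e": -1.0}, -1000, 1000, ""),
                "EX_o2_e": ({"o2_e": -1.0}, -1000, 1000, ""),
            }
        )
        out = apply_medium(net, Medium("m", [MediumComponent("glc", "EX_glc_e", 10)]))
        assert out.reactions["EX_glc_e"].lower_bound == -10.0
        assert out.reactions["EX_o2_e"].lower_bound == 0.0
        # secretion side untouched
        assert out.reactions["EX_o2_e"].upper_bound == 1000.0

    def test_empty_medium_closes_all_uptakes(self):
        net = build_network(
            {"EX_a_e": ({"a_e": -1.0}, -1000, 1000, "")}
        )
        out = apply_medium(net, Medium("void", []))
        assert out.reactions["EX_a_e"].lower_bound == 0.0

    def test_unknown_component_warns_and_continues(self):
        net = build_network(
            {"EX_a_e": ({"a_e": -1.0}, -1000, 1000, "")}
        )
        log: list[str] = []
        out = apply_medium(
            net,
            Medium("m", [MediumComponent("xyz", "EX_xyz_e", 5),
                         MediumComponent("a", "EX_a_e", 7)]),
            log=log,
        )
        assert out.reactions["EX_a_e"].lower_bound == -7.0
        assert any("EX_xyz_e" in line for line in log)

    def test_tightening_never_increases_growth(self):
        from gsmcompare.synthetic_data import (
            GeneratorConfig,
            generate_reference,
            reference_medium,
        )

        net = generate_reference(GeneratorConfig(seed=4))
        medium = reference_medium()
        full = fba(apply_medium(net, medium)).objective_value
        for comp in medium.components:
            less = fba(apply_medium(net, medium.without(comp.compound)))
            assert less.objective_value <= full + 1e-9


class TestSingleOmission:
    def _setup(self):
        # two substrates, one essential (s), one unused spare (u)
        net = build_network(
            {
                "EX_s_e": ({"s_e": -1.0}, -1000, 1000, ""),
                "EX_u_e": ({"u_e": -1.0}, -1000, 1000, ""),
                "T_s": ({"s_e": -1.0, "s_c": 1.0}, 0, 1000, ""),
                "T_u": ({"u_e": -1.0, "u_c": 1.0}, 0, 1000, ""),
                "CONV": ({"s_c": -1.0, "b_c": 1.0}, 0, 1000, ""),
                "SPARE": ({"u_c": -1.0, "w_c": 1.0}, 0, 1000, ""),
                "biomass": ({"b_c": -1.0}, 0, 1000, ""),
            },
            objective="biomass",
        )
        medium = Medium("basal", [
            MediumComponent("s", "EX_s_e", 10),
            MediumComponent("u", "EX_u_e", 10),
        ])
        return net, medium

    def test_essential_omission_with_no_growth_in_vivo_is_tn(self):
        net, medium = self._setup()
        outs = single_omission(net, medium, ["s"], {"s": False})
        assert outs[0].label == "TN"
        assert outs[0].in_silico_rate == pytest.approx(0.0)

    def test_unused_omission_with_growth_in_vivo_is_tp(self):
        net, medium = self._setup()
        outs = single_omission(net, medium, ["u"], {"u": True})
        assert outs[0].label == "TP"

    def test_rate_below_ten_percent_is_no_growth(self):
        # second route at 5% capacity: omission leaves 5% of basal -> FN
        net, medium = self._setup()
        net.add_reaction(
            type(net.reactions["CONV"])(
                id="TRICKLE",
                stoichiometry={"u_c": -1.0, "b_c": 1.0},
                lower_bound=0.0,
                upper_bound=0.5,
            )
        )
        outs = single_omission(net, medium, ["s"], {"s": True})
        assert outs[0].in_silico_rate == pytest.approx(0.5)
        assert not outs[0].in_silico_growth
        assert outs[0].label == "FN"

    def test_no_basal_growth_aborts(self):
        net, _ = self._setup()
        with pytest.raises(FBAError):
            single_omission(net, Medium("void", []), ["s"], {"s": False})


class TestPerformanceMetrics:
    def test_formula_values(self):
        m = performance_metrics((3, 4, 1, 2))
        assert m.sensitivity == pytest.approx(0.6)
        assert m.specificity == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.npv == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(0.7)
        assert m.f_score == pytest.approx(2 / 3)

    def test_perfect_classifier(self):
        m = performance_metrics((5, 5, 0, 0))
        for v in (m.sensitivity, m.specificity, m.precision, m.npv,
                  m.accuracy, m.f_score):
            assert v == 1.0

    def test_zero_denominators_are_nan_not_crash(self):
        m = performance_metrics((0, 4, 0, 2))
        assert math.isnan(m.precision)
        assert m.specificity == 1.0

    def test_accuracy_and_f_score_identities(self):
        for counts in [(3, 4, 1, 2), (1, 1, 1, 1), (10, 0, 3, 2)]:
            tp, tn, fp, fn = counts
            m = performance_metrics(counts)
            assert m.accuracy == pytest.approx((tp + tn) / sum(counts))
            if not math.isnan(m.precision) and not math.isnan(m.sensitivity):
                expect = (
                    2 * m.precision * m.sensitivity
                    / (m.precision + m.sensitivity)
                )
                assert m.f_score == pytest.approx(expect)
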