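"""Similarity metrics and gene/metabolite/reaction set comparison."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmcompare.namespace_map import MappingTable
from gsmcompare.network_compare import (
    CAT_EXACT,
    CAT_PROTON,
    CAT_REVERSED,
    compare_genes,
    compare_metabolite_sets,
    compare_reaction_sets,
    jaccard,
    match_equations,
    ratio,
)
from gsmcompare.synthetic_data import GeneratorConfig, generate_scenario

from conftest import build_network

sets = st.sets(st.sampled_from("abcdefgh"), max_size=8)


class TestJaccard:
    def test_hand_enumerated(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_identity_and_disjoint(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 0.0
        assert jaccard({"a"}, {"b"}) == 1.0

    def test_both_empty_undefined(self):
        assert math.isnan(jaccard(set(), set()))

    @settings(max_examples=200, derandomize=True)
    @given(sets, sets)
    def test_symmetry(self, a, b):
        if a or b:
            assert jaccard(a, b) == jaccard(b, a)

    @settings(max_examples=200, derandomize=True)
    @given(
        sets.filter(bool), sets.filter(bool), sets.filter(bool)
    )
    def test_triangle_inequality(self, a, b, c):
        assert jaccard(a, c) <= jaccard(a, b) + jaccard(b, c) + 1e-12

    @settings(max_examples=100, derandomize=True)
    @given(sets.filter(bool), sets.filter(bool))
    def test_zero_iff_equal(self, a, b):
        assert (jaccard(a, b) == 0.0) == (a == b)


class TestRatio:
    def test_hand_enumerated(self):
        assert ratio({"a", "b", "c"}, {"b", "c", "d"}) == 2.0

    def test_strict_subset_is_infinite(self):
        assert ratio({"a"}, {"a", "b"}) == math.inf

    def test_disjoint_is_zero(self):
        assert ratio({"a"}, {"b"}) == 0.0

    def test_both_empty_undefined(self):
        assert math.isnan(ratio(set(), set()))


class TestCompareGenes:
    def test_identical_networks(self):
        net = build_network(
            {"r": ({"a_c": -1.0, "b_c": 1.0}, 0, 1000, "g1 and g2")}
        )
        rep = compare_genes(net, net)
        assert rep.coverage_pct == 100.0
        assert rep.additional_pct == 0.0
        assert rep.jd == 0.0

    def test_planted_overlap(self):
        """|G_ref|=100, recall 0.8, 10 extras: coverage 80%, R_g = 8."""
        ref_genes = [f"g{i:03d}" for i in range(100)]
        ref = build_network(
            {
                f"r{i}": ({f"m{i}_c": -1.0, f"m{i+1}_c": 1.0}, 0, 1000,
                          " or ".join(ref_genes[2 * i: 2 * i + 2]))
                for i in range(50)
            },
            net_id="ref",
        )
        draft_rules = ref_genes[:80] + [f"x{i}" for i in range(10)]
        draft = build_network(
            {
                f"d{i}": ({f"m{i}_c": -1.0, f"m{i+1}_c": 1.0}, 0, 1000,
                          " or ".join(draft_rules[3 * i: 3 * i + 3]))
                for i in range(30)
            },
            net_id="draft",
        )
        rep = compare_genes(draft, ref)
        assert rep.coverage_pct == 80.0
        assert rep.additional_pct == 10.0
        assert rep.r == 8.0

    def test_empty_reference_undefined_with_warning(self):
        ref = build_network({"r": ({"a_c": -1.0, "b_c": 1.0}, 0, 1000, "")})
        draft = build_network({"r": ({"a_c": -1.0, "b_c": 1.0}, 0, 1000, "g")})
        rep = compare_genes(draft, ref)
        assert math.isnan(rep.coverage_pct)
        assert rep.warnings


class TestMatchEquations:
    def test_identical_is_exact(self):
        s = {"glc_c": -1.0, "atp_c": -1.0, "g6p_c": 1.0, "adp_c": 1.0}
        assert match_equations(dict(s), dict(s)) == CAT_EXACT

    def test_proton_stoichiometry_difference_is_partial(self):
        d = {"glc_c": -1.0, "atp_c": -1.0, "g6p_c": 1.0, "adp_c": 1.0,
             "h_c": 1.0}
        r = {"glc_c": -1.0, "atp_c": -1.0, "g6p_c": 1.0, "adp_c": 1.0,
             "h_c": 2.0}
        assert match_equations(d, r) == CAT_PROTON

    def test_opposite_direction_is_reversed(self):
        d = {"a_c": -1.0, "b_c": -1.0, "c_c": 1.0}
        r = {"a_c": 1.0, "b_c": 1.0, "c_c": -1.0}
        assert match_equations(d, r) == CAT_REVERSED

    def test_untranslated_blocks_everything(self):
        assert match_equations(None, {"a_c": 1.0}) == "none"

    def test_different_substrate_is_no_match(self):
        d = {"a_c": -1.0, "c_c": 1.0}
        r = {"b_c": -1.0, "c_c": 1.0}
        assert match_equations(d, r) == "none"


class TestCompareReactionSets:
    def test_self_comparison_is_all_exact(self):
        sc = generate_scenario(GeneratorConfig(seed=5, n_reactions=80,
                                               n_metabolites=60, n_genes=30))
        net = sc.reference
        rep = compare_reaction_sets(net, net, MappingTable())
        assert all(m.category == CAT_EXACT for m in rep.matches)
        assert rep.jd == 0.0
        assert len(rep.additional) == 0

    def test_planted_categories_recovered(self):
        cfg = GeneratorConfig(seed=9, reaction_dropout=0.2,
                              proton_perturb_rate=0.4, reversal_rate=0.05)
        sc = generate_scenario(cfg)
        rep = compare_reaction_sets(sc.draft, sc.reference, sc.mapping)
        fates = sc.truth.fate_counts()
        cats = {}
        for m in rep.matches:
            cats[m.category] = cats.get(m.category, 0) + 1
        assert cats.get(CAT_EXACT, 0) == (
            fates.get("kept_exact", 0) + fates.get("duplicated", 0)
        )
        assert cats.get(CAT_REVERSED, 0) == fates.get("kept_reversed", 0)
        assert cats.get(CAT_PROTON, 0) == fates.get("kept_proton_perturbed", 0)

    def test_renaming_with_complete_table_changes_nothing(self):
        base = GeneratorConfig(seed=21, rename_rate=0.0)
        renamed = GeneratorConfig(seed=21, rename_rate=0.5)
        sc0 = generate_scenario(base)
        sc1 = generate_scenario(renamed)
        rep0 = compare_reaction_sets(sc0.draft, sc0.reference, sc0.mapping)
        rep1 = compare_reaction_sets(sc1.draft, sc1.reference, sc1.mapping)
        assert rep0.coverage_pct == rep1.coverage_pct
        assert rep0.n_proton_partial == rep1.n_proton_partial

    def test_by_equation_beats_by_id_with_gappy_reaction_table(self):
        """Identifier mapping loses coverage when reaction-id entries are
        missing but metabolite entries are complete."""
        cfg = GeneratorConfig(seed=13, rename_rate=0.4)
        sc = generate_scenario(cfg)
        # withhold half the reaction-id synonyms, keep metabolite ones
        gappy = MappingTable()
        gappy.metabolite_syn = dict(sc.mapping.metabolite_syn)
        items = sorted(sc.mapping.reaction_syn.items())
        for src, targets in items[: len(items) // 2]:
            gappy.reaction_syn[src] = set(targets)
        by_eq = compare_reaction_sets(sc.draft, sc.reference, gappy,
                                      method="by_equation")
        by_id = compare_reaction_sets(sc.draft, sc.reference, gappy,
                                      method="by_id")
        assert by_eq.coverage_pct >= by_id.coverage_pct

    def test_exclude_exchange_flag(self):
        sc = generate_scenario(GeneratorConfig(seed=2))
        full = compare_reaction_sets(sc.draft, sc.reference, sc.mapping)
        noex = compare_reaction_sets(sc.draft, sc.reference, sc.mapping,
                                     exclude_exchange=True)
        assert noex.n_ref < full.n_ref


class TestCompareMetabolites:
    def test_identical_networks(self):
        net = build_network(
            {"r": ({"a_c": -1.0, "b_c": 1.0}, 0, 1000, "")}
        )
        rep = compare_metabolite_sets(net, net, MappingTable())
        assert rep.coverage_pct == 100.0
        assert rep.jd == 0.0

    def test_full_rename_with_complete_table_is_invisible(self):
        plain = generate_scenario(GeneratorConfig(seed=31, rename_rate=0.0))
        moved = generate_scenario(GeneratorConfig(seed=31, rename_rate=1.0))
        rep_plain = compare_metabolite_sets(
            plain.draft, plain.reference, plain.mapping
        )
        rep_moved = compare_metabolite_sets(
            moved.draft, moved.reference, moved.mapping
        )
        assert rep_plain.coverage_pct == rep_moved.coverage_pct
        assert rep_plain.jd == rep_moved.jd

    def test_truncated_table_lowers_coverage(self):
        sc = generate_scenario(GeneratorConfig(seed=41, rename_rate=0.6))
        full_cov = compare_metabolite_sets(
            sc.draft, sc.reference, sc.mapping
        ).coverage_pct
        half = MappingTable()
        items = sorted(sc.mapping.metabolite_syn.items())
        rng = random.Random(0)
        keep = rng.sample(range(len(items)), len(items) // 2)
        for i in keep:
            src, targets = items[i]
            half.metabolite_syn[src] = set(targets)
        half_cov = compare_metabolite_sets(
            sc.draft, sc.reference, half
        ).coverage_pct
        assert half_cov < full_cov


def test_gene_ratio_equals_coverage_over_additional():
    """R_g = coverage_pct / additional_pct whenever additional_pct > 0."""
    for seed in range(5):
        sc = generate_scenario(GeneratorConfig(seed=seed))
        rep = compare_genes(sc.draft, sc.reference)
        if rep.additional_pct and rep.additional_pct > 0:
            assert rep.r == pytest.approx(
                rep.coverage_pct / rep.additional_pct
            )
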