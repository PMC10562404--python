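"""Key evaluation, verification, greedy generation and rendering."""

import pytest
from hypothesis import given, settings, strategies as st

import morphokey as mk
from morphokey.synthetic_data import SimConfig, random_matrix, specimens_from_taxon


class TestEvaluate:
    def test_balteata_record_traces_1_2_3_unique(self, table1, printed_key):
        trace = mk.evaluate_key(printed_key, table1.taxon("S. balteata"),
                                matrix=table1)
        assert trace.path[:3] == [1, 2, 3]
        assert trace.terminals == frozenset({"S. balteata"})
        assert trace.status == "unique"

    def test_holotype_specimen_keys_out_to_robertsi(self, table1, printed_key,
                                                    panels):
        holotype = panels["holotype"].specimens[0]
        trace = mk.evaluate_key(printed_key, holotype, matrix=table1)
        assert trace.terminals == frozenset({"S. robertsi"})
        assert trace.status == "unique"

    def test_lobe_absent_only_specimen_is_ambiguous_over_eight_taxa(
            self, table1, printed_key):
        s = mk.Specimen(id="x", observations={"axillary_lobe": "absent"})
        trace = mk.evaluate_key(printed_key, s, matrix=table1)
        assert trace.status == "ambiguous"
        assert len(trace.terminals) == 8
        # the four lobe-present species are excluded
        assert not trace.terminals & {"S. balteata", "S. paucifasciata",
                                      "S. ataranensis", "S. tenebrosa"}

    def test_unknown_cells_explore_both_leads(self, table1, printed_key):
        # paucifasciata carries '?' cells yet still keys out uniquely
        trace = mk.evaluate_key(printed_key, table1.taxon("S. paucifasciata"),
                                matrix=table1)
        assert trace.terminals == frozenset({"S. paucifasciata"})

    def test_removing_an_observation_never_shrinks_the_terminal_set(
            self, table1, printed_key, panels):
        full = panels["holotype"].specimens[0]
        full_terms = mk.evaluate_key(printed_key, full, matrix=table1).terminals
        for drop in full.observations:
            obs = {k: v for k, v in full.observations.items() if k != drop}
            sub = mk.Specimen(id="sub", observations=obs) if obs else None
            if sub is None:
                continue
            terms = mk.evaluate_key(printed_key, sub, matrix=table1).terminals
            assert full_terms <= terms

    def test_predicate_on_unknown_character_is_an_error(self, table1, printed_key):
        s = mk.Specimen(id="x", observations={"axillary_lobe": "absent"})
        bad = mk.Predicate(char="no_such_char", test=("in", frozenset({"a"})))
        key = mk.DichotomousKey(couplets={1: mk.Couplet(id=1, leads=(
            mk.Lead(predicates=(bad,), target=("taxon", "S. balteata")),
            mk.Lead(predicates=(bad,), target=("taxon", "S. robertsi")),
        ))}, start=1)
        with pytest.raises(mk.MorphokeyError, match="no_such_char"):
            mk.evaluate_key(key, s, matrix=table1)


class TestVerify:
    def test_printed_key_flags_aurantiaca_dead_end_at_couplet_8(
            self, table1, printed_key):
        # Table 1 codes the anus of S. aurantiaca at middistance, which routes
        # it to couplet 8; neither lead there fits its 9+8 caudal formula and
        # light, thin caudal bar. The printed key and the matrix disagree.
        report = mk.verify_key(printed_key, table1)
        assert "S. aurantiaca" in report.failures
        trace = report.traces["S. aurantiaca"]
        assert trace.status == "dead_end"
        assert trace.dead_ends[0][0] == 8

    def test_terminal_missing_from_matrix_is_an_error(self, table1):
        key = mk.DichotomousKey(couplets={1: mk.Couplet(id=1, leads=(
            mk.Lead(predicates=(mk.Predicate("axillary_lobe",
                                             ("in", frozenset({"present"}))),),
                    target=("taxon", "S. balteata")),
            mk.Lead(predicates=(mk.Predicate("axillary_lobe",
                                             ("in", frozenset({"absent"}))),),
                    target=("taxon", "S. nonexistens")),
        ))}, start=1)
        with pytest.raises(mk.KeyStructureError, match="S. nonexistens"):
            mk.verify_key(key, table1)

    def test_generated_key_verifies_for_all_twelve_species(self, table1):
        key = mk.generate_key(table1)
        report = mk.verify_key(key, table1)
        assert report.ok, report.failures


class TestGenerate:
    def test_two_taxa_differing_in_one_character_gives_single_couplet(self):
        chars = [mk.CharacterDef(id="axillary_lobe", kind=mk.QUALITATIVE,
                                 vocabulary=("present", "absent"))]
        taxa = [
            mk.TaxonRecord("A", {"axillary_lobe": mk.StateSet(frozenset({"present"}))}),
            mk.TaxonRecord("B", {"axillary_lobe": mk.StateSet(frozenset({"absent"}))}),
        ]
        key = mk.generate_key(mk.CharacterMatrix(characters=chars, taxa=taxa))
        assert len(key.couplets) == 1
        assert set(key.terminal_taxa()) == {"A", "B"}

    def test_table1_yields_eleven_couplets_for_twelve_taxa(self, table1):
        # a correct binary key over n uniquely diagnosable taxa has n-1 couplets
        key = mk.generate_key(table1)
        assert len(key.couplets) == 11
        assert len(key.terminal_taxa()) == 12

    def test_duplicated_taxon_row_is_an_error_naming_the_pair(self, table1):
        dup = mk.TaxonRecord("S. clone", dict(table1.taxon("S. hartli").values))
        m = mk.CharacterMatrix(characters=table1.characters,
                               taxa=table1.taxa + [dup])
        with pytest.raises(mk.MorphokeyError, match="S. clone"):
            mk.generate_key(m)

    @pytest.mark.parametrize("objective", ["minimax-branch", "min-expected-depth"])
    def test_both_objectives_produce_verifying_keys(self, table1, objective):
        key = mk.generate_key(table1, objective=objective)
        assert mk.verify_key(key, table1).ok

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000), n_taxa=st.integers(2, 10))
    def test_generated_keys_verify_on_random_distinguishable_matrices(
            self, seed, n_taxa):
        m = random_matrix(SimConfig(n_taxa=n_taxa, n_characters=8,
                                    seed=seed, disjoint=True))
        key = mk.generate_key(m)
        report = mk.verify_key(key, m)
        assert report.ok, report.failures
        assert len(key.couplets) == n_taxa - 1


class TestRenderRoundtrip:
    def test_single_couplet_key_renders_two_leads(self):
        chars = [mk.CharacterDef(id="c", kind=mk.QUALITATIVE,
                                 vocabulary=("x", "y"))]
        taxa = [mk.TaxonRecord("A", {"c": mk.StateSet(frozenset({"x"}))}),
                mk.TaxonRecord("B", {"c": mk.StateSet(frozenset({"y"}))})]
        key = mk.generate_key(mk.CharacterMatrix(characters=chars, taxa=taxa))
        text = mk.render_key(key)
        body = [l for l in text.splitlines() if l and not l.startswith("#")]
        assert len(body) == 2

    def test_fixture_key_renders_eleven_numbered_couplets(self, printed_key):
        text = mk.render_key(printed_key)
        numbered = [l for l in text.splitlines() if l[:2].strip().isdigit()]
        assert len(numbered) == 11

    def test_render_then_parse_recovers_the_key(self, printed_key):
        text = mk.render_key(printed_key)
        again = mk.parse_rendered_key(text)
        assert mk.key_to_json(again) == mk.key_to_json(printed_key)


class TestStructure:
    def test_cyclic_key_rejected(self):
        p = mk.Predicate("c", ("in", frozenset({"x"})))
        with pytest.raises(mk.KeyStructureError, match="cycle"):
            mk.DichotomousKey(couplets={
                1: mk.Couplet(id=1, leads=(
                    mk.Lead((p,), ("couplet", 2)), mk.Lead((p,), ("taxon", "A")))),
                2: mk.Couplet(id=2, leads=(
                    mk.Lead((p,), ("couplet", 1)), mk.Lead((p,), ("taxon", "B")))),
            }, start=1)

    def test_unreachable_couplet_rejected(self):
        p = mk.Predicate("c", ("in", frozenset({"x"})))
        with pytest.raises(mk.KeyStructureError, match="unreachable"):
            mk.DichotomousKey(couplets={
                1: mk.Couplet(id=1, leads=(
                    mk.Lead((p,), ("taxon", "A")), mk.Lead((p,), ("taxon", "B")))),
                2: mk.Couplet(id=2, leads=(
                    mk.Lead((p,), ("taxon", "C")), mk.Lead((p,), ("taxon", "D")))),
            }, start=1)
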