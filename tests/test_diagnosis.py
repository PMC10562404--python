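"""Pairwise diagnosability, minimal diagnostic sets, classification, panels."""

import itertools

import pytest

import morphokey as mk
from morphokey.datamodel import values_compatible


def _diff(diffs, a, b):
    for d in diffs:
        if {d.taxon_a, d.taxon_b} == {a, b}:
            return d
    raise AssertionError((a, b))


class TestPairwiseDiffs:
    def test_all_unordered_pairs_present(self, table1):
        diffs = mk.pairwise_diffs(table1)
        assert len(diffs) == 12 * 11 // 2

    def test_robertsi_peninsulae_fin_ray_characters(self, table1):
        # The published account singles out pectoral and caudal-ray counts as
        # the external separators of this pair; both must be recovered, and
        # they are the only fin-ray or colour characters that separate it
        # (cephalic pore counts in the matrix also happen to be disjoint).
        d = _diff(mk.pairwise_diffs(table1), "S. robertsi", "S. peninsulae")
        assert {"pectoral_rays", "caudal_rays"} <= set(d.distinguishing)
        non_pore = {c for c in d.distinguishing if "pores" not in c}
        assert non_pore == {"pectoral_rays", "caudal_rays"}

    def test_identical_duplicated_taxa_have_empty_diff(self, table1):
        a = table1.taxon("S. hartli")
        m = mk.CharacterMatrix(
            characters=table1.characters,
            taxa=[a, mk.TaxonRecord("copy", dict(a.values))])
        assert mk.pairwise_diffs(m)[0].distinguishing == ()

    def test_unknown_everywhere_taxon_distinguishes_nothing(self, table1):
        ghost = mk.TaxonRecord(
            "ghost", {c.id: mk.UNKNOWN for c in table1.characters})
        m = mk.CharacterMatrix(characters=table1.characters,
                               taxa=table1.taxa + [ghost])
        for d in mk.pairwise_diffs(m):
            if d.involves("ghost"):
                assert d.distinguishing == ()


class TestUniqueCombination:
    def test_table1_every_species_uniquely_diagnosable(self, table1):
        ok, offending = mk.unique_combination_check(table1)
        assert ok and offending == []

    def test_two_identical_taxa_fail_with_pair_listed(self, table1):
        a = table1.taxon("S. hartli")
        m = mk.CharacterMatrix(
            characters=table1.characters,
            taxa=[a, mk.TaxonRecord("copy", dict(a.values))])
        ok, offending = mk.unique_combination_check(m)
        assert not ok and offending == [("S. hartli", "copy")]

    def test_single_taxon_matrix_vacuously_true(self, table1):
        m = mk.CharacterMatrix(characters=table1.characters,
                               taxa=[table1.taxon("S. hartli")])
        ok, offending = mk.unique_combination_check(m)
        assert ok and offending == []

    def test_equivalence_with_key_generation(self, table1):
        """unique_combination_check true <=> generate_key succeeds."""
        assert mk.unique_combination_check(table1)[0]
        mk.generate_key(table1)   # must not raise
        a = table1.taxon("S. hartli")
        m = mk.CharacterMatrix(
            characters=table1.characters,
            taxa=[a, mk.TaxonRecord("copy", dict(a.values))])
        assert not mk.unique_combination_check(m)[0]
        with pytest.raises(mk.MorphokeyError):
            mk.generate_key(m)


def brute_force_diagnostic(matrix, taxon, chars):
    """Independent oracle: no other taxon compatible on every member."""
    focal = matrix.taxon(taxon)
    for other in matrix.taxa:
        if other.name == taxon:
            continue
        if all(values_compatible(focal.values[c], other.values[c])
               for c in chars):
            return False
    return True


class TestMinimalDiagnosticSets:
    def test_every_returned_set_is_diagnostic_and_minimal(self, table1):
        for taxon in table1.taxon_names:
            sets = mk.minimal_diagnostic_sets(table1, taxon, k_max=3)
            for ds in sets:
                assert brute_force_diagnostic(table1, taxon, ds.characters)
                for r in range(1, len(ds.characters)):
                    for sub in itertools.combinations(ds.characters, r):
                        assert not brute_force_diagnostic(table1, taxon, sub)

    def test_ataranensis_unique_flank_pattern_is_a_singleton_set(self, table1):
        sets = mk.minimal_diagnostic_sets(table1, "S. ataranensis", k_max=2)
        assert ("body_bars",) in [d.characters for d in sets]

    def test_duplicated_taxon_has_no_diagnostic_set(self, table1):
        a = table1.taxon("S. hartli")
        m = mk.CharacterMatrix(
            characters=table1.characters,
            taxa=[a, mk.TaxonRecord("copy", dict(a.values))])
        assert mk.minimal_diagnostic_sets(m, "S. hartli", k_max=18) == []

    def test_uncertain_character_excluded_by_default(self, table1):
        # the paucifasciata caudal formula carries an uncertainty mark
        default = mk.minimal_diagnostic_sets(table1, "S. paucifasciata", k_max=3)
        for ds in default:
            assert "caudal_rays" not in ds.characters
        with_flag = mk.minimal_diagnostic_sets(table1, "S. paucifasciata",
                                               k_max=3, include_uncertain=True)
        assert any("caudal_rays" in ds.characters for ds in with_flag)

    def test_unknown_values_never_appear_in_diagnostic_sets(self, table1):
        sets = mk.minimal_diagnostic_sets(table1, "S. paucifasciata", k_max=4)
        unknowns = {c.id for c in table1.characters
                    if table1.value("S. paucifasciata", c.id) is mk.UNKNOWN}
        for ds in sets:
            assert not (set(ds.characters) & unknowns)

    def test_absent_taxon_is_an_error(self, table1):
        with pytest.raises(mk.MorphokeyError):
            mk.minimal_diagnostic_sets(table1, "S. imaginaria", k_max=2)


class TestClassify:
    def test_holotype_classifies_uniquely_to_robertsi(self, table1, panels):
        res = mk.classify_specimen(table1, panels["holotype"].specimens[0])
        assert res.status == "unique"
        assert res.overall == ("S. robertsi",)

    def test_phuket_8_plus_8_specimen_reports_conflict(self, table1):
        s = mk.Specimen(id="phuket",
                        observations={"pectoral_rays": 8, "caudal_rays": (8, 8)})
        res = mk.classify_specimen(table1, s)
        assert {"S. robertsi", "S. myaekanbawensis"} <= set(
            res.per_character["pectoral_rays"])
        assert "S. peninsulae" in res.per_character["caudal_rays"]
        assert res.status == "conflict"
        assert ("caudal_rays", "pectoral_rays") in res.conflicts

    def test_impossible_observation_yields_conflict(self, table1):
        s = mk.Specimen(id="odd", observations={"pectoral_rays": 99,
                                                "axillary_lobe": "present"})
        res = mk.classify_specimen(table1, s)
        assert res.status == "conflict"
        assert res.per_character["pectoral_rays"] == ()

    def test_specimen_sampled_from_taxon_always_includes_it(self, table1):
        from morphokey.synthetic_data import specimens_from_taxon
        for taxon in ("S. balteata", "S. robertsi", "S. tenebrosa"):
            panel = specimens_from_taxon(table1, taxon, 5, seed=9)
            for s in panel.specimens:
                res = mk.classify_specimen(table1, s)
                assert taxon in res.overall
                for cands in res.per_character.values():
                    assert taxon in cands

    def test_unknown_character_observation_is_an_error(self, table1):
        s = mk.Specimen(id="x", observations={"wing_length": 3})
        with pytest.raises(mk.MorphokeyError, match="wing_length"):
            mk.classify_specimen(table1, s)


class TestPanelReport:
    def test_phuket_tallies_match_published_arithmetic(self, table1, panels):
        report = mk.panel_report(table1, panels["zrc"])
        assert report["pectoral_rays"]["S. robertsi"] == 20
        assert report["caudal_rays"]["S. robertsi"] == 8
        assert report["caudal_rays"]["S. peninsulae"] == 12

    def test_mcz_paratypes_split_four_four(self, table1, panels):
        report = mk.panel_report(table1, panels["mcz"])
        assert report["caudal_rays"]["S. robertsi"] == 4
        assert report["caudal_rays"]["S. peninsulae"] == 4

    def test_empty_panel_is_an_error(self, table1):
        with pytest.raises(mk.MorphokeyError):
            mk.panel_report(table1, mk.SpecimenPanel(name="empty", specimens=[]))
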