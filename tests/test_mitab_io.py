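"""MITAB parsing, the experimental-validation filter, identifier mapping."""

import pytest
from hypothesis import given, strategies as st

from ppinet.mitab_io import (IdMap, InteractionRecord, MethodWhitelist,
                             filter_experimental, map_identifiers,
                             parse_mitab, write_mitab)


def mitab_row(a="uniprotkb:P1", b="uniprotkb:P2",
              method='psi-mi:"MI:0018"(two hybrid)',
              source='psi-mi:"MI:0469"(IntAct)',
              taxa=("taxid:9606", "taxid:9606"), ncols=15):
    cols = ["-"] * ncols
    cols[0], cols[1], cols[6], cols[12] = a, b, method, source
    cols[9], cols[10] = taxa
    return "\t".join(cols)


class TestParseMitab:
    def test_single_method_extracted(self):
        records, skipped = parse_mitab([mitab_row()])
        assert skipped == 0
        (rec,) = records
        assert rec.interactor_a == "P1"
        assert rec.interactor_b == "P2"
        assert rec.methods == {"MI:0018"}
        assert rec.source == "IntAct"
        assert rec.taxon_a == rec.taxon_b == "9606"

    def test_multiple_methods_split_into_set(self):
        row = mitab_row(method='psi-mi:"MI:0006"(x)|psi-mi:"MI:0007"(y)')
        records, _ = parse_mitab([row])
        assert records[0].methods == {"MI:0006", "MI:0007"}

    def test_empty_input_is_empty_with_zero_warnings(self):
        records, skipped = parse_mitab([])
        assert records == [] and skipped == 0

    @pytest.mark.parametrize("bad_row", [
        "only\ttwo",                              # < 15 columns
        mitab_row(method="yeast two hybrid"),     # no MI accession
    ])
    def test_malformed_rows_skipped_and_counted(self, bad_row):
        records, skipped = parse_mitab([bad_row, mitab_row()])
        assert len(records) == 1 and skipped == 1

    def test_comment_and_blank_lines_ignored(self):
        records, skipped = parse_mitab(["# header", "", mitab_row()])
        assert len(records) == 1 and skipped == 0

    def test_source_override(self):
        records, _ = parse_mitab([mitab_row()], source="BioGrid")
        assert records[0].source == "BioGrid"

    def test_roundtrip_preserves_retained_fields(self):
        original = [
            InteractionRecord("P1", "P2", frozenset({"MI:0006", "MI:0018"}),
                              "DIP", "9606", "10090"),
            InteractionRecord("Q5", "Q5", frozenset({"MI:0114"}), "IntAct"),
        ]
        reparsed, skipped = parse_mitab(write_mitab(original))
        assert skipped == 0
        assert reparsed == original
        # a second round-trip is bit-identical
        assert list(write_mitab(reparsed)) == list(write_mitab(original))


class TestMethodWhitelist:
    def test_default_is_nonempty_and_well_formed(self):
        wl = MethodWhitelist.default()
        assert "MI:0018" in wl and "MI:0006" in wl

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            MethodWhitelist(accepted=frozenset())

    def test_load_yaml_and_tsv(self, tmp_path):
        y = tmp_path / "wl.yaml"
        y.write_text("accepted: ['MI:0018']\n")
        t = tmp_path / "wl.tsv"
        t.write_text("MI:0018\ttwo hybrid\n# comment\nMI:0006\tcoip\n")
        assert MethodWhitelist.load(y).accepted == {"MI:0018"}
        assert MethodWhitelist.load(t).accepted == {"MI:0018", "MI:0006"}


class TestFilterExperimental:
    WL = MethodWhitelist(accepted=frozenset({"MI:0018", "MI:0006"}))

    @pytest.mark.parametrize("methods,kept_methods", [
        ({"MI:0018"}, {"MI:0018"}),             # whitelisted: kept
        ({"MI:0063"}, None),                    # prediction only: discarded
        ({"MI:0018", "MI:0063"}, {"MI:0018"}),  # reduced to whitelist subset
    ])
    def test_whitelist_intersection_rule(self, methods, kept_methods):
        rec = InteractionRecord("A", "B", frozenset(methods))
        kept, discarded = filter_experimental([rec], self.WL)
        if kept_methods is None:
            assert kept == [] and discarded == 1
        else:
            assert discarded == 0
            assert kept[0].methods == kept_methods

    @given(st.lists(st.frozensets(
        st.sampled_from(["MI:0018", "MI:0006", "MI:0063", "MI:0058"]),
        min_size=1), max_size=20))
    def test_kept_plus_discarded_equals_input(self, method_sets):
        records = [InteractionRecord("A", "B", ms) for ms in method_sets]
        kept, discarded = filter_experimental(records, self.WL)
        assert len(kept) + discarded == len(records)
        assert all(r.methods and r.methods <= self.WL.accepted for r in kept)


class TestIntraSpeciesFilter:
    def test_cross_species_rejected_missing_taxon_kept(self):
        from ppinet.mitab_io import filter_intra_species
        records = [
            InteractionRecord("A", "B", frozenset({"MI:0018"}),
                              taxon_a="9606", taxon_b="9606"),
            InteractionRecord("A", "C", frozenset({"MI:0018"}),
                              taxon_a="9606", taxon_b="10090"),
            InteractionRecord("A", "D", frozenset({"MI:0018"}),
                              taxon_a="9606", taxon_b=None),
        ]
        kept, dropped = filter_intra_species(records)
        assert dropped == 1
        assert [r.interactor_b for r in kept] == ["B", "D"]


class TestMapIdentifiers:
    IDMAP = IdMap.from_pairs([("P1", "G1"), ("P1", "G3"), ("P2", "G2")])

    def test_one_to_one(self):
        rec = InteractionRecord("P2", "P2", frozenset({"MI:0018"}))
        mapped, dropped = map_identifiers([rec], self.IDMAP)
        assert dropped == 0
        assert [(r.interactor_a, r.interactor_b) for r in mapped] \
            == [("G2", "G2")]

    def test_one_to_many_multiplies_record(self):
        rec = InteractionRecord("P1", "P2", frozenset({"MI:0018"}))
        mapped, dropped = map_identifiers([rec], self.IDMAP)
        assert dropped == 0
        assert {(r.interactor_a, r.interactor_b) for r in mapped} \
            == {("G1", "G2"), ("G3", "G2")}

    def test_unmappable_interactor_drops_record(self):
        rec = InteractionRecord("PX", "P2", frozenset({"MI:0018"}))
        mapped, dropped = map_identifiers([rec], self.IDMAP)
        assert mapped == [] and dropped == 1

    @given(st.lists(st.tuples(
        st.sampled_from(["P1", "P2", "PX"]),
        st.sampled_from(["P1", "P2", "PX"])), max_size=15))
    def test_output_size_is_crossproduct_sum(self, pairs):
        records = [InteractionRecord(a, b, frozenset({"MI:0018"}))
                   for a, b in pairs]
        mapped, dropped = map_identifiers(records, self.IDMAP)
        expected = sum(len(self.IDMAP[a]) * len(self.IDMAP[b])
                       for a, b in pairs)
        assert len(mapped) == expected
        assert dropped == sum(1 for a, b in pairs
                              if not self.IDMAP[a] or not self.IDMAP[b])

    def test_idmap_tsv_loader(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("P1\tG1\nP1\tG3\nP1\tG1\n# note\nP2\tG2\n")
        m = IdMap.load(p)
        assert m["P1"] == ("G1", "G3")   # sorted, de-duplicated
        assert m["P2"] == ("G2",)
        assert m["missing"] == ()
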