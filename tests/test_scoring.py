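"""The two-step Bayesian scoring scheme: reference sets, method
likelihood ratios, naive-Bayes edge weights."""

import math

import pytest
from hypothesis import given, strategies as st

from ppinet.consolidate import build_generic_interactome
from ppinet.go_annotations import AnnotationSet, TermSelection
from ppinet.mitab_io import InteractionRecord
from ppinet.scoring import (MethodGrouping, MethodScores, ReferenceSetError,
                            ReferenceSets, build_reference_sets,
                            group_methods, score_interaction,
                            score_interactome, score_methods,
                            weight_histogram)

from oracles import (brute_method_lr, brute_reference_sets, brute_weight)

COIP = MethodGrouping(group_of={"MI:0006": "coip", "MI:0007": "coip"})


def net_from(pairs_methods):
    records = [InteractionRecord(a, b, frozenset(ms), "s")
               for (a, b), ms in pairs_methods.items()]
    return build_generic_interactome({"s": records})


def ann_for(genes, term="GO:1"):
    ann = AnnotationSet()
    for g in genes:
        ann.add(g, term, "IDA")
    return ann


class TestGroupMethods:
    def test_coimmunoprecipitation_variants_share_a_label(self):
        grp = MethodGrouping.default()
        assert group_methods({"MI:0006", "MI:0007"}, grp) \
            == {"coimmunoprecipitation"}

    def test_identity_fallback(self):
        assert group_methods({"MI:0018"}, COIP) == {"MI:0018"}

    def test_empty(self):
        assert group_methods(set(), COIP) == set()

    def test_grouping_tsv_loader(self, tmp_path):
        p = tmp_path / "grp.tsv"
        p.write_text("# comment\nMI:0006\tcoip\nMI:0007\tcoip\n")
        grp = MethodGrouping.load(p)
        assert grp["MI:0006"] == grp["MI:0007"] == "coip"
        assert grp["MI:0018"] == "MI:0018"


class TestReferenceSets:
    NET = net_from({("G1", "G2"): {"MI:0018"},   # both annotated
                    ("G3", "G4"): {"MI:0018"},   # neither
                    ("G1", "G3"): {"MI:0018"}})  # mixed
    ANN = ann_for(["G1", "G2"])
    SEL = TermSelection(terms=frozenset({"GO:1"}))

    def test_three_case_partition(self):
        refs = build_reference_sets(self.NET, self.ANN, self.SEL)
        assert refs.positive == {("G1", "G2")}
        assert refs.negative == {("G3", "G4")}
        # the mixed edge belongs to neither set
        assert ("G1", "G3") not in refs.positive | refs.negative

    def test_matches_bruteforce_partition(self):
        pairs = [p for p, _ in self.NET.edges()]
        pos, neg, mixed = brute_reference_sets(pairs, {"G1", "G2"})
        refs = build_reference_sets(self.NET, self.ANN, self.SEL)
        assert refs.positive == pos and refs.negative == neg
        assert len(pos) + len(neg) + len(mixed) == len(self.NET)

    def test_empty_positive_set_is_fatal(self):
        net = net_from({("G3", "G4"): {"MI:0018"}})
        with pytest.raises(ReferenceSetError, match="positive"):
            build_reference_sets(net, self.ANN, self.SEL)

    def test_empty_negative_set_is_fatal(self):
        net = net_from({("G1", "G2"): {"MI:0018"}})
        with pytest.raises(ReferenceSetError, match="negative"):
            build_reference_sets(net, self.ANN, self.SEL)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            ReferenceSets(positive={("A", "B")}, negative={("A", "B")})


class TestScoreMethods:
    def test_stated_arithmetic_case(self):
        """|P|=3, |N|=3, method detects 2 positives and 1 negative,
        alpha=1 -> lr = (3/5)/(2/5) = 1.5."""
        refs = ReferenceSets(
            positive={("P1", "P2"), ("P3", "P4"), ("P5", "P6")},
            negative={("N1", "N2"), ("N3", "N4"), ("N5", "N6")})
        net2 = net_from({
            ("P1", "P2"): {"MI:0030"}, ("P3", "P4"): {"MI:0030"},
            ("P5", "P6"): {"MI:0018"},
            ("N1", "N2"): {"MI:0030"}, ("N3", "N4"): {"MI:0018"},
            ("N5", "N6"): {"MI:0018"},
        })
        scores = score_methods(net2, refs, MethodGrouping(), pseudocount=1.0)
        assert scores.lr["MI:0030"] == pytest.approx(1.5)
        assert scores.lr["MI:0018"] == pytest.approx((2 / 5) / (3 / 5))

    def test_symmetric_method_scores_one(self):
        net = net_from({("P1", "P2"): {"MI:0018"},
                        ("N1", "N2"): {"MI:0018"}})
        refs = ReferenceSets(positive={("P1", "P2")},
                             negative={("N1", "N2")})
        scores = score_methods(net, refs, MethodGrouping())
        assert scores.lr["MI:0018"] == pytest.approx(1.0)

    def test_unobserved_in_references_scores_one_when_balanced(self):
        # method present only on a mixed edge; |P| == |N|
        net = net_from({("P1", "P2"): {"MI:0018"},
                        ("N1", "N2"): {"MI:0018"},
                        ("P1", "N1"): {"MI:0030"}})
        refs = ReferenceSets(positive={("P1", "P2")},
                             negative={("N1", "N2")})
        scores = score_methods(net, refs, MethodGrouping())
        assert scores.lr["MI:0030"] == pytest.approx(1.0)

    def test_all_ratios_finite_and_positive(self):
        net = net_from({("P1", "P2"): {"MI:0006"},
                        ("N1", "N2"): {"MI:0018"}})
        refs = ReferenceSets(positive={("P1", "P2")},
                             negative={("N1", "N2")})
        scores = score_methods(net, refs, COIP)
        for lr in scores.lr.values():
            assert 0 < lr < math.inf


class TestScoreInteraction:
    SCORES = MethodScores(lr={"m1": 1.5, "m2": 2.0, "coip": 3.0})

    def test_single_method_arithmetic(self):
        assert score_interaction({"m1"}, self.SCORES) \
            == pytest.approx(1.5 / 2.5)  # 0.6

    def test_uninformative_evidence_returns_prior(self):
        scores = MethodScores(lr={"m1": 1.0, "m2": 1.0}, prior=0.3)
        assert score_interaction({"m1", "m2"}, scores) == pytest.approx(0.3)

    def test_grouped_accessions_count_once(self):
        """MI:0006 and MI:0007 on one edge weigh the same as either alone
        (overlapping evidence is ignored)."""
        both = score_interaction(
            group_methods({"MI:0006", "MI:0007"}, COIP), self.SCORES)
        alone = score_interaction(
            group_methods({"MI:0006"}, COIP), self.SCORES)
        assert both == alone == pytest.approx(3.0 / 4.0)

    def test_unscored_group_treated_as_neutral(self, caplog):
        with caplog.at_level("WARNING"):
            w = score_interaction({"m1", "never-seen"}, self.SCORES)
        assert w == pytest.approx(1.5 / 2.5)
        assert "never-seen" in caplog.text

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            score_interaction(set(), self.SCORES)

    @given(st.lists(st.floats(0.1, 10.0), min_size=1, max_size=5),
           st.floats(0.05, 0.95))
    def test_matches_closed_form_and_permutation_invariant(self, lrs, prior):
        labels = [f"m{i}" for i in range(len(lrs))]
        scores = MethodScores(lr=dict(zip(labels, lrs)), prior=prior)
        w = score_interaction(labels, scores)
        assert w == pytest.approx(brute_weight(labels, scores.lr, prior))
        assert w == pytest.approx(
            score_interaction(list(reversed(labels)), scores))
        assert 0 < w < 1

    def test_strictly_increasing_in_added_favorable_evidence(self):
        base = score_interaction({"m1"}, self.SCORES)
        more = score_interaction({"m1", "m2"}, self.SCORES)
        assert more > base


class TestScoreInteractome:
    NET = net_from({("G1", "G2"): {"MI:0018"},
                    ("G3", "G4"): {"MI:0018"},
                    ("G1", "G3"): {"MI:0018"}})

    def test_constant_evidence_gives_equal_weights(self):
        ann = ann_for(["G1", "G2"])
        sel = TermSelection(terms=frozenset({"GO:1"}))
        weighted, hist = score_interactome(self.NET, ann, sel,
                                           MethodGrouping())
        weights = {ev.weight for _, ev in weighted.edges()}
        assert len(weights) == 1
        assert sum(hist) == len(weighted)

    def test_input_not_mutated_and_weights_in_open_interval(self):
        ann = ann_for(["G1", "G2"])
        sel = TermSelection(terms=frozenset({"GO:1"}))
        weighted, _ = score_interactome(self.NET, ann, sel, MethodGrouping())
        assert all(ev.weight is None for _, ev in self.NET.edges())
        assert all(0 < ev.weight < 1 for _, ev in weighted.edges())


class TestBruteForceEquivalence:
    """On small planted networks the full scoring pipeline must agree
    with independent enumeration to near machine precision."""

    def test_lr_and_weights_match_enumeration(self):
        edge_methods = {
            ("A1", "A2"): {"MI:0006", "MI:0018"},
            ("A1", "A3"): {"MI:0007"},
            ("A2", "A3"): {"MI:0018"},
            ("B1", "B2"): {"MI:0018"},
            ("B1", "B3"): {"MI:0018", "MI:0030"},
            ("B2", "B3"): {"MI:0018"},
            ("A1", "B1"): {"MI:0018"},
        }
        net = net_from(edge_methods)
        annotated = {"A1", "A2", "A3"}
        ann = ann_for(annotated)
        sel = TermSelection(terms=frozenset({"GO:1"}))
        pos, neg, _ = brute_reference_sets(edge_methods, annotated)
        expected_lr = brute_method_lr(edge_methods, pos, neg, COIP.group_of)
        refs = build_reference_sets(net, ann, sel)
        scores = score_methods(net, refs, COIP)
        assert set(scores.lr) == set(expected_lr)
        for g in expected_lr:
            assert scores.lr[g] == pytest.approx(expected_lr[g], abs=1e-12)
        weighted, _ = score_interactome(net, ann, sel, COIP)
        for pair, ev in weighted.edges():
            groups = {COIP.group_of.get(m, m) for m in edge_methods[pair]}
            assert ev.weight == pytest.approx(
                brute_weight(groups, expected_lr), abs=1e-12)


class TestWeightHistogram:
    def test_right_closed_bins(self):
        counts = weight_histogram([0.05, 0.0500000001, 1.0, 0.0])
        assert counts[0] == 2   # 0.05 and 0.0 in (0, 0.05]
        assert counts[1] == 1
        assert counts[19] == 1
        assert sum(counts) == 4

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MethodScores(lr={}, pseudocount=0.0)
        with pytest.raises(ValueError):
            MethodScores(lr={}, prior=1.0)
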