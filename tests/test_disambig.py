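"""Co-citation graphs, communities, the 0.1% rule and the full pipeline."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from litmine import (
    CitationGraph,
    Corpus,
    GeneAnnotationSet,
    Publication,
    build_cocitation,
    classify_disconnected,
    detect_communities,
    disambiguate,
    evaluate_against_reference,
    find_candidates,
    label_communities,
)
from litmine.disambig import CommunityPartition
from litmine.lexicon import SynonymDictionary, SynonymEntry
from litmine.tagging import Mention, MentionIndex
from oracles import cocitation_bruteforce


class TestCoCitation:
    def test_no_common_citers_edgeless(self):
        graph = CitationGraph({("C", "A"), ("D", "B")})
        assert build_cocitation(graph, {"A", "B"}).weights == {}

    def test_two_citers_weight_two(self):
        graph = CitationGraph({("C", "A"), ("C", "B"), ("D", "A"), ("D", "B")})
        assert build_cocitation(graph, {"A", "B"}).weights == {("A", "B"): 2}

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            nodes = [f"N{i}" for i in range(50)]
            edges = {
                (nodes[i], nodes[j])
                for i, j in rng.integers(0, 50, size=(120, 2))
                if i != j
            }
            candidates = set(rng.choice(nodes, size=20, replace=False))
            ours = build_cocitation(CitationGraph(edges), candidates).weights
            assert ours == cocitation_bruteforce(edges, candidates)

    def test_isolated_nodes_kept(self):
        graph = CitationGraph({("C", "A"), ("C", "B")})
        cocite = build_cocitation(graph, {"A", "B", "Z"})
        assert cocite.isolated() == {"Z"}


class TestCommunities:
    @staticmethod
    def _clique_graph():
        edges = {}
        left = [f"L{i}" for i in range(4)]
        right = [f"R{i}" for i in range(4)]
        for group in (left, right):
            for i in range(4):
                for j in range(i + 1, 4):
                    edges[(min(group[i], group[j]), max(group[i], group[j]))] = 3
        edges[("L0", "R0")] = 1
        from litmine import CoCitationGraph

        return CoCitationGraph(nodes=left + right, weights=edges), left, right

    def test_two_cliques_split(self):
        graph, left, right = self._clique_graph()
        part = detect_communities(graph)
        left_ids = {part.membership[n] for n in left}
        right_ids = {part.membership[n] for n in right}
        assert len(left_ids) == 1 and len(right_ids) == 1
        assert left_ids != right_ids

    def test_single_edge_one_community(self):
        from litmine import CoCitationGraph

        graph = CoCitationGraph(nodes=["A", "B"], weights={("A", "B"): 1})
        part = detect_communities(graph)
        assert part.membership["A"] == part.membership["B"]

    def test_sizes_partition_connected_nodes(self, planted_world):
        mentions = find_candidates(
            planted_world.corpus, planted_world.dictionary, planted_world.target_gene
        )
        cocite = build_cocitation(
            planted_world.citations, mentions.docs_of(planted_world.target_gene)
        )
        part = detect_communities(cocite)
        total = sum(len(m) for m in part.communities().values())
        assert total == len(cocite.nodes)

    def test_planted_partition_recovered(self, planted_world):
        mentions = find_candidates(
            planted_world.corpus, planted_world.dictionary, planted_world.target_gene
        )
        cocite = build_cocitation(
            planted_world.citations, mentions.docs_of(planted_world.target_gene)
        )
        part = detect_communities(cocite)
        connected = sorted(cocite.degree_nodes())
        ari = adjusted_rand_score(
            [planted_world.community_truth[p] for p in connected],
            [part.membership[p] for p in connected],
        )
        assert ari >= 0.8


def _mentions(entity, safe_docs, unsafe_docs):
    ms = [Mention(entity, p, "safesyn", 0, 7, "safe") for p in safe_docs]
    ms += [Mention(entity, p, "amb", 0, 3, "unsafe") for p in unsafe_docs]
    return MentionIndex(ms)


class TestLabelCommunities:
    def test_no_safe_rejected(self):
        part = CommunityPartition(membership={"a": 0, "b": 0})
        lab = label_communities(part, _mentions("G", [], ["a", "b"]), "G")
        assert lab.labels[0] == "rejected"

    def test_boundary_ratio_just_above(self):
        members = [f"p{i}" for i in range(1000)]
        part = CommunityPartition(membership={p: 0 for p in members})
        lab = label_communities(
            part, _mentions("G", members[:1], members[1:]), "G"
        )
        # 1 safe / 999 unsafe-only = 0.1001% > 0.1%
        assert lab.labels[0] == "linked"

    def test_all_safe_linked(self):
        part = CommunityPartition(membership={"a": 0, "b": 0})
        lab = label_communities(part, _mentions("G", ["a", "b"], []), "G")
        assert lab.labels[0] == "linked"

    def test_mixed_doc_counts_in_numerator_only(self):
        part = CommunityPartition(membership={"a": 0, "b": 0})
        mentions = MentionIndex(
            [
                Mention("G", "a", "safesyn", 0, 7, "safe"),
                Mention("G", "a", "amb", 8, 11, "unsafe"),
                Mention("G", "b", "amb", 0, 3, "unsafe"),
            ]
        )
        lab = label_communities(part, mentions, "G")
        assert lab.labels[0] == "linked"  # ratio 1/1 > 0.1%


class TestClassifyDisconnected:
    def test_safe_direct_regardless_of_classifier(self):
        corpus = Corpus([Publication(pub_id="d1", title="safesyn here", abstract="", year=2000)])
        out = classify_disconnected(
            set(), set(), {"d1"}, _mentions("G", ["d1"], []), "G", corpus
        )
        assert out == {"d1": "safe-direct"}

    def test_zero_disconnected_no_additions(self):
        corpus = Corpus()
        out = classify_disconnected(
            {"x"}, set(), set(), _mentions("G", [], []), "G", corpus
        )
        assert out == {}

    def test_no_linked_community_warns(self):
        corpus = Corpus([Publication(pub_id="d1", title="amb here", abstract="", year=2000)])
        with pytest.warns(UserWarning, match="no linked community"):
            out = classify_disconnected(
                set(), set(), {"d1"}, _mentions("G", [], ["d1"]), "G", corpus
            )
        assert out == {}


class TestDisambiguate:
    def test_only_safe_synonyms_annotates_all_candidates(self):
        d = SynonymDictionary([SynonymEntry("G1", "uniqsyn", set(), "safe")])
        pubs = [
            Publication(pub_id=f"p{i}", title="uniqsyn study", abstract="", year=2000)
            for i in range(4)
        ]
        corpus = Corpus(pubs)
        citations = CitationGraph({("p0", "p1")})
        ann = disambiguate(corpus, citations, d, "G1", seed=0)
        assert ann.docs_of("G1") == {f"p{i}" for i in range(4)}

    def test_zero_candidates_empty(self):
        d = SynonymDictionary([SynonymEntry("G1", "uniqsyn", set(), "safe")])
        corpus = Corpus([Publication(pub_id="p0", title="other", abstract="", year=2000)])
        ann = disambiguate(corpus, CitationGraph(), d, "G1", seed=0)
        assert ann.docs_of("G1") == set()

    def test_planted_world_end_to_end(self, planted_world):
        ann = disambiguate(
            planted_world.corpus,
            planted_world.citations,
            planted_world.dictionary,
            planted_world.target_gene,
            seed=0,
        )
        ours = ann.docs_of(planted_world.target_gene)
        truth = planted_world.gene_truth
        tp = len(ours & truth)
        precision = tp / len(ours)
        recall = tp / len(truth)
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.9

    def test_safe_mention_monotonicity(self):
        # a doc left unannotated becomes annotated once it carries a safe synonym
        d = SynonymDictionary(
            [
                SynonymEntry("G1", "uniqsyn", set(), "safe"),
                SynonymEntry("G1", "amb", set(), "unsafe"),
            ]
        )
        base = [
            Publication(pub_id=f"p{i}", title="uniqsyn study", abstract="", year=2000)
            for i in range(3)
        ]
        lonely_before = Publication(pub_id="q", title="amb alone", abstract="", year=2000)
        lonely_after = Publication(
            pub_id="q", title="amb alone uniqsyn", abstract="", year=2000
        )
        before = disambiguate(Corpus(base + [lonely_before]), CitationGraph(), d, "G1", seed=0)
        after = disambiguate(Corpus(base + [lonely_after]), CitationGraph(), d, "G1", seed=0)
        assert before.docs_of("G1") <= after.docs_of("G1")
        assert "q" in after.docs_of("G1")


class TestEvaluate:
    def _ann(self, mapping):
        ann = GeneAnnotationSet()
        for g, docs in mapping.items():
            for p in docs:
                ann.add(g, p, "community")
        return ann

    def test_identical_perfect(self):
        ann = self._ann({"G1": {"a", "b"}})
        frame = evaluate_against_reference(ann, {"G1": {"a", "b"}}).set_index("gene")
        assert frame.loc["G1", "recall"] == 1.0
        assert frame.loc["G1", "precision"] == 1.0

    def test_disjoint_zero(self):
        ann = self._ann({"G1": {"a"}})
        frame = evaluate_against_reference(ann, {"G1": {"b"}}).set_index("gene")
        assert frame.loc["G1", "recall"] == 0.0
        assert frame.loc["G1", "precision"] == 0.0

    def test_three_gene_hand_computed(self):
        ann = self._ann({"G1": {"a", "b", "c"}, "G2": {"d"}, "G3": {"e", "f"}})
        ref = {"G1": {"a", "b", "x", "y"}, "G2": {"d"}, "G3": {"z"}}
        frame = evaluate_against_reference(ann, ref).set_index("gene")
        assert frame.loc["G1", "recall"] == pytest.approx(2 / 4)
        assert frame.loc["G1", "precision"] == pytest.approx(2 / 3)
        assert frame.loc["G2", "recall"] == 1.0
        assert frame.loc["G3", "precision"] == 0.0
        assert frame.loc["__average__", "recall"] == pytest.approx((0.5 + 1 + 0) / 3)

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty reference"):
            evaluate_against_reference(self._ann({}), {})
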