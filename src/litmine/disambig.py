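"""Gene/disease publication disambiguation via co-citation communities.

Candidate publications (those matching any synonym) are joined into a
weighted, undirected co-citation graph: the weight of an edge counts the
distinct third publications citing both endpoints.  Connected components
are broken into communities by greedy modularity maximisation; a community
is linked to the entity when the ratio of members with at least one safe
synonym to members with only unsafe synonyms exceeds 0.1%.  Publications
disconnected from the co-citation graph are linked directly when they carry
a safe synonym, and otherwise classified by positive-unlabelled bagging of
a logistic-regression text classifier trained on the linked and rejected
communities.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd

from .corpus import CitationGraph, Corpus
from .lexicon import DiseaseDictionary, SynonymDictionary
from .tagging import MentionIndex, find_candidates
from .textproc import TfidfModel, preprocess, pu_bag_train

logger = logging.getLogger("litmine")

__all__ = [
    "CoCitationGraph",
    "CommunityPartition",
    "GeneAnnotationSet",
    "build_cocitation",
    "detect_communities",
    "label_communities",
    "classify_disconnected",
    "disambiguate",
    "evaluate_against_reference",
]


@dataclass
class CoCitationGraph:
    """Weighted undirected co-citation graph over a candidate set."""

    nodes: list[str]
    weights: dict[tuple[str, str], int]  # key is the sorted pair

    def degree_nodes(self) -> set[str]:
        """Nodes with at least one co-citation edge."""
        out: set[str] = set()
        for u, v in self.weights:
            out.add(u)
            out.add(v)
        return out

    def isolated(self) -> set[str]:
        return set(self.nodes) - self.degree_nodes()

    def save(self, path: str | Path) -> None:
        pd.DataFrame(
            [(u, v, w) for (u, v), w in sorted(self.weights.items())],
            columns=["pub_a", "pub_b", "weight"],
        ).to_csv(path, sep="\t", index=False)


def build_cocitation(citations: CitationGraph, candidates: Iterable[str]) -> CoCitationGraph:
    """Count, for every unordered candidate pair, the citing papers citing both.

    Every publication citing two or more candidates (whether or not it is a
    candidate itself) adds one to the weight of each cited pair.  Candidates
    that gain no edge remain isolated nodes.
    """
    candidates = set(candidates)
    weights: dict[tuple[str, str], int] = defaultdict(int)
    for cited_set in citations.cited_by().values():
        hit = sorted(cited_set & candidates)
        for u, v in combinations(hit, 2):
            weights[(u, v)] += 1
    return CoCitationGraph(nodes=sorted(candidates), weights=dict(weights))


@dataclass
class CommunityPartition:
    """pub_id -> community id, with per-community link/reject labels."""

    membership: dict[str, int]
    labels: dict[int, str] = field(default_factory=dict)  # community -> linked|rejected

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = defaultdict(list)
        for pub, com in self.membership.items():
            out[com].append(pub)
        return dict(out)

    def docs_with_label(self, label: str) -> set[str]:
        return {
            pub for pub, com in self.membership.items() if self.labels.get(com) == label
        }


def detect_communities(graph: CoCitationGraph) -> CommunityPartition:
    """Greedy modularity maximisation on edge weights (fast-greedy).

    Isolated nodes each form a singleton community.  Determinism is fixed by
    sorted node order during graph construction.
    """
    connected = sorted(graph.degree_nodes())
    membership: dict[str, int] = {}
    next_id = 0
    if connected:
        g = ig.Graph()
        g.add_vertices(connected)
        index = {n: i for i, n in enumerate(connected)}
        edges = sorted(graph.weights.items())
        g.add_edges([(index[u], index[v]) for (u, v), _ in edges])
        g.es["weight"] = [w for _, w in edges]
        clustering = g.community_fastgreedy(weights="weight").as_clustering()
        for com_id, members in enumerate(clustering):
            for vid in members:
                membership[connected[vid]] = com_id
            next_id = com_id + 1
    for pub in sorted(graph.isolated()):
        membership[pub] = next_id
        next_id += 1
    return CommunityPartition(membership=membership)


def label_communities(
    partition: CommunityPartition,
    mentions: MentionIndex,
    entity: str,
    ratio_threshold: float = 0.001,
) -> CommunityPartition:
    """Label each community linked/rejected by the safe-to-unsafe-only ratio.

    A member with at least one safe synonym counts in the numerator; a
    member whose mentions are all unsafe counts in the denominator (a member
    with both kinds counts only in the numerator).  A community with no
    unsafe-only members is linked iff it has any safe member; a community
    with no safe members is rejected.
    """
    safe_counts = mentions.safe_counts()
    mentioned = mentions.docs_of(entity)
    labels: dict[int, str] = {}
    for com, members in partition.communities().items():
        n_safe = sum(1 for p in members if safe_counts.get((entity, p), 0) > 0)
        n_unsafe_only = sum(
            1
            for p in members
            if p in mentioned and safe_counts.get((entity, p), 0) == 0
        )
        if n_safe == 0:
            labels[com] = "rejected"
        elif n_unsafe_only == 0:
            labels[com] = "linked"
        else:
            labels[com] = (
                "linked" if n_safe / n_unsafe_only > ratio_threshold else "rejected"
            )
    return CommunityPartition(membership=dict(partition.membership), labels=labels)


@dataclass
class GeneAnnotationSet:
    """Entity -> annotated publications with provenance.

    Provenance is one of 'community' (linked via its co-citation community),
    'safe-direct' (disconnected but carrying a safe synonym) or 'classifier'
    (linked by the PU text classifier).
    """

    annotations: dict[str, dict[str, str]] = field(default_factory=dict)

    def docs_of(self, entity: str) -> set[str]:
        return set(self.annotations.get(entity, {}))

    def add(self, entity: str, pub_id: str, provenance: str) -> None:
        self.annotations.setdefault(entity, {})[pub_id] = provenance

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (entity, pub, prov)
            for entity, docs in self.annotations.items()
            for pub, prov in docs.items()
        ]
        return pd.DataFrame(rows, columns=["gene_id", "pub_id", "provenance"])

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _doc_tokens(corpus: Corpus, pub_id: str) -> list[str]:
    return preprocess(corpus[pub_id].text)


def classify_disconnected(
    linked_docs: set[str],
    rejected_docs: set[str],
    disconnected: set[str],
    mentions: MentionIndex,
    entity: str,
    corpus: Corpus,
    n_iterations: int = 50,
    seed: int = 0,
    threshold: float = 0.5,
    other_gene_docs: Sequence[str] | None = None,
    min_unlabelled: int = 1000,
    aux_negative_size: int = 1000,
) -> dict[str, str]:
    """Link disconnected publications; returns pub_id -> provenance additions.

    Safe-mention disconnected publications are linked outright.  The rest
    are scored by PU bagging of a logistic regression on TF-IDF features of
    titles+abstracts+keywords, with the linked communities as positives and
    the rejected communities as known negatives; a publication is linked
    when its mean held-out score exceeds ``threshold``.  When the unlabelled
    pool is smaller than ``min_unlabelled``, an auxiliary negative class of
    up to ``aux_negative_size`` publications mentioning other genes is added.
    """
    additions: dict[str, str] = {}
    safe = mentions.safe_docs_of(entity)
    ambiguous = []
    for pub in sorted(disconnected):
        if pub in safe:
            additions[pub] = "safe-direct"
        else:
            ambiguous.append(pub)
    if not ambiguous:
        return additions
    if not linked_docs:
        warnings.warn(
            f"no linked community for {entity!r}; "
            f"{len(ambiguous)} ambiguous disconnected publication(s) left unannotated",
            stacklevel=2,
        )
        return additions

    linked_sorted = sorted(linked_docs)
    rejected_sorted = sorted(rejected_docs)
    rng = np.random.default_rng(seed)
    aux: list[str] = []
    if len(ambiguous) < min_unlabelled and other_gene_docs:
        pool = sorted(set(other_gene_docs) - linked_docs - rejected_docs - set(ambiguous))
        if pool:
            take = min(aux_negative_size, len(pool))
            aux = [pool[i] for i in rng.choice(len(pool), size=take, replace=False)]

    train_docs = linked_sorted + rejected_sorted
    vectorizer = TfidfModel()
    try:
        vectorizer.fit([_doc_tokens(corpus, p) for p in train_docs])
    except ValueError:
        warnings.warn(
            f"training vocabulary empty for {entity!r}; "
            "ambiguous disconnected publications left unannotated",
            stacklevel=2,
        )
        return additions
    all_docs = train_docs + aux + ambiguous
    features = vectorizer.transform([_doc_tokens(corpus, p) for p in all_docs])
    n_linked, n_rejected, n_aux = len(linked_sorted), len(rejected_sorted), len(aux)
    positives = list(range(n_linked))
    known_neg = list(range(n_linked, n_linked + n_rejected + n_aux))
    unlabelled = list(range(n_linked + n_rejected + n_aux, len(all_docs)))
    ensemble = pu_bag_train(
        features,
        positives=positives,
        unlabelled=unlabelled,
        n_iterations=n_iterations,
        base_model="logistic",
        known_negatives=known_neg or None,
        seed=seed,
    )
    for pub, score in zip(ambiguous, ensemble.scores):
        if score > threshold:
            additions[pub] = "classifier"
    return additions


def disambiguate(
    corpus: Corpus,
    citations: CitationGraph,
    dictionary: SynonymDictionary | DiseaseDictionary,
    entity: str,
    ratio_threshold: float = 0.001,
    n_iterations: int = 50,
    seed: int = 0,
    other_gene_docs: Sequence[str] | None = None,
    mentions: MentionIndex | None = None,
) -> GeneAnnotationSet:
    """Full per-entity disambiguation pipeline.

    Composition of candidate search, co-citation construction, community
    detection, community labelling and disconnected-publication
    classification.  Annotations carry provenance.
    """
    if mentions is None:
        mentions = find_candidates(corpus, dictionary, entity)
    candidates = mentions.docs_of(entity)
    annotations = GeneAnnotationSet()
    if not candidates:
        return annotations
    cocite = build_cocitation(citations, candidates)
    partition = detect_communities(cocite)
    connected = cocite.degree_nodes()
    connected_partition = CommunityPartition(
        membership={p: c for p, c in partition.membership.items() if p in connected}
    )
    labelled = label_communities(
        connected_partition, mentions, entity, ratio_threshold
    )
    linked = labelled.docs_with_label("linked")
    rejected = labelled.docs_with_label("rejected")
    for pub in sorted(linked):
        annotations.add(entity, pub, "community")
    additions = classify_disconnected(
        linked,
        rejected,
        cocite.isolated(),
        mentions,
        entity,
        corpus,
        n_iterations=n_iterations,
        seed=seed,
        other_gene_docs=other_gene_docs,
    )
    for pub, prov in additions.items():
        annotations.add(entity, pub, prov)
    return annotations


def evaluate_against_reference(
    annotations: GeneAnnotationSet,
    reference: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-gene and macro-averaged recall/precision against a reference table.

    Recall = |ours ∩ ref| / |ref|; precision = |ours ∩ ref| / |ours|; the
    macro average runs over genes with a nonempty reference.  The returned
    frame has one row per gene plus an '__average__' row.
    """
    reference = {g: set(docs) for g, docs in reference.items() if docs}
    if not reference:
        raise ValueError("empty reference")
    rows = []
    for gene in sorted(reference):
        ours = annotations.docs_of(gene)
        ref = reference[gene]
        inter = len(ours & ref)
        rows.append(
            {
                "gene": gene,
                "recall": inter / len(ref),
                "precision": inter / len(ours) if ours else 0.0,
            }
        )
    frame = pd.DataFrame(rows)
    avg = {
        "gene": "__average__",
        "recall": frame["recall"].mean(),
        "precision": frame["precision"].mean(),
    }
    return pd.concat([frame, pd.DataFrame([avg])], ignore_index=True)
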