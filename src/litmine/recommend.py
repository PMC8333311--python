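"""Review recommendation by PageRank-weighted citation coverage.

Given the citation subgraph of a gene's publications, each publication gets
a PageRank score (scores sum to 1), and each review is scored by the summed
PageRank of the publications it cites, normalised so that a hypothetical
review citing everything scores 1.  Combinations of reviews are ranked
either by the literal matrix formula (row sum of the selected coverage
columns times the PageRank vector, which double-counts multiply-cited
publications) or, by default, by its binarised 'union' variant that counts
each covered publication once.  Exhaustive enumeration is used up to a
combination cap, with greedy forward selection beyond it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .corpus import CitationGraph

logger = logging.getLogger("litmine")

__all__ = ["ReviewCoverage", "pagerank", "score_reviews", "recommend"]


def pagerank(
    subgraph: CitationGraph,
    nodes: Sequence[str],
    damping: float = 0.85,
    tol: float = 1e-10,
) -> np.ndarray:
    """PageRank over the citation subgraph restricted to ``nodes``.

    Standard power iteration with uniform redistribution of dangling mass;
    edges point from citing to cited publication, so highly cited
    publications accumulate score.  Scores sum to 1.
    """
    nodes = list(nodes)
    if not nodes:
        raise ValueError("empty subgraph")
    node_set = set(nodes)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(
        (u, v) for u, v in subgraph.edges if u in node_set and v in node_set
    )
    scores = nx.pagerank(g, alpha=damping, tol=tol, max_iter=1000)
    return np.array([scores[n] for n in nodes])


@dataclass
class ReviewCoverage:
    """Binary publications x reviews coverage with PageRank weights."""

    publications: list[str]
    reviews: list[str]
    adjacency: np.ndarray  # (n_pubs, n_reviews) binary
    pagerank: np.ndarray  # (n_pubs,) sums to 1

    @classmethod
    def build(
        cls,
        citations: CitationGraph,
        publications: Sequence[str],
        reviews: Sequence[str],
        damping: float = 0.85,
    ) -> "ReviewCoverage":
        publications = list(publications)
        reviews = list(reviews)
        pub_index = {p: i for i, p in enumerate(publications)}
        adjacency = np.zeros((len(publications), len(reviews)))
        cited_by = citations.cited_by()
        for j, review in enumerate(reviews):
            for cited in cited_by.get(review, ()):  # the review cites these
                i = pub_index.get(cited)
                if i is not None:
                    adjacency[i, j] = 1.0
        scores = pagerank(citations, publications, damping=damping)
        return cls(publications, reviews, adjacency, scores)


def score_reviews(coverage: np.ndarray, pagerank_scores: np.ndarray) -> np.ndarray:
    """Per-review normalised score: summed PageRank of cited publications.

    The normaliser is the score of a hypothetical review citing every
    publication (the full PageRank mass); with scores summing to 1, the
    normalised score equals the raw sum.  A review citing nothing scores 0.
    """
    raw = coverage.T @ pagerank_scores
    total = float(pagerank_scores.sum())
    return raw / total if total > 0 else raw


def _combo_score(
    adjacency: np.ndarray,
    pagerank_scores: np.ndarray,
    cols: Sequence[int],
    mode: str,
) -> float:
    rowsum = adjacency[:, list(cols)].sum(axis=1)
    if mode == "union":
        rowsum = (rowsum > 0).astype(float)
    elif mode != "literal":
        raise ValueError(f"unknown mode {mode!r}")
    total = float(pagerank_scores.sum())
    return float(rowsum @ pagerank_scores) / total


def recommend(
    coverage: ReviewCoverage,
    r_min: int,
    r_max: int,
    topic_probs: np.ndarray | None = None,
    dates: Mapping[str, int] | None = None,
    mode: str = "union",
    exhaustive_cap: int = 100_000,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Rank review combinations of sizes r_min..r_max by coverage score.

    ``mode='literal'`` uses the printed matrix formula (double-counting
    multiply-cited publications); ``mode='union'`` (default) binarises the
    row sum first so overlapping reviews gain nothing from redundancy.  All
    combinations of a size are enumerated exhaustively while their count is
    at most ``exhaustive_cap``; beyond that, greedy forward selection is
    used and a notice logged.  Each emitted combination carries the
    normalised score, the mean year of its cited publications and the mean
    topic profile of its cited publications (when topics/dates are given).
    """
    if r_min < 1:
        raise ValueError("r_min must be >= 1")
    if r_min > r_max or r_max > len(coverage.reviews):
        raise ValueError("need r_min <= r_max <= number of reviews")
    adjacency, scores = coverage.adjacency, coverage.pagerank
    n_reviews = len(coverage.reviews)

    rows = []
    for size in range(r_min, r_max + 1):
        if comb(n_reviews, size) <= exhaustive_cap:
            combos = list(combinations(range(n_reviews), size))
        else:
            logger.info(
                "C(%d,%d) exceeds the exhaustive cap; using greedy forward selection",
                n_reviews,
                size,
            )
            chosen: list[int] = []
            remaining = set(range(n_reviews))
            while len(chosen) < size:
                best = max(
                    sorted(remaining),
                    key=lambda j: _combo_score(adjacency, scores, chosen + [j], mode),
                )
                chosen.append(best)
                remaining.discard(best)
            combos = [tuple(chosen)]
        for cols in combos:
            covered = adjacency[:, list(cols)].sum(axis=1) > 0
            row = {
                "reviews": tuple(coverage.reviews[j] for j in cols),
                "size": size,
                "score": _combo_score(adjacency, scores, cols, mode),
            }
            if dates is not None:
                years = [
                    dates[coverage.publications[i]]
                    for i in np.flatnonzero(covered)
                    if coverage.publications[i] in dates
                ]
                row["mean_year"] = float(np.mean(years)) if years else float("nan")
            if topic_probs is not None:
                if covered.any():
                    profile = topic_probs[covered].mean(axis=0)
                else:
                    profile = np.full(topic_probs.shape[1], np.nan)
                for k, v in enumerate(profile):
                    row[f"topic_{k}"] = float(v)
            rows.append(row)
    frame = pd.DataFrame(rows).sort_values(
        ["score", "size"], ascending=[False, True], kind="stable"
    )
    frame = frame.reset_index(drop=True)
    return frame.head(top_n) if top_n else frame
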