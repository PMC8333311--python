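"""Latent-topic detection over a gene's publications and topic timelines.

A nonnegative TF-IDF matrix A (documents x n-grams) is factorised into
W (documents x K) and H (K x terms) with W.H ~ A; W holds the strength of
association between a publication and a latent topic, H between a topic and
an n-gram.  NMF is the default; LDA is available as an alternative.  Topic
"probabilities" are the L1-normalised rows of W.  The timeline of a topic
is the per-calendar-year mean and standard deviation of these normalised
weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import NMF, LatentDirichletAllocation

from .textproc import DocTermMatrix

__all__ = ["TopicModel", "fit_topics", "topic_timeline", "top_phrases"]


@dataclass
class TopicModel:
    """Nonnegative factors of the document-term matrix."""

    W: np.ndarray  # documents x K
    H: np.ndarray  # K x terms
    K: int
    method: str

    def doc_topic_probabilities(self) -> np.ndarray:
        """L1-normalised rows of W; all-zero rows become uniform."""
        sums = self.W.sum(axis=1, keepdims=True)
        out = np.where(sums > 0, self.W / np.where(sums == 0, 1, sums), 1.0 / self.K)
        return out

    def save(self, w_path: str | Path, h_path: str | Path, vocabulary: Sequence[str]) -> None:
        pd.DataFrame(self.W).to_csv(w_path, sep="\t", index=False)
        frame = pd.DataFrame(self.H, columns=list(vocabulary))
        frame.to_csv(h_path, sep="\t", index=False)


def fit_topics(
    matrix: DocTermMatrix,
    K: int,
    method: str = "nmf",
    tol: float = 1e-12,
    seed: int = 0,
    max_iter: int = 2000,
) -> TopicModel:
    """Factorise the TF-IDF matrix into K nonnegative topics.

    Iterates until the relative error change falls below ``tol`` or the
    iteration cap is reached; deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n_docs = matrix.shape[0]
    if n_docs == 0:
        raise ValueError("empty matrix")
    if K > n_docs:
        raise ValueError(f"K={K} exceeds the number of documents ({n_docs})")
    if method == "nmf":
        model = NMF(
            n_components=K,
            init="nndsvda",
            tol=tol,
            max_iter=max_iter,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # max_iter convergence notices
            w = model.fit_transform(matrix.matrix)
        h = model.components_
    elif method == "lda":
        model = LatentDirichletAllocation(
            n_components=K,
            random_state=seed,
            max_iter=max(10, max_iter // 100),
        )
        w = model.fit_transform(matrix.matrix)
        h = model.components_
    else:
        raise ValueError(f"unknown method {method!r}")
    return TopicModel(W=np.asarray(w), H=np.asarray(h), K=K, method=method)


def topic_timeline(model: TopicModel, years: Sequence[int]) -> pd.DataFrame:
    """Per-year mean and standard deviation of normalised topic weights.

    ``years`` gives the calendar year of each document (model row).  Years
    with zero documents are simply absent from the output.  Columns: year,
    topic, mean, std.
    """
    years = np.asarray(years)
    if years.shape[0] != model.W.shape[0]:
        raise ValueError("one year per document required")
    probs = model.doc_topic_probabilities()
    rows = []
    for year in np.unique(years):
        block = probs[years == year]
        mean = block.mean(axis=0)
        std = block.std(axis=0)
        for k in range(model.K):
            rows.append(
                {"year": int(year), "topic": k, "mean": float(mean[k]), "std": float(std[k])}
            )
    return pd.DataFrame(rows)


def top_phrases(
    model: TopicModel,
    matrix: DocTermMatrix,
    topic: int,
    n: int = 10,
) -> list[tuple[str, float]]:
    """Top-n phrases of a topic by summed TF-IDF over its documents.

    Documents are hard-assigned to their argmax topic; the phrases of a
    topic are ranked by their summed TF-IDF weight within the topic's
    documents.  A topic with no assigned documents yields an empty list
    with a warning.  ``n`` beyond the vocabulary returns the full ranking.
    """
    if not 0 <= topic < model.K:
        raise ValueError(f"topic {topic} out of range")
    assign = model.W.argmax(axis=1)
    mask = assign == topic
    if not mask.any():
        warnings.warn(f"topic {topic} has no assigned documents", stacklevel=2)
        return []
    sums = np.asarray(matrix.matrix[mask].sum(axis=0)).ravel()
    order = np.argsort(-sums, kind="stable")
    ranked = [
        (matrix.vocabulary[j], float(sums[j])) for j in order if sums[j] > 0
    ]
    return ranked[:n]
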