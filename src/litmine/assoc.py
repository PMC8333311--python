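"""Gene-gene / gene-disease co-occurrence, NMI and MeSH-parent mapping."""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping

import pandas as pd

from .lexicon import DiseaseDictionary

__all__ = ["cooccurrence", "nmi", "map_gene_to_mesh_parent", "pair_table"]


def cooccurrence(annot_a: Iterable[str], annot_b: Iterable[str], mode: str = "union") -> float:
    """Co-occurrence score of two annotation sets.

    The default normalises the joint count by the number of publications
    presenting either tag (Jaccard); ``mode='min'`` normalises by the
    smaller set instead.  Two empty sets score 0 with a warning.
    """
    a, b = set(annot_a), set(annot_b)
    if not a and not b:
        warnings.warn("both annotation sets empty; co-occurrence 0", stacklevel=2)
        return 0.0
    joint = len(a & b)
    if joint == 0:
        return 0.0
    if mode == "union":
        return joint / len(a | b)
    if mode == "min":
        return joint / min(len(a), len(b))
    raise ValueError(f"unknown mode {mode!r}")


def _entropy(ps: list[float]) -> float:
    return -sum(p * math.log(p) for p in ps if p > 0.0)


def nmi(annot_a: Iterable[str], annot_b: Iterable[str], n_corpus: int) -> float:
    """Normalised mutual information of two tags over a corpus of size n.

    Membership in each set is a binary variable over the corpus;
    NMI = I(A;B) / sqrt(H(A) H(B)), and 0 when either variable is constant.
    """
    if n_corpus == 0:
        raise ValueError("n_corpus must be positive")
    a, b = set(annot_a), set(annot_b)
    if n_corpus < len(a | b):
        raise ValueError("n_corpus smaller than the union of the sets")
    n11 = len(a & b)
    n10 = len(a) - n11
    n01 = len(b) - n11
    n00 = n_corpus - n11 - n10 - n01
    n = float(n_corpus)
    pa, pb = len(a) / n, len(b) / n
    ha = _entropy([pa, 1 - pa])
    hb = _entropy([pb, 1 - pb])
    if ha == 0.0 or hb == 0.0:
        return 0.0
    mi = 0.0
    for nij, pi, pj in (
        (n11, pa, pb),
        (n10, pa, 1 - pb),
        (n01, 1 - pa, pb),
        (n00, 1 - pa, 1 - pb),
    ):
        if nij > 0:
            pij = nij / n
            mi += pij * math.log(pij / (pi * pj))
    return max(0.0, mi) / math.sqrt(ha * hb)


def pair_table(
    annotations: Mapping[str, Iterable[str]],
    n_corpus: int,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Symmetric co-occurrence/NMI table for entity pairs.

    With ``pairs=None`` all unordered pairs of annotated entities are
    scored.  Columns: entity_a, entity_b, jaccard, nmi, joint, n_a, n_b.
    """
    sets = {e: set(docs) for e, docs in annotations.items()}
    if pairs is None:
        names = sorted(sets)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
    rows = []
    for ea, eb in pairs:
        a, b = sets[ea], sets[eb]
        rows.append(
            {
                "entity_a": ea,
                "entity_b": eb,
                "jaccard": cooccurrence(a, b) if (a or b) else 0.0,
                "nmi": nmi(a, b, n_corpus),
                "joint": len(a & b),
                "n_a": len(a),
                "n_b": len(b),
            }
        )
    return pd.DataFrame(rows)


def map_gene_to_mesh_parent(
    gene_disease_counts: Mapping[str, Mapping[str, float]],
    ontology: DiseaseDictionary,
    root: str,
) -> dict[str, str]:
    """Assign each gene the top-level disease ancestor with maximal co-occurrence.

    Every disease term is mapped to its lowest ancestor directly under the
    disease ``root`` (a term directly under the root maps to itself); each
    gene is then linked to the ancestor with the maximal summed
    co-occurrence over its diseases.  Ties break to the lexicographically
    smaller term id.  Terms with no path to the root are skipped with a
    warning.
    """

    def top_ancestor(term: str) -> str | None:
        seen = set()
        frontier = [term]
        # breadth-first walk up; the first top-level ancestor found wins,
        # ties across multiple parents break lexicographically
        while frontier:
            tops = sorted(t for t in frontier if root in ontology.parents.get(t, []))
            if tops:
                return tops[0]
            nxt = []
            for t in frontier:
                for p in ontology.parents.get(t, []):
                    if p not in seen and p != root:
                        seen.add(p)
                        nxt.append(p)
            frontier = nxt
        return None

    out: dict[str, str] = {}
    for gene, counts in gene_disease_counts.items():
        summed: dict[str, float] = {}
        for term, count in counts.items():
            if term == root:
                continue
            anc = top_ancestor(term)
            if anc is None:
                warnings.warn(
                    f"disease term {term!r} has no path to root {root!r}; skipped",
                    stacklevel=2,
                )
                continue
            summed[anc] = summed.get(anc, 0.0) + float(count)
        if summed:
            best = max(summed.values())
            out[gene] = min(t for t, v in summed.items() if v == best)
    return out
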