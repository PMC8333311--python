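"""Synthetic corpora, lexicons, citation graphs, series and topic documents.

Every generator is a pure function of (seed, parameters) and returns its
ground truth alongside the generated data, so each downstream stage can be
tested against a planted answer without any external download:

* :func:`gen_lexicon` plants genes with one unique long synonym each and,
  at a configurable rate, one ambiguous synonym (an English word, a short
  token, a promiscuous token shared with another gene, or a token nested
  inside another gene's synonym).
* :func:`gen_safety_corpus` plants the document evidence those safety
  features are estimated from: safe synonyms co-occur with their symbol,
  ambiguous tokens also occur alone in ambient (non-gene) documents.
* :func:`gen_field_corpus` plants research fields as stochastic-block
  co-citation structure: one field truly concerns the target gene (partly
  via its safe synonym, partly via an ambiguous one), the other fields use
  the same ambiguous token with a different meaning.
* :func:`gen_timeseries` plants smooth Poisson-around-exponential growth
  with multiplicative publication bursts inside the forecast window.
* :func:`gen_topic_corpus` plants topic-term distributions and a
  year-indexed drift schedule of expected topic mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import CitationGraph, Corpus, Publication
from .lexicon import SynonymDictionary, SynonymEntry, build_gene_dictionary
from .textproc import ENGLISH_WORDS
from .trends import CATEGORIES

__all__ = [
    "PlantedWorld",
    "gen_lexicon",
    "gen_safety_corpus",
    "gen_field_corpus",
    "gen_timeseries",
    "gen_topic_corpus",
]

_CONSONANTS = "bcdfghjklmnpqrstvz"
_VOWELS = "aeiou"


class _WordFactory:
    """Deterministic pseudo-word source avoiding English words and repeats."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[str] = set()

    def word(self, n_syllables: int = 3) -> str:
        while True:
            w = "".join(
                self.rng.choice(list(_CONSONANTS)) + self.rng.choice(list(_VOWELS))
                for _ in range(n_syllables)
            )
            if w not in ENGLISH_WORDS and w not in self.used:
                self.used.add(w)
                return w

    def words(self, n: int, n_syllables: int = 3) -> list[str]:
        return [self.word(n_syllables) for _ in range(n)]


@dataclass
class PlantedWorld:
    """A generated world together with all of its ground truth."""

    corpus: Corpus | None = None
    citations: CitationGraph | None = None
    dictionary: SynonymDictionary | None = None
    target_gene: str | None = None
    lexicon_truth: pd.DataFrame | None = None
    gene_truth: set[str] = field(default_factory=set)  # pubs truly about the gene
    community_truth: dict[str, int] = field(default_factory=dict)
    burst_truth: dict[str, int] = field(default_factory=dict)
    topic_truth: dict | None = None


# ---------------------------------------------------------------------------
# Lexicon with planted ambiguity


def gen_lexicon(
    seed: int,
    n_genes: int,
    ambiguity_rate: float,
) -> tuple[SynonymDictionary, pd.DataFrame]:
    """Generate a gene synonym dictionary with planted ambiguous synonyms.

    Every gene receives its symbol plus one unique long multi-word synonym;
    with probability ``ambiguity_rate`` it additionally receives one
    ambiguous synonym of a random planted type (english / short /
    promiscuous / nested).  Returns the classified dictionary and a truth
    table (symbol, synonym, planted_type, unsafe).
    """
    if not 0 <= ambiguity_rate <= 1:
        raise ValueError("ambiguity_rate must be in [0, 1]")
    if n_genes < 2 and ambiguity_rate > 0:
        raise ValueError("promiscuous synonyms need at least 2 genes")
    rng = np.random.default_rng(seed)
    factory = _WordFactory(rng)
    symbols = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    unique_words = {s: factory.words(2) for s in symbols}

    english_pool = sorted(w for w in ENGLISH_WORDS if len(w) >= 4)
    rows = []
    truth_rows = []
    used_english: set[str] = set()
    used_short: set[str] = set()
    kinds = ["english", "short", "promiscuous", "nested"]
    letters = list("abcdefghijklmnopqrstuvwxyz")
    for idx, symbol in enumerate(symbols):
        unique = " ".join(unique_words[symbol])
        rows.append((symbol, unique))
        truth_rows.append((symbol, unique, "unique", False))
        truth_rows.append((symbol, symbol, "symbol", False))
        if rng.random() >= ambiguity_rate:
            continue
        kind = kinds[rng.integers(0, len(kinds))]
        if kind == "english":
            while True:
                w = english_pool[rng.integers(0, len(english_pool))]
                if w not in used_english:
                    used_english.add(w)
                    break
            rows.append((symbol, w))
            truth_rows.append((symbol, w, "english", True))
        elif kind == "short":
            while True:
                w = "".join(rng.choice(letters, size=2)).upper()
                if w not in used_short:
                    used_short.add(w)
                    break
            rows.append((symbol, w))
            truth_rows.append((symbol, w, "short", True))
        elif kind == "promiscuous":
            partner = symbols[(idx + 1 + int(rng.integers(0, n_genes - 1))) % n_genes]
            w = factory.word(2).upper()
            rows.append((symbol, w))
            rows.append((partner, w))
            truth_rows.append((symbol, w, "promiscuous", True))
            truth_rows.append((partner, w, "promiscuous", True))
        else:  # nested: first word of another gene's unique synonym
            partner = symbols[(idx + 1 + int(rng.integers(0, n_genes - 1))) % n_genes]
            w = unique_words[partner][0]
            rows.append((symbol, w))
            truth_rows.append((symbol, w, "nested", True))

    table = pd.DataFrame(rows, columns=["symbol", "synonym"])
    table["source"] = "synthetic"
    dictionary = build_gene_dictionary([table])
    truth = pd.DataFrame(
        truth_rows, columns=["symbol", "synonym", "planted_type", "unsafe"]
    ).drop_duplicates(subset=["symbol", "synonym"])
    return dictionary, truth


def gen_safety_corpus(
    seed: int,
    dictionary: SynonymDictionary,
    truth: pd.DataFrame,
    docs_per_gene: int = 4,
    ambient_docs: int = 6,
) -> Corpus:
    """Plant the document evidence behind the safety features.

    Each gene gets ``docs_per_gene`` publications mentioning its unique
    synonym together with its symbol (so alternatives co-occur); each
    planted-unsafe synonym additionally occurs alone in ``ambient_docs``
    generic publications, emulating its non-gene usage.
    """
    rng = np.random.default_rng(seed)
    factory = _WordFactory(rng)
    filler = factory.words(80)
    pubs = []
    counter = 0

    def fill(n: int) -> str:
        return " ".join(rng.choice(filler, size=n))

    unsafe = {
        (r.symbol, r.synonym) for r in truth.itertuples() if r.unsafe
    }
    by_symbol: dict[str, list[str]] = {}
    for r in truth.itertuples():
        if r.planted_type == "unique":
            by_symbol[r.symbol] = [r.synonym]
    for symbol, uniques in by_symbol.items():
        for _ in range(docs_per_gene):
            counter += 1
            year = int(rng.integers(1995, 2020))
            pubs.append(
                Publication(
                    pub_id=f"S{counter:06d}",
                    title=f"Role of {uniques[0]} ({symbol}) in {fill(2)}",
                    abstract=f"{fill(10)} {uniques[0]} {fill(10)}",
                    year=year,
                )
            )
    for symbol, synonym in sorted(unsafe):
        for _ in range(ambient_docs):
            counter += 1
            year = int(rng.integers(1995, 2020))
            pubs.append(
                Publication(
                    pub_id=f"S{counter:06d}",
                    title=f"{fill(3)} {synonym} {fill(3)}",
                    abstract=f"{fill(8)} {synonym} {fill(8)}",
                    year=year,
                )
            )
    return Corpus(pubs)


# ---------------------------------------------------------------------------
# Planted-field corpus with stochastic-block co-citation structure


def gen_field_corpus(
    seed: int,
    n_fields: int = 3,
    pubs_per_field: int = 60,
    p_in: float = 0.2,
    p_out: float = 0.005,
    lexicon: SynonymDictionary | None = None,
    frac_safe: float = 0.6,
    frac_disconnected: float = 0.2,
) -> PlantedWorld:
    """Plant research fields sharing an ambiguous synonym.

    Publications are partitioned into ``n_fields`` fields with disjoint
    vocabularies.  Field 0's documents concern the target gene: a
    ``frac_safe`` fraction mention its safe long synonym, the rest only the
    ambiguous token; every document of the other fields mentions the same
    ambiguous token with a different meaning.  Extra citing publications are
    added so that each same-field pair of connected documents is co-cited
    with probability ``p_in`` and each cross-field pair with ``p_out``;
    a ``frac_disconnected`` fraction of documents per field receives no
    co-citation edges at all.
    """
    if not p_in > p_out:
        raise ValueError("need p_in > p_out for recoverable communities")
    rng = np.random.default_rng(seed)
    factory = _WordFactory(rng)

    gene = "GENE0001"
    ambiguous = "orca"
    if lexicon is None:
        safe_long = " ".join(factory.words(2))
        lexicon = SynonymDictionary(
            [
                SynonymEntry(gene, gene, set(), "safe"),
                SynonymEntry(gene, safe_long, set(), "safe"),
                SynonymEntry(gene, ambiguous, {"english"}, "unsafe"),
            ]
        )
    else:
        safe = [e for e in lexicon.synonyms_of(gene) if e.safety == "safe" and " " in e.synonym]
        unsafe = [e for e in lexicon.synonyms_of(gene) if e.safety == "unsafe"]
        if not safe or not unsafe:
            raise ValueError("lexicon must hold a safe multi-word and an unsafe synonym for GENE0001")
        safe_long = safe[0].synonym
        ambiguous = unsafe[0].synonym

    field_vocab = [factory.words(30) for _ in range(n_fields)]
    shared = factory.words(15)

    pubs: list[Publication] = []
    community_truth: dict[str, int] = {}
    gene_truth: set[str] = set()

    def doc_text(f: int, n: int) -> str:
        own = rng.choice(field_vocab[f], size=n)
        mix = rng.choice(shared, size=max(1, n // 3))
        return " ".join(np.concatenate([own, mix]))

    doc_ids: list[list[str]] = []
    for f in range(n_fields):
        ids = []
        for i in range(pubs_per_field):
            pid = f"F{f}P{i:03d}"
            ids.append(pid)
            community_truth[pid] = f
            year = int(rng.integers(1995, 2020))
            if f == 0:
                gene_truth.add(pid)
                if i < int(round(frac_safe * pubs_per_field)):
                    title = f"{safe_long} in {doc_text(f, 4)}"
                else:
                    title = f"{ambiguous} and {doc_text(f, 4)}"
            else:
                title = f"{ambiguous} {doc_text(f, 4)}"
            pubs.append(
                Publication(
                    pub_id=pid,
                    title=title,
                    abstract=doc_text(f, 25),
                    year=year,
                )
            )
        doc_ids.append(ids)

    # connected subset per field; the rest stay disconnected by construction
    connected: list[list[str]] = []
    for f in range(n_fields):
        k = int(round((1 - frac_disconnected) * pubs_per_field))
        connected.append(doc_ids[f][:k])

    edges: set[tuple[str, str]] = set()
    citer = 0
    flat = [(f, pid) for f in range(n_fields) for pid in connected[f]]
    for a in range(len(flat)):
        for b in range(a + 1, len(flat)):
            fa, pa = flat[a]
            fb, pb = flat[b]
            p = p_in if fa == fb else p_out
            if rng.random() < p:
                citer += 1
                cid = f"C{citer:05d}"
                pubs.append(
                    Publication(
                        pub_id=cid,
                        title=doc_text(fa, 4),
                        abstract=doc_text(fb, 10),
                        year=int(rng.integers(1995, 2020)),
                    )
                )
                edges.add((cid, pa))
                edges.add((cid, pb))

    corpus = Corpus(pubs)
    return PlantedWorld(
        corpus=corpus,
        citations=CitationGraph(edges),
        dictionary=lexicon,
        target_gene=gene,
        gene_truth=gene_truth,
        community_truth=community_truth,
    )


# ---------------------------------------------------------------------------
# Yearly count series with planted bursts


def gen_timeseries(
    seed: int,
    n_genes: int,
    years: Sequence[int] = tuple(range(1980, 2020)),
    burst_fraction: float = 0.1,
    burst_multiplier: float = 4.0,
    train_end: int = 2013,
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Cumulative category series with multiplicative bursts in the horizon.

    Baseline yearly new publications are Poisson around a per-gene
    exponential trend; citations are proportional to publications, and the
    remaining eight categories are binomial thinnings.  A ``burst_fraction``
    of genes has its new counts multiplied by ``burst_multiplier`` from a
    planted year inside the forecast window onward.  Returns the series per
    gene and the planted gene -> burst-year truth.
    """
    years = np.asarray(sorted(years))
    if years.size == 0:
        raise ValueError("empty year range")
    if burst_multiplier <= 1:
        raise ValueError("burst_multiplier must exceed 1")
    horizon = years[years > train_end]
    rng = np.random.default_rng(seed)

    n_burst = int(round(burst_fraction * n_genes))
    burst_genes = rng.choice(n_genes, size=n_burst, replace=False) if n_burst else []
    burst_truth: dict[str, int] = {}

    out: dict[str, pd.DataFrame] = {}
    fractions = {
        "reviews": 0.12,
        "trials": 0.05,
        "pub_big_pharma": 0.08,
        "pub_med_pharma": 0.06,
    }
    cit_fractions = {
        "cit_reviews": 0.20,
        "cit_trials": 0.05,
        "cit_big_pharma": 0.08,
        "cit_med_pharma": 0.06,
    }
    for g in range(n_genes):
        name = f"G{g:04d}"
        rate = rng.uniform(0.01, 0.07)
        base = float(np.exp(rng.uniform(-0.5, 2.5)))
        mean = base * np.exp(rate * (years - years[0]))
        new_pubs = rng.poisson(mean).astype(float)
        if g in burst_genes:
            if horizon.size == 0:
                raise ValueError("burst requested but no years beyond train_end")
            burst_year = int(horizon[rng.integers(0, horizon.size)])
            burst_truth[name] = burst_year
            new_pubs[years >= burst_year] *= burst_multiplier
        new_cits = rng.poisson(6.0 * new_pubs).astype(float)
        frame = pd.DataFrame(0.0, index=years, columns=CATEGORIES)
        frame["publications"] = new_pubs
        frame["citations"] = new_cits
        for cat, frac in fractions.items():
            frame[cat] = rng.binomial(new_pubs.astype(int), frac)
        for cat, frac in cit_fractions.items():
            frame[cat] = rng.binomial(new_cits.astype(int), frac)
        out[name] = frame.cumsum()
    return out, burst_truth


# ---------------------------------------------------------------------------
# Topic-mixture documents with drift


def gen_topic_corpus(
    seed: int,
    K: int,
    docs_per_year: int,
    years: Sequence[int] = tuple(range(2005, 2020)),
    drift: Mapping[int, Sequence[float]] | Callable[[int], Sequence[float]] | None = None,
    words_per_doc: int = 40,
    words_per_topic: int = 25,
    concentration: float = 8.0,
) -> tuple[list[list[str]], np.ndarray, dict]:
    """Documents drawn from planted topic-term distributions with drift.

    Each document's topic mixture is Dirichlet around the year's expected
    weights from the ``drift`` schedule (default: constant uniform); words
    are drawn from disjoint per-topic vocabularies.  Returns (token
    documents, document years, truth) where truth holds the topic-term
    matrix, the vocabulary and the per-document mixtures.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    years = np.asarray(sorted(years))
    rng = np.random.default_rng(seed)
    factory = _WordFactory(rng)
    vocab_by_topic = [factory.words(words_per_topic) for _ in range(K)]
    vocabulary = [w for ws in vocab_by_topic for w in ws]
    topic_term = np.zeros((K, len(vocabulary)))
    offset = 0
    for k in range(K):
        weights = rng.dirichlet(np.full(words_per_topic, 5.0))
        topic_term[k, offset : offset + words_per_topic] = weights
        offset += words_per_topic

    def schedule(year: int) -> np.ndarray:
        if drift is None:
            return np.full(K, 1.0 / K)
        if callable(drift):
            w = np.asarray(drift(year), dtype=float)
        else:
            if year not in drift:
                raise ValueError(f"drift schedule does not cover year {year}")
            w = np.asarray(drift[year], dtype=float)
        if w.size != K or w.min() < 0 or w.sum() <= 0:
            raise ValueError("drift weights must be K nonnegative numbers")
        return w / w.sum()

    docs: list[list[str]] = []
    doc_years: list[int] = []
    mixtures: list[np.ndarray] = []
    for year in years:
        expected = schedule(int(year))
        for _ in range(docs_per_year):
            alpha = np.maximum(concentration * expected, 1e-3)
            mix = rng.dirichlet(alpha)
            topics = rng.choice(K, size=words_per_doc, p=mix)
            words = [
                vocabulary[
                    int(rng.choice(len(vocabulary), p=topic_term[k]))
                ]
                for k in topics
            ]
            docs.append(words)
            doc_years.append(int(year))
            mixtures.append(mix)
    truth = {
        "topic_term": topic_term,
        "vocabulary": vocabulary,
        "mixtures": np.stack(mixtures),
        "vocab_by_topic": vocab_by_topic,
    }
    return docs, np.asarray(doc_years), truth
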