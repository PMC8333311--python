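"""Gene and disease synonym dictionaries and unsafe-synonym classification.

A gene synonym is any string the literature uses for a gene, including the
approved symbol itself.  Synonyms fall into four ambiguity classes:

* ``nested`` — a word-bounded substring of another synonym ('insulin' inside
  'insulin receptor');
* ``promiscuous`` — shared by two or more gene symbols;
* ``english`` — an ordinary English word ('STAR');
* ``short`` — fewer than three characters.

A synonym is labelled *unsafe* if it is English, short, promiscuous, or if a
positive-unlabelled random-forest classifier trained on engineered features
(candidate counts, contribution, length, character information content,
nesting, conditional co-mention probabilities, symbol flag) scores it above
a threshold.  Unsafe synonyms never link a publication to a gene directly.
"""

from __future__ import annotations

import json
import logging
import math
import re
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus
from .textproc import ENGLISH_WORDS, PUBagEnsemble, pu_bag_train

logger = logging.getLogger("litmine")

__all__ = [
    "SynonymEntry",
    "SynonymDictionary",
    "DiseaseDictionary",
    "build_gene_dictionary",
    "build_disease_dictionary",
    "reverse_comma_name",
    "character_frequencies",
    "compute_safety_features",
    "train_safety_ensemble",
    "classify_unsafe",
    "FEATURE_COLUMNS",
]


@dataclass
class SynonymEntry:
    symbol: str
    synonym: str
    classes: set[str] = field(default_factory=set)
    safety: str = "unknown"  # safe | unsafe | unknown
    score: float = float("nan")


class SynonymDictionary:
    """Gene symbol -> synonyms, with ambiguity classes and safety labels."""

    def __init__(self, entries: Iterable[SynonymEntry] = ()) -> None:
        self.entries: list[SynonymEntry] = list(entries)

    def symbols(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.symbol, None)
        return list(seen)

    def synonyms_of(self, symbol: str) -> list[SynonymEntry]:
        return [e for e in self.entries if e.symbol == symbol]

    def entry(self, symbol: str, synonym: str) -> SynonymEntry:
        for e in self.entries:
            if e.symbol == symbol and e.synonym == synonym:
                return e
        raise KeyError((symbol, synonym))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "symbol": [e.symbol for e in self.entries],
                "synonym": [e.synonym for e in self.entries],
                "classes": [",".join(sorted(e.classes)) for e in self.entries],
                "safety": [e.safety for e in self.entries],
                "score": [e.score for e in self.entries],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class DiseaseDictionary:
    """Disease ontology terms: id -> names (with comma-reversed variants) and parents."""

    names: dict[str, list[str]] = field(default_factory=dict)
    parents: dict[str, list[str]] = field(default_factory=dict)

    def all_names(self) -> set[str]:
        return {n for names in self.names.values() for n in names}

    def __len__(self) -> int:
        return len(self.names)


def reverse_comma_name(name: str) -> str | None:
    """'Insipidus, Diabetes' -> 'Diabetes Insipidus'.

    Multi-comma names get a single full reversal of their comma-separated
    segments.  Returns None when the name has no comma.
    """
    if "," not in name:
        return None
    segments = [s.strip() for s in name.split(",")]
    return " ".join(reversed(segments))


def build_disease_dictionary(ontology_export: str | Path | Mapping) -> DiseaseDictionary:
    """Build the disease dictionary from a JSON ontology export.

    The export maps each term to its id, preferred name, concept-list terms
    (synonyms) and parent ids.  Comma-form names are additionally stored in
    reversed form.  Cyclic parent links are an error.
    """
    if isinstance(ontology_export, (str, Path)):
        data = json.loads(Path(ontology_export).read_text(encoding="utf-8"))
    else:
        data = ontology_export
    names: dict[str, list[str]] = {}
    parents: dict[str, list[str]] = {}
    for term in data["terms"]:
        tid = term["id"]
        if tid in names:
            raise ValueError(f"duplicate term id {tid!r}")
        all_names = [term["name"], *term.get("synonyms", [])]
        extra = [r for n in all_names if (r := reverse_comma_name(n)) is not None]
        names[tid] = list(dict.fromkeys(all_names + extra))
        parents[tid] = list(term.get("parents", []))

    # cycle check by iterative colouring
    state: dict[str, int] = {}

    def visit(tid: str, stack: list[str]) -> None:
        if state.get(tid) == 2:
            return
        if tid in stack:
            raise ValueError(f"cyclic parent links involving {tid!r}")
        stack.append(tid)
        for p in parents.get(tid, []):
            visit(p, stack)
        stack.pop()
        state[tid] = 2

    for tid in names:
        visit(tid, [])
    return DiseaseDictionary(names=names, parents=parents)


# ---------------------------------------------------------------------------
# Gene dictionary

_WORD_BOUND_CACHE: dict[str, re.Pattern] = {}


def _word_bounded_in(needle: str, haystack: str) -> bool:
    """Case-insensitive containment of needle in haystack at word boundaries."""
    pat = _WORD_BOUND_CACHE.get(needle)
    if pat is None:
        pat = re.compile(
            r"(?<![0-9A-Za-z])" + re.escape(needle) + r"(?![0-9A-Za-z])",
            re.IGNORECASE,
        )
        _WORD_BOUND_CACHE[needle] = pat
    return pat.search(haystack) is not None


def build_gene_dictionary(
    source_tables: Sequence[str | Path | pd.DataFrame],
    disease_names: DiseaseDictionary | None = None,
) -> SynonymDictionary:
    """Aggregate symbol->synonym tables into a classified dictionary.

    Synonyms are unioned per symbol with case-preserving deduplication (the
    first-seen casing wins; comparison is case-insensitive).  The symbol
    itself is always included among its synonyms.  Synonyms string-identical
    (case-insensitively) to any disease name are eliminated; if that empties
    a symbol's synonym set, the symbol is retained with itself as the only
    synonym and a warning is logged.  Ambiguity classes are then computed.
    Deterministic and order-independent across source tables.
    """
    raw: dict[str, dict[str, str]] = defaultdict(dict)  # symbol -> lower -> cased
    frames = []
    for tab in source_tables:
        if isinstance(tab, pd.DataFrame):
            frames.append(tab)
        else:
            frames.append(pd.read_csv(tab, sep="\t", dtype=str))
    for frame in frames:
        for symbol, synonym in zip(frame["symbol"], frame["synonym"]):
            if not symbol or pd.isna(symbol):
                raise ValueError("empty gene symbol in source table")
            if pd.isna(synonym) or not str(synonym):
                continue
            raw[str(symbol)].setdefault(str(synonym).lower(), str(synonym))
    for symbol in list(raw):
        raw[symbol].setdefault(symbol.lower(), symbol)

    disease_lower = (
        {n.lower() for n in disease_names.all_names()} if disease_names else set()
    )
    per_symbol: dict[str, list[str]] = {}
    for symbol in sorted(raw):
        kept = [
            cased
            for low, cased in sorted(raw[symbol].items())
            if low not in disease_lower
        ]
        if not kept:
            warnings.warn(
                f"all synonyms of {symbol!r} were disease names; "
                "retaining the symbol itself",
                stacklevel=2,
            )
            kept = [symbol]
        per_symbol[symbol] = kept

    # class computation
    syn_to_symbols: dict[str, set[str]] = defaultdict(set)
    for symbol, syns in per_symbol.items():
        for s in syns:
            syn_to_symbols[s.lower()].add(symbol)
    all_synonyms = sorted({s for syns in per_symbol.values() for s in syns})
    symbols_lower = {s.lower() for s in per_symbol}

    entries = []
    for symbol, syns in per_symbol.items():
        for s in syns:
            classes = set()
            if len(syn_to_symbols[s.lower()]) >= 2:
                classes.add("promiscuous")
            if s.lower() in ENGLISH_WORDS:
                classes.add("english")
            if len(s) < 3:
                classes.add("short")
            if any(
                other.lower() != s.lower() and _word_bounded_in(s, other)
                for other in all_synonyms
            ):
                classes.add("nested")
            entries.append(SynonymEntry(symbol=symbol, synonym=s, classes=classes))
    return SynonymDictionary(entries)


# ---------------------------------------------------------------------------
# Safety features (candidate counts, bits, conditional probabilities)

FEATURE_COLUMNS = [
    "total",
    "contribution",
    "n_chars",
    "bits",
    "n_nested",
    "p_syn_given_alt",
    "p_alt_given_syn",
    "is_symbol",
]


def character_frequencies(corpus: Corpus) -> dict[str, float]:
    """Character relative frequencies over the corpus titles and abstracts."""
    counts: Counter[str] = Counter()
    for pub in corpus:
        counts.update(pub.title.lower())
        counts.update(pub.abstract.lower())
    total = sum(counts.values())
    if total == 0:
        return {}
    return {ch: c / total for ch, c in counts.items()}


def _bits(synonym: str, freqs: dict[str, float]) -> float:
    """Summed character information content: sum of -log2 character frequency.

    Characters unseen in the corpus contribute the information of the rarest
    observed character (a finite, conservative surprisal).
    """
    if not freqs:
        return 0.0
    floor = min(freqs.values())
    return float(
        sum(-math.log2(freqs.get(ch, floor)) for ch in synonym.lower())
    )


def compute_safety_features(
    dictionary: SynonymDictionary,
    corpus: Corpus,
    candidate_docs: Mapping[tuple[str, str], set[str]],
) -> pd.DataFrame:
    """Engineered per-synonym safety features.

    ``candidate_docs`` maps (symbol, synonym) to the set of publication ids
    the synonym matched (as produced by entity tagging).  ``total`` is the
    number of distinct publications hit by any synonym of the symbol;
    ``contribution`` the fraction contributed by this synonym; ``bits`` the
    summed character information content under the corpus character
    frequencies; the conditional probabilities are estimated over candidate
    documents only (probability that a candidate document of this synonym
    also mentions another synonym of the same symbol, and vice versa).
    """
    freqs = character_frequencies(corpus)
    nested_counts: dict[tuple[str, str], int] = {}
    all_syns = sorted({e.synonym for e in dictionary})
    for e in dictionary:
        nested_counts[(e.symbol, e.synonym)] = sum(
            1
            for other in all_syns
            if other.lower() != e.synonym.lower()
            and _word_bounded_in(e.synonym, other)
        )

    rows = []
    for symbol in dictionary.symbols():
        entries = dictionary.synonyms_of(symbol)
        docs_by_syn = {
            e.synonym: set(candidate_docs.get((symbol, e.synonym), set()))
            for e in entries
        }
        symbol_docs: set[str] = set().union(*docs_by_syn.values()) if docs_by_syn else set()
        total = len(symbol_docs)
        for e in entries:
            own = docs_by_syn[e.synonym]
            alt: set[str] = set().union(
                *(d for s, d in docs_by_syn.items() if s != e.synonym)
            ) if len(docs_by_syn) > 1 else set()
            if total == 0:
                warnings.warn(
                    f"no candidate documents for symbol {symbol!r}; "
                    "contribution and probabilities set to 0",
                    stacklevel=2,
                )
                contribution = p_sga = p_ags = 0.0
            else:
                contribution = len(own) / total
                p_sga = len(own & alt) / len(alt) if alt else 0.0
                p_ags = len(own & alt) / len(own) if own else 0.0
            rows.append(
                {
                    "symbol": symbol,
                    "synonym": e.synonym,
                    "total": total,
                    "contribution": contribution,
                    "n_chars": len(e.synonym),
                    "bits": _bits(e.synonym, freqs),
                    "n_nested": nested_counts[(symbol, e.synonym)],
                    "p_syn_given_alt": p_sga,
                    "p_alt_given_syn": p_ags,
                    "is_symbol": float(e.synonym.lower() == symbol.lower()),
                }
            )
    return pd.DataFrame(rows)


def train_safety_ensemble(
    features: pd.DataFrame,
    dictionary: SynonymDictionary,
    n_iterations: int = 5,
    seed: int = 0,
    known_labels: Mapping[tuple[str, str], str] | None = None,
) -> PUBagEnsemble:
    """Train the PU random-forest over synonym features.

    The initial positive (unsafe) class is the union of English, short and
    promiscuous synonyms; everything else is unlabelled.  The ensemble runs
    for five iterations with a random-forest base model.  ``known_labels``
    optionally merges externally curated (symbol, synonym) -> 'unsafe'|'safe'
    decisions into the positive / known-negative pools, standing in for the
    interactive relabelling rounds.
    """
    known_labels = dict(known_labels or {})
    x = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    keys = list(zip(features["symbol"], features["synonym"]))
    by_key = {k: i for i, k in enumerate(keys)}
    pos, neg = set(), set()
    for e in dictionary:
        k = (e.symbol, e.synonym)
        if k not in by_key:
            continue
        if known_labels.get(k) == "unsafe":
            pos.add(by_key[k])
        elif known_labels.get(k) == "safe":
            neg.add(by_key[k])
        elif e.classes & {"english", "short", "promiscuous"}:
            pos.add(by_key[k])
    unlab = [i for i in range(len(keys)) if i not in pos and i not in neg]
    return pu_bag_train(
        x,
        positives=sorted(pos),
        unlabelled=unlab,
        n_iterations=n_iterations,
        base_model="random_forest",
        known_negatives=sorted(neg) or None,
        seed=seed,
    )


def classify_unsafe(
    features: pd.DataFrame,
    dictionary: SynonymDictionary,
    ensemble: PUBagEnsemble | None,
    threshold: float = 0.5,
) -> SynonymDictionary:
    """Label every synonym safe/unsafe by the four disjunctive rules.

    A synonym is unsafe iff (i) it is an English word, (ii) it has fewer
    than three characters, (iii) the classifier score exceeds ``threshold``,
    or (iv) it is promiscuous.  Rules (i), (ii) and (iv) are classifier-
    independent.  A synonym with no feature row is labelled unsafe
    (conservative) with a warning.
    """
    keys = list(zip(features["symbol"], features["synonym"]))
    by_key = {k: i for i, k in enumerate(keys)}
    scores = np.full(len(keys), np.nan)
    if ensemble is not None:
        for pos, idx in enumerate(ensemble.unlabelled):
            scores[idx] = ensemble.scores[pos]

    out = []
    for e in dictionary:
        k = (e.symbol, e.synonym)
        classes = set(e.classes)
        if k not in by_key:
            warnings.warn(
                f"missing features for {k!r}; labelled unsafe", stacklevel=2
            )
            out.append(
                SynonymEntry(e.symbol, e.synonym, classes, "unsafe", float("nan"))
            )
            continue
        score = scores[by_key[k]]
        unsafe = (
            "english" in classes
            or "short" in classes
            or "promiscuous" in classes
            or (not math.isnan(score) and score > threshold)
        )
        out.append(
            SynonymEntry(
                e.symbol,
                e.synonym,
                classes,
                "unsafe" if unsafe else "safe",
                float(score),
            )
        )
    return SynonymDictionary(out)
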