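"""Text preprocessing, TF-IDF vectorisation and positive-unlabelled bagging.

The preprocessing dialect applies seven steps in a fixed order: (i) removal
of non-alphanumeric characters, (ii) whitespace tokenisation, (iii) stop-word
deletion, (iv) lower-casing, (v) deletion of tokens shorter than three
characters, (vi) deletion of integer tokens, (vii) stemming.  The stemmer is
a Porter-style English stemmer whose conformance anchor is the family
'disambiguated' / 'disambiguations' / 'disambiguating' -> 'disambiguat'
(see docs/methods.md for the one rule where it departs from textbook Porter).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV

logger = logging.getLogger("litmine")

__all__ = [
    "STOPWORDS",
    "ENGLISH_WORDS",
    "porter_stem",
    "preprocess",
    "DocTermMatrix",
    "TfidfModel",
    "fit_vectorizer",
    "PUBagEnsemble",
    "pu_bag_train",
    "tune_base_model",
]


def _load_wordfile(name: str) -> frozenset[str]:
    text = resources.files("litmine.data").joinpath(name).read_text("utf-8")
    return frozenset(w.strip() for w in text.split() if w.strip())


#: Frozen English stop-word list bundled with the package.
STOPWORDS: frozenset[str] = _load_wordfile("stopwords.txt")

#: Frozen common-English word list (spell-checker style core vocabulary).
ENGLISH_WORDS: frozenset[str] = _load_wordfile("english_words.txt")


# ---------------------------------------------------------------------------
# Porter-style stemmer

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        vowel = not _is_cons(stem, i)
        if prev_vowel and not vowel:
            m += 1
        prev_vowel = vowel
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]
_STEP2.sort(key=lambda p: -len(p[0]))

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP3.sort(key=lambda p: -len(p[0]))

# Step 4: suffix -> replacement.  Textbook Porter deletes 'ate'; this dialect
# rewrites it to 'at' so that the whole 'disambiguat*' family collapses onto
# 'disambiguat' (the conformance anchor) instead of 'disambigu'.
_STEP4 = [
    ("ement", ""), ("ance", ""), ("ence", ""), ("able", ""), ("ible", ""),
    ("ment", ""), ("ion", None), ("ent", ""), ("ism", ""), ("ate", "at"),
    ("iti", ""), ("ous", ""), ("ive", ""), ("ize", ""), ("al", ""),
    ("er", ""), ("ic", ""), ("ou", ""), ("ant", ""),
]
_STEP4.sort(key=lambda p: -len(p[0]))


def porter_stem(word: str) -> str:
    """Stem a lowercase token with the package's Porter-style dialect."""
    if len(word) <= 2:
        return word

    # Step 1a
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith("ies"):
        word = word[:-2]
    elif word.endswith("ss"):
        pass
    elif word.endswith("s"):
        word = word[:-1]

    # Step 1b
    recode = False
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            word = word[:-1]
    elif word.endswith("ed") and _has_vowel(word[:-2]):
        word = word[:-2]
        recode = True
    elif word.endswith("ing") and _has_vowel(word[:-3]):
        word = word[:-3]
        recode = True
    if recode:
        if word.endswith(("at", "bl", "iz")):
            word += "e"
        elif _ends_double_cons(word) and word[-1] not in "lsz":
            word = word[:-1]
        elif _measure(word) == 1 and _ends_cvc(word):
            word += "e"

    # Step 1c
    if word.endswith("y") and _has_vowel(word[:-1]):
        word = word[:-1] + "i"

    # Step 2
    for suffix, repl in _STEP2:
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if _measure(stem) > 0:
                word = stem + repl
            break

    # Step 3
    for suffix, repl in _STEP3:
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if _measure(stem) > 0:
                word = stem + repl
            break

    # Step 4
    for suffix, repl in _STEP4:
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion":
                    if stem and stem[-1] in "st":
                        word = stem
                else:
                    word = stem + repl
            break

    # Step 5a
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            word = stem

    # Step 5b
    if word.endswith("ll") and _measure(word) > 1:
        word = word[:-1]

    return word


def _stem_fixpoint(word: str) -> str:
    """Apply the stemmer until stable.

    Porter-style stemming is not idempotent on its own output (a stem ending
    in 's' would lose it on a second pass); stemming to the fixed point makes
    preprocessing a projection, so running it twice changes nothing.
    """
    while True:
        stemmed = porter_stem(word)
        if stemmed == word:
            return word
        word = stemmed


# ---------------------------------------------------------------------------
# Seven-step preprocessing

_NONALNUM_RE = re.compile(r"[^0-9A-Za-z]+")


def preprocess(text: str) -> list[str]:
    """Apply the seven preprocessing steps in order, returning a token stream.

    The output upholds the token-stream invariants (no token shorter than
    three characters, no integer token, no stop word), re-applying the
    length/integer/stop-word filters after stemming since stemming can
    shorten a token below three characters.  Idempotent on its own output.
    """
    cleaned = _NONALNUM_RE.sub(" ", text)                       # (i)
    tokens = cleaned.split()                                    # (ii)
    tokens = [t for t in tokens if t.lower() not in STOPWORDS]  # (iii)
    tokens = [t.lower() for t in tokens]                        # (iv)
    tokens = [t for t in tokens if len(t) >= 3]                 # (v)
    tokens = [t for t in tokens if not t.isdigit()]             # (vi)
    tokens = [_stem_fixpoint(t) for t in tokens]                # (vii)
    return [
        t for t in tokens
        if len(t) >= 3 and not t.isdigit() and t not in STOPWORDS
    ]


# ---------------------------------------------------------------------------
# TF-IDF over 1..4-grams

TokenStream = Sequence[str]


def _ngrams(tokens: TokenStream, nmax: int = 4) -> list[str]:
    out = []
    for n in range(1, nmax + 1):
        for i in range(len(tokens) - n + 1):
            out.append(" ".join(tokens[i : i + n]))
    return out


@dataclass
class DocTermMatrix:
    """TF-IDF weighted documents x n-grams matrix with its vocabulary."""

    matrix: sp.csr_matrix
    vocabulary: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def save(self, vocab_path, matrix_path) -> None:
        """Persist as a vocabulary TSV plus MatrixMarket sparse triplets."""
        from pathlib import Path
        from scipy.io import mmwrite

        with Path(vocab_path).open("w", encoding="utf-8") as fh:
            for j, term in enumerate(self.vocabulary):
                fh.write(f"{j}\t{term}\n")
        mmwrite(str(matrix_path), self.matrix)


class TfidfModel:
    """N-gram (1..4) TF-IDF vectoriser with the corpus filtering rules.

    A retained n-gram must occur at least twice in the whole corpus and have
    a document frequency below 0.6.  The IDF convention is smoothed add-one:
    idf(t) = ln((1 + N) / (1 + df(t))) + 1, with raw term counts and L2 row
    normalisation.  Transforming unseen documents uses the fitted vocabulary
    only.
    """

    def __init__(self, nmax: int = 4, min_count: int = 2, max_df: float = 0.6):
        self.nmax = nmax
        self.min_count = min_count
        self.max_df = max_df
        self.vocabulary_: dict[str, int] | None = None
        self._tfidf = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False)

    def _count(self, docs: Sequence[TokenStream], vocab: dict[str, int]) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for i, doc in enumerate(docs):
            counts: dict[int, int] = {}
            for gram in _ngrams(doc, self.nmax):
                j = vocab.get(gram)
                if j is not None:
                    counts[j] = counts.get(j, 0) + 1
            rows.extend([i] * len(counts))
            cols.extend(counts.keys())
            vals.extend(counts.values())
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(docs), len(vocab)), dtype=np.float64
        )

    def fit(self, docs: Sequence[TokenStream]) -> DocTermMatrix:
        if len(docs) == 0:
            raise ValueError("at least one document required")
        total: dict[str, int] = {}
        df: dict[str, int] = {}
        for doc in docs:
            grams = _ngrams(doc, self.nmax)
            for g in grams:
                total[g] = total.get(g, 0) + 1
            for g in set(grams):
                df[g] = df.get(g, 0) + 1
        n = len(docs)
        kept = sorted(
            g for g, c in total.items()
            if c >= self.min_count and df[g] / n < self.max_df
        )
        if not kept:
            raise ValueError("empty vocabulary")
        self.vocabulary_ = {g: j for j, g in enumerate(kept)}
        counts = self._count(docs, self.vocabulary_)
        matrix = self._tfidf.fit_transform(counts)
        return DocTermMatrix(matrix.tocsr(), kept)

    def transform(self, docs: Sequence[TokenStream]) -> sp.csr_matrix:
        if self.vocabulary_ is None:
            raise RuntimeError("vectoriser not fitted")
        return self._tfidf.transform(self._count(docs, self.vocabulary_)).tocsr()


def fit_vectorizer(docs: Sequence[TokenStream], nmax: int = 4) -> tuple[DocTermMatrix, TfidfModel]:
    """Fit the n-gram TF-IDF vectoriser; returns the matrix and the reusable model."""
    model = TfidfModel(nmax=nmax)
    dtm = model.fit(docs)
    return dtm, model


# ---------------------------------------------------------------------------
# Positive-unlabelled bagging (Mordelet & Vert style)

_BASE_MODELS: dict[str, Callable[[int], object]] = {
    "logistic": lambda rs: LogisticRegression(
        max_iter=2000, class_weight="balanced", random_state=rs
    ),
    "random_forest": lambda rs: RandomForestClassifier(
        n_estimators=100, class_weight="balanced", random_state=rs
    ),
}


@dataclass
class PUBagEnsemble:
    """Bagged PU classifier: mean held-out membership score per unlabelled example."""

    members: list = field(default_factory=list)
    n_iterations: int = 0
    base_model: str = "logistic"
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    unlabelled: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def score_of(self, index: int) -> float:
        pos = np.flatnonzero(self.unlabelled == index)
        if pos.size == 0:
            raise KeyError(index)
        return float(self.scores[pos[0]])


def pu_bag_train(
    features,
    positives: Sequence[int],
    unlabelled: Sequence[int],
    n_iterations: int = 50,
    base_model: str = "logistic",
    known_negatives: Sequence[int] | None = None,
    seed: int = 0,
    bootstrap_size: int | None = None,
) -> PUBagEnsemble:
    """Train a bagged positive-unlabelled ensemble.

    Each iteration draws a bootstrap of the unlabelled set as provisional
    negatives (plus any known negatives), fits the base model with balanced
    class weights, and scores the unlabelled examples held out of the
    bootstrap.  The final score of an unlabelled example is the mean over
    the iterations in which it was held out; an example never held out falls
    back to the mean over all members, with a warning.  The bootstrap size
    defaults to the size of the positive set (balanced bags).
    """
    positives = np.asarray(list(positives), dtype=int)
    unlabelled = np.asarray(list(unlabelled), dtype=int)
    known_negatives = (
        np.asarray(list(known_negatives), dtype=int)
        if known_negatives is not None
        else np.empty(0, dtype=int)
    )
    if positives.size == 0:
        raise ValueError("positives must be nonempty")
    if unlabelled.size == 0:
        raise ValueError("unlabelled must be nonempty")
    if np.intersect1d(positives, unlabelled).size:
        raise ValueError("positives and unlabelled must be disjoint")
    if base_model not in _BASE_MODELS:
        raise ValueError(f"unknown base model {base_model!r}")

    rng = np.random.default_rng(seed)
    k = bootstrap_size if bootstrap_size is not None else positives.size
    n_u = unlabelled.size

    held_sum = np.zeros(n_u)
    held_cnt = np.zeros(n_u, dtype=int)
    full_sum = np.zeros(n_u)
    members = []
    y_template = np.concatenate(
        [
            np.ones(positives.size),
            np.zeros(k + known_negatives.size),
        ]
    )
    for _ in range(n_iterations):
        boot_pos = rng.integers(0, n_u, size=k)
        boot = unlabelled[boot_pos]
        train_idx = np.concatenate([positives, boot, known_negatives])
        model = clone(_BASE_MODELS[base_model](int(rng.integers(0, 2**31 - 1))))
        model.fit(features[train_idx], y_template)
        members.append(model)
        probs = model.predict_proba(features[unlabelled])[:, 1]
        full_sum += probs
        held = np.ones(n_u, dtype=bool)
        held[boot_pos] = False
        held_sum[held] += probs[held]
        held_cnt[held] += 1

    scores = np.where(held_cnt > 0, held_sum / np.maximum(held_cnt, 1), 0.0)
    never = held_cnt == 0
    if never.any():
        warnings.warn(
            f"{int(never.sum())} unlabelled example(s) never held out; "
            "falling back to the full-ensemble mean score",
            stacklevel=2,
        )
        logger.warning("%d unlabelled examples never held out", int(never.sum()))
        scores[never] = full_sum[never] / n_iterations

    return PUBagEnsemble(
        members=members,
        n_iterations=n_iterations,
        base_model=base_model,
        scores=scores,
        unlabelled=unlabelled,
    )


def tune_base_model(features, labels, base_model: str = "logistic", grid: dict | None = None, cv: int = 3):
    """Select base-model hyper-parameters by threefold CV on weighted F1.

    A documented small default grid is used when none is given; the full
    sweep of alternative classifier families is configuration, not default.
    """
    if grid is None:
        grid = (
            {"C": [0.1, 1.0, 10.0]}
            if base_model == "logistic"
            else {"n_estimators": [100, 200], "min_samples_leaf": [2, 6]}
        )
    search = GridSearchCV(
        _BASE_MODELS[base_model](0), grid, scoring="f1_weighted", cv=cv
    )
    search.fit(features, labels)
    return search.best_estimator_, search.best_params_, float(search.best_score_)
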