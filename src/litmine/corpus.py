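"""Publication corpus data model and readers/writers.

The corpus is an in-process store of publication records (title, abstract,
keywords, year, review/trial flags, affiliations, pharma class) together with
a directed citation graph.  Two on-disk dialects are supported: a
PubMed-baseline-style XML subset and a line-delimited JSON record dialect.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

__all__ = [
    "PharmaClass",
    "Publication",
    "Corpus",
    "CitationGraph",
    "OrganisationList",
    "read_corpus",
    "write_corpus",
    "read_edge_list",
    "build_citation_graph",
    "tag_affiliations",
]


class PharmaClass(str, Enum):
    """Pharmaceutical-affiliation class of a publication."""

    NONE = "none"
    BIG = "big"
    MEDIUM = "medium"


@dataclass(frozen=True)
class Publication:
    """One literature record.

    ``year`` is the calendar year of publication; dates are reduced to years
    because all downstream series are per calendar year.
    """

    pub_id: str
    title: str = ""
    abstract: str = ""
    keywords: tuple[str, ...] = ()
    year: int = 1900
    is_review: bool = False
    is_trial: bool = False
    affiliations: tuple[str, ...] = ()
    pharma_class: PharmaClass = PharmaClass.NONE

    def __post_init__(self) -> None:
        if not self.pub_id:
            raise ValueError("pub_id must be non-empty")
        if not 1800 <= self.year <= 2100:
            raise ValueError(f"year {self.year} outside [1800, 2100]")

    @property
    def text(self) -> str:
        """Searchable text: title, abstract and keywords.

        Keywords are joined with ' ; ' so that no synonym pattern can match
        across a keyword boundary (the separator is not in the fuzzy
        separator class).
        """
        return " ; ".join([self.title, self.abstract, *self.keywords])


class Corpus:
    """A collection of publications keyed by ``pub_id``."""

    def __init__(self, publications: Iterable[Publication] = ()) -> None:
        self._pubs: dict[str, Publication] = {}
        for pub in publications:
            self.add(pub)

    def add(self, pub: Publication) -> None:
        if pub.pub_id in self._pubs:
            raise ValueError(f"duplicate pub_id {pub.pub_id!r}")
        self._pubs[pub.pub_id] = pub

    def __len__(self) -> int:
        return len(self._pubs)

    def __iter__(self) -> Iterator[Publication]:
        return iter(self._pubs.values())

    def __contains__(self, pub_id: str) -> bool:
        return pub_id in self._pubs

    def __getitem__(self, pub_id: str) -> Publication:
        return self._pubs[pub_id]

    def ids(self) -> list[str]:
        return list(self._pubs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._pubs == other._pubs


@dataclass
class CitationGraph:
    """Directed citations: edges are (citing pub_id, cited pub_id)."""

    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = {e for e in self.edges if e[0] != e[1]}

    def cited_by(self) -> dict[str, set[str]]:
        """Map citing pub_id -> set of cited pub_ids."""
        out: dict[str, set[str]] = {}
        for citing, cited in self.edges:
            out.setdefault(citing, set()).add(cited)
        return out

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class OrganisationList:
    """Organisation names with pharma-size labels (big: >100 patents)."""

    entries: dict[str, str] = field(default_factory=dict)  # name -> big|medium

    def __post_init__(self) -> None:
        for name, size in self.entries.items():
            if not name:
                raise ValueError("organisation name must be non-empty")
            if size not in ("big", "medium"):
                raise ValueError(f"unknown size class {size!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrganisationList":
        entries: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            name, size = line.split("\t")
            entries[name] = size
        return cls(entries)


# ---------------------------------------------------------------------------
# Readers / writers


def _pub_to_json(pub: Publication) -> dict:
    return {
        "pub_id": pub.pub_id,
        "title": pub.title,
        "abstract": pub.abstract,
        "keywords": list(pub.keywords),
        "year": pub.year,
        "is_review": pub.is_review,
        "is_trial": pub.is_trial,
        "affiliations": list(pub.affiliations),
        "pharma_class": pub.pharma_class.value,
    }


def _pub_from_json(rec: dict, index: int) -> Publication:
    try:
        return Publication(
            pub_id=str(rec["pub_id"]),
            title=rec.get("title", ""),
            abstract=rec.get("abstract", ""),
            keywords=tuple(rec.get("keywords", ())),
            year=int(rec.get("year", 1900)),
            is_review=bool(rec.get("is_review", False)),
            is_trial=bool(rec.get("is_trial", False)),
            affiliations=tuple(rec.get("affiliations", ())),
            pharma_class=PharmaClass(rec.get("pharma_class", "none")),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed record {index}: {exc}") from exc


_REVIEW_TYPES = {"review", "systematic review"}
_TRIAL_TYPES = {"clinical trial", "randomized controlled trial"}


def _read_xml(path: Path) -> Corpus:
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        return Corpus()
    root = etree.fromstring(text.encode("utf-8"))
    pubs = []
    for index, art in enumerate(root.iter("PubmedArticle")):
        pmid = art.findtext(".//PMID")
        if pmid is None or not pmid.strip():
            raise ValueError(f"malformed record {index}: missing PMID")
        year_text = art.findtext(".//PubDate/Year")
        if year_text is None:
            raise ValueError(f"malformed record {index}: missing PubDate/Year")
        ptypes = {
            (el.text or "").strip().lower()
            for el in art.iter("PublicationType")
        }
        pubs.append(
            Publication(
                pub_id=pmid.strip(),
                title=art.findtext(".//ArticleTitle") or "",
                abstract=art.findtext(".//AbstractText") or "",
                keywords=tuple(
                    (el.text or "") for el in art.iter("Keyword")
                ),
                year=int(year_text),
                is_review=bool(ptypes & _REVIEW_TYPES),
                is_trial=bool(ptypes & _TRIAL_TYPES),
                affiliations=tuple(
                    (el.text or "") for el in art.iter("Affiliation")
                ),
            )
        )
    return Corpus(pubs)


def _write_xml(corpus: Corpus, path: Path) -> None:
    root = etree.Element("PubmedArticleSet")
    for pub in corpus:
        art = etree.SubElement(root, "PubmedArticle")
        etree.SubElement(art, "PMID").text = pub.pub_id
        etree.SubElement(art, "ArticleTitle").text = pub.title
        etree.SubElement(art, "AbstractText").text = pub.abstract
        date = etree.SubElement(art, "PubDate")
        etree.SubElement(date, "Year").text = str(pub.year)
        for kw in pub.keywords:
            etree.SubElement(art, "Keyword").text = kw
        for aff in pub.affiliations:
            etree.SubElement(art, "Affiliation").text = aff
        if pub.is_review:
            etree.SubElement(art, "PublicationType").text = "Review"
        if pub.is_trial:
            etree.SubElement(art, "PublicationType").text = "Clinical Trial"
    path.write_bytes(etree.tostring(root, pretty_print=True))


def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Read a corpus from ``path`` in the named dialect ('xml' or 'jsonl').

    Missing abstract/keywords become empty.  Note the XML dialect does not
    carry the pharma class (it is derived by :func:`tag_affiliations`), so
    round-trip identity through XML holds for untagged corpora.
    """
    path = Path(path)
    if format == "xml":
        return _read_xml(path)
    if format != "jsonl":
        raise ValueError(f"unknown format {format!r}")
    pubs = []
    with path.open(encoding="utf-8") as fh:
        for index, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"malformed record {index}: {exc}") from exc
            pubs.append(_pub_from_json(rec, index))
    return Corpus(pubs)


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    path = Path(path)
    if format == "xml":
        _write_xml(corpus, path)
        return
    if format != "jsonl":
        raise ValueError(f"unknown format {format!r}")
    with path.open("w", encoding="utf-8") as fh:
        for pub in corpus:
            fh.write(json.dumps(_pub_to_json(pub)) + "\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (citing, cited) TSV edge list."""
    edges = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}")
        edges.append((parts[0].strip(), parts[1].strip()))
    return edges


def build_citation_graph(edge_list: str | Path | list[tuple[str, str]], corpus: Corpus) -> CitationGraph:
    """Build a citation graph restricted to publications present in ``corpus``.

    Duplicate edges are collapsed and self-loops dropped.
    """
    if isinstance(edge_list, (str, Path)):
        edge_list = read_edge_list(edge_list)
    edges = {
        (citing, cited)
        for citing, cited in edge_list
        if citing != cited and citing in corpus and cited in corpus
    }
    return CitationGraph(edges)


# ---------------------------------------------------------------------------
# Affiliation tagging

_NORM_RE = re.compile(r"[^0-9a-z]+")


def _norm_tokens(text: str) -> list[str]:
    """Case-fold and strip punctuation, returning the token sequence."""
    return [t for t in _NORM_RE.split(text.lower()) if t]


def _contains_tokens(haystack: list[str], needle: list[str]) -> bool:
    """Token-bounded substring: needle tokens appear contiguously in haystack."""
    n = len(needle)
    if n == 0:
        return False
    return any(haystack[i : i + n] == needle for i in range(len(haystack) - n + 1))


def tag_affiliations(corpus: Corpus, orgs: OrganisationList) -> Corpus:
    """Assign a pharma class to every publication from its affiliations.

    A publication is 'big' if any affiliation contains a big-pharma
    organisation name as a token-bounded substring (case-insensitive,
    punctuation-stripped); otherwise 'medium' if a medium name matches;
    otherwise 'none'.  Big takes precedence over medium.  Idempotent.
    """
    big = [_norm_tokens(n) for n, s in orgs.entries.items() if s == "big"]
    medium = [_norm_tokens(n) for n, s in orgs.entries.items() if s == "medium"]
    tagged = []
    for pub in corpus:
        toks = [_norm_tokens(aff) for aff in pub.affiliations]
        if any(_contains_tokens(t, b) for t in toks for b in big):
            cls = PharmaClass.BIG
        elif any(_contains_tokens(t, m) for t in toks for m in medium):
            cls = PharmaClass.MEDIUM
        else:
            cls = PharmaClass.NONE
        tagged.append(replace(pub, pharma_class=cls))
    return Corpus(tagged)
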