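"""Entity tagging: fuzzy synonym patterns and candidate-publication lookup.

Synonym matching is case-insensitive, treats '', '-', ' ' and '/' between
alphanumeric runs as equivalent separators (so 'ErbB-1' matches 'erbB1',
'ERBB1' and 'ErbB 1'), and uses lookarounds so a match can never start or
end inside a longer alphanumeric token ('STAR' does not match inside
'START').  When two dictionary synonyms are nested, only the longer one is
credited at a given span — 'insulin' is not credited inside a matched
'insulin receptor'.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .corpus import Corpus
from .lexicon import DiseaseDictionary, SynonymDictionary

__all__ = ["Mention", "MentionIndex", "compile_pattern", "find_candidates"]

_RUN_RE = re.compile(r"[0-9A-Za-z]+")
_SEPARATOR = r"[-/ ]?"


def compile_pattern(synonym: str) -> re.Pattern:
    """Compile a fuzzy, boundary-guarded matcher for one synonym.

    The synonym is split into alphanumeric runs; any single separator from
    {'', '-', ' ', '/'} is accepted between runs.  Lookarounds enforce word
    boundaries on both sides.
    """
    runs = _RUN_RE.findall(synonym)
    if not runs:
        raise ValueError(f"synonym {synonym!r} has no alphanumeric content")
    body = _SEPARATOR.join(re.escape(run) for run in runs)
    return re.compile(
        r"(?<![0-9A-Za-z])" + body + r"(?![0-9A-Za-z])", re.IGNORECASE
    )


@dataclass(frozen=True)
class Mention:
    entity_id: str
    pub_id: str
    synonym: str
    start: int
    end: int
    safety: str


@dataclass
class MentionIndex:
    """Credited synonym matches per (entity, publication)."""

    mentions: list[Mention] = field(default_factory=list)

    def safe_counts(self) -> dict[tuple[str, str], int]:
        """Per (entity_id, pub_id): number of distinct safe synonyms matched."""
        out: dict[tuple[str, str], set[str]] = {}
        for m in self.mentions:
            if m.safety == "safe":
                out.setdefault((m.entity_id, m.pub_id), set()).add(m.synonym.lower())
        return {k: len(v) for k, v in out.items()}

    def candidate_docs(self) -> dict[tuple[str, str], set[str]]:
        """Per (entity_id, synonym): set of publication ids matched."""
        out: dict[tuple[str, str], set[str]] = {}
        for m in self.mentions:
            out.setdefault((m.entity_id, m.synonym), set()).add(m.pub_id)
        return out

    def docs_of(self, entity_id: str) -> set[str]:
        return {m.pub_id for m in self.mentions if m.entity_id == entity_id}

    def safe_docs_of(self, entity_id: str) -> set[str]:
        return {
            m.pub_id
            for m in self.mentions
            if m.entity_id == entity_id and m.safety == "safe"
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entity_id": [m.entity_id for m in self.mentions],
                "pub_id": [m.pub_id for m in self.mentions],
                "synonym": [m.synonym for m in self.mentions],
                "start": [m.start for m in self.mentions],
                "end": [m.end for m in self.mentions],
                "safety": [m.safety for m in self.mentions],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _dictionary_synonyms(
    dictionary: SynonymDictionary | DiseaseDictionary,
) -> list[tuple[str, str, str]]:
    """Flatten a dictionary into (entity_id, synonym, safety) triples."""
    if isinstance(dictionary, DiseaseDictionary):
        return [
            (tid, name, "safe")
            for tid, names in dictionary.names.items()
            for name in names
        ]
    return [(e.symbol, e.synonym, e.safety) for e in dictionary]


def find_candidates(
    corpus: Corpus,
    dictionary: SynonymDictionary | DiseaseDictionary,
    entity: str | None = None,
) -> MentionIndex:
    """Scan title+abstract+keywords of every publication for synonym matches.

    Returns all credited matches with spans and safety labels.  Credit is
    longest-match exclusive across the whole dictionary: a match whose span
    is strictly contained in another credited match's span is dropped; two
    synonyms matching the same exact span (promiscuous synonyms) are both
    credited.  ``entity=None`` scans for every entity in the dictionary.
    """
    triples = _dictionary_synonyms(dictionary)
    if entity is not None:
        triples = [t for t in triples if t[0] == entity]
        if not triples:
            raise KeyError(f"entity {entity!r} not in dictionary")
    compiled = [
        (eid, syn, safety, compile_pattern(syn)) for eid, syn, safety in triples
    ]
    mentions: list[Mention] = []
    for pub in corpus:
        text = pub.text
        raw: list[Mention] = []
        for eid, syn, safety, pat in compiled:
            for m in pat.finditer(text):
                raw.append(Mention(eid, pub.pub_id, syn, m.start(), m.end(), safety))
        if not raw:
            continue
        spans = {(m.start, m.end) for m in raw}
        for m in raw:
            if any(
                (s <= m.start and m.end <= e) and (s, e) != (m.start, m.end)
                for s, e in spans
            ):
                continue  # strictly nested inside a longer credited match
            mentions.append(m)
    return MentionIndex(mentions)
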