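"""Shared fixtures: small corpora and planted worlds reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from litmine import Corpus, Publication, gen_field_corpus


@pytest.fixture()
def tiny_corpus() -> Corpus:
    return Corpus(
        [
            Publication(
                pub_id="1",
                title="Steroidogenic Acute Regulatory Protein and STAR",
                abstract="The STAR gene regulates steroid synthesis.",
                keywords=("steroid", "mitochondria"),
                year=2001,
            ),
            Publication(
                pub_id="2",
                title="A star is born",
                abstract="Astrophysics of stellar formation.",
                year=2005,
            ),
            Publication(
                pub_id="3",
                title="Insulin receptor signalling",
                abstract="Insulin binds the insulin receptor.",
                year=2010,
                is_review=True,
            ),
        ]
    )


@pytest.fixture(scope="session")
def planted_world():
    """One deterministic planted-field world shared by the slower tests."""
    return gen_field_corpus(0)


def random_corpus(rng: np.random.Generator, n: int) -> Corpus:
    """A small random corpus for round-trip and oracle tests."""
    words = ["alpha", "beta", "gamma", "delta", "kinase", "receptor", "cell"]
    pubs = []
    for i in range(n):
        pubs.append(
            Publication(
                pub_id=f"P{i}",
                title=" ".join(rng.choice(words, size=rng.integers(1, 5))),
                abstract=" ".join(rng.choice(words, size=rng.integers(0, 8))),
                keywords=tuple(rng.choice(words, size=rng.integers(0, 3))),
                year=int(rng.integers(1950, 2021)),
                is_review=bool(rng.random() < 0.2),
                is_trial=bool(rng.random() < 0.1),
                affiliations=tuple(
                    rng.choice(["BigCo Ltd", "Uni X", "MedCo"], size=rng.integers(0, 2))
                ),
            )
        )
    return Corpus(pubs)
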