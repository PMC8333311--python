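"""Gene/disease dictionaries, ambiguity classes and unsafe classification."""

import numpy as np
import pandas as pd
import pytest

from litmine import (
    Corpus,
    Publication,
    build_disease_dictionary,
    build_gene_dictionary,
    classify_unsafe,
    compute_safety_features,
    find_candidates,
)
from litmine.lexicon import reverse_comma_name


def table(rows):
    frame = pd.DataFrame(rows, columns=["symbol", "synonym"])
    frame["source"] = "test"
    return frame


class TestGeneDictionary:
    def test_disease_identical_synonym_removed(self):
        diseases = build_disease_dictionary(
            {"terms": [{"id": "D1", "name": "Li Fraumeni syndrome", "parents": []}]}
        )
        d = build_gene_dictionary(
            [table([("TP53", "Li Fraumeni syndrome"), ("TP53", "p53")])], diseases
        )
        syns = {e.synonym for e in d.synonyms_of("TP53")}
        assert "Li Fraumeni syndrome" not in syns
        assert {"p53", "TP53"} <= syns

    def test_nested_class(self):
        d = build_gene_dictionary(
            [table([("INS", "insulin"), ("INSR", "insulin receptor")])]
        )
        assert "nested" in d.entry("INS", "insulin").classes
        assert "nested" not in d.entry("INSR", "insulin receptor").classes

    def test_promiscuous_class(self):
        symbols = ["NR2F2", "ACTR1A", "ACTR1B", "ANGPTL1", "APOBEC2", "ARFRP1", "PITX2"]
        d = build_gene_dictionary([table([(s, "ARP1") for s in symbols])])
        for s in symbols:
            assert "promiscuous" in d.entry(s, "ARP1").classes

    def test_english_and_short_classes(self):
        d = build_gene_dictionary([table([("STAR", "STAR"), ("XK", "XK")])])
        assert "english" in d.entry("STAR", "STAR").classes
        assert "short" in d.entry("XK", "XK").classes

    def test_symbol_always_included(self):
        d = build_gene_dictionary([table([("EGFR", "ErbB-1")])])
        assert {e.synonym for e in d.synonyms_of("EGFR")} == {"EGFR", "ErbB-1"}

    def test_source_order_independent(self):
        t1 = table([("A1X", "foo bar")])
        t2 = table([("B2Y", "baz qux")])
        d1 = build_gene_dictionary([t1, t2]).to_frame()
        d2 = build_gene_dictionary([t2, t1]).to_frame()
        pd.testing.assert_frame_equal(d1, d2)

    def test_all_filtered_symbol_retained_with_warning(self):
        diseases = build_disease_dictionary(
            {"terms": [{"id": "D1", "name": "GRIT", "parents": []}]}
        )
        with pytest.warns(UserWarning, match="retaining the symbol"):
            d = build_gene_dictionary([table([("GRIT", "GRIT")])], diseases)
        assert {e.synonym for e in d.synonyms_of("GRIT")} == {"GRIT"}


class TestDiseaseDictionary:
    def test_comma_reversal(self):
        assert reverse_comma_name("Insipidus, Diabetes") == "Diabetes Insipidus"

    def test_no_comma_no_variant(self):
        assert reverse_comma_name("Diabetes Insipidus") is None

    def test_two_commas_full_reversal(self):
        assert reverse_comma_name("Acquired, Insipidus, Diabetes") == (
            "Diabetes Insipidus Acquired"
        )

    def test_variants_stored(self):
        d = build_disease_dictionary(
            {
                "terms": [
                    {
                        "id": "D1",
                        "name": "Insipidus, Diabetes",
                        "synonyms": ["Water Diabetes"],
                        "parents": [],
                    }
                ]
            }
        )
        assert "Diabetes Insipidus" in d.names["D1"]
        assert "Water Diabetes" in d.names["D1"]

    def test_cycle_detection(self):
        export = {
            "terms": [
                {"id": "A", "name": "a", "parents": ["B"]},
                {"id": "B", "name": "b", "parents": ["A"]},
            ]
        }
        with pytest.raises(ValueError, match="cyclic"):
            build_disease_dictionary(export)


class TestSafetyFeatures:
    def _world(self):
        d = build_gene_dictionary(
            [table([("STAR", "Steroidogenic Acute Regulatory Protein"), ("STAR", "STAR")])]
        )
        pubs = [
            Publication(
                pub_id="g1",
                title="Steroidogenic Acute Regulatory Protein (STAR)",
                abstract="steroid transport",
                year=2000,
            ),
        ]
        # many non-gene documents using 'star' in its ordinary sense
        for i in range(8):
            pubs.append(
                Publication(pub_id=f"a{i}", title="a bright star", abstract="sky", year=2000)
            )
        return d, Corpus(pubs)

    def test_conditional_probability_asymmetry(self):
        d, corpus = self._world()
        mentions = find_candidates(corpus, d)
        feats = compute_safety_features(d, corpus, mentions.candidate_docs()).set_index("synonym")
        star = feats.loc["STAR"]
        assert star["p_alt_given_syn"] < star["p_syn_given_alt"]

    def test_contribution_single_synonym(self):
        d = build_gene_dictionary([table([("ABCX1", "ABCX1")])])
        corpus = Corpus(
            [Publication(pub_id="1", title="ABCX1 works", abstract="", year=2000)]
        )
        mentions = find_candidates(corpus, d)
        feats = compute_safety_features(d, corpus, mentions.candidate_docs())
        assert feats.iloc[0]["contribution"] == 1.0
        assert feats.iloc[0]["total"] == 1

    def test_bits_closed_form(self):
        # corpus whose title+abstract characters are exactly 'a' and 'b' once each
        corpus = Corpus([Publication(pub_id="1", title="ab", abstract="", year=2000)])
        d = build_gene_dictionary([table([("AQ1", "a"), ("AQ1", "")])])
        mentions = find_candidates(corpus, d)
        feats = compute_safety_features(d, corpus, mentions.candidate_docs()).set_index("synonym")
        assert feats.loc["a", "bits"] == pytest.approx(1.0)  # -log2(1/2)

    def test_zero_candidates_warns(self):
        d = build_gene_dictionary([table([("QQQX", "QQQX")])])
        corpus = Corpus([Publication(pub_id="1", title="nothing", abstract="", year=2000)])
        with pytest.warns(UserWarning, match="no candidate documents"):
            feats = compute_safety_features(d, corpus, {})
        assert feats.iloc[0]["contribution"] == 0.0


class TestClassifyUnsafe:
    def _features(self, d):
        rows = [
            {
                "symbol": e.symbol,
                "synonym": e.synonym,
                "total": 5,
                "contribution": 0.5,
                "n_chars": len(e.synonym),
                "bits": 10.0,
                "n_nested": 0,
                "p_syn_given_alt": 0.5,
                "p_alt_given_syn": 0.5,
                "is_symbol": 1.0,
            }
            for e in d
        ]
        return pd.DataFrame(rows)

    def test_english_word_unsafe(self):
        d = build_gene_dictionary([table([("STAR", "STAR")])])
        out = classify_unsafe(self._features(d), d, ensemble=None)
        assert out.entry("STAR", "STAR").safety == "unsafe"

    def test_short_unsafe_even_with_zero_score(self):
        d = build_gene_dictionary([table([("XK", "XK")])])
        out = classify_unsafe(self._features(d), d, ensemble=None)
        assert out.entry("XK", "XK").safety == "unsafe"

    def test_rules_classifier_independent(self):
        d = build_gene_dictionary(
            [table([("STAR", "STAR"), ("XK", "XK"), ("AA1", "ARP1"), ("BB2", "ARP1")])]
        )
        out = classify_unsafe(self._features(d), d, ensemble=None)
        for e in out:
            if e.classes & {"english", "short", "promiscuous"}:
                assert e.safety == "unsafe"

    def test_missing_features_conservative(self):
        d = build_gene_dictionary([table([("ZZZ9", "unique zz name")])])
        empty = self._features(d).iloc[:0]
        with pytest.warns(UserWarning, match="missing features"):
            out = classify_unsafe(empty, d, ensemble=None)
        assert all(e.safety == "unsafe" for e in out)

    def test_threshold_monotonicity(self):
        from litmine import gen_lexicon, gen_safety_corpus, train_safety_ensemble

        d, truth = gen_lexicon(3, 40, 0.4)
        corpus = gen_safety_corpus(3, d, truth)
        mentions = find_candidates(corpus, d)
        feats = compute_safety_features(d, corpus, mentions.candidate_docs())
        ens = train_safety_ensemble(feats, d, seed=3)
        low = classify_unsafe(feats, d, ens, threshold=0.2)
        high = classify_unsafe(feats, d, ens, threshold=0.8)
        # lowering the threshold never converts unsafe -> safe
        unsafe_high = {(e.symbol, e.synonym) for e in high if e.safety == "unsafe"}
        unsafe_low = {(e.symbol, e.synonym) for e in low if e.safety == "unsafe"}
        assert unsafe_high <= unsafe_low
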