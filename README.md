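# litmine

Literature-trend mining for genes and diseases: who is talking about which
gene, how fast is that conversation growing, what is it about, and which
reviews should you read first.

Biomedical gene names are ambiguous — `STAR` is both a gene symbol and an
English word, `ARP1` is a synonym of seven different genes, `insulin` is
nested inside `insulin receptor`, and `CCP4` names both a gene and a
crystallography suite. Counting publications per gene without resolving
this ambiguity badly distorts any downstream trend analysis. `litmine`
implements a complete pipeline for:

1. **Synonym safety classification.** Gene synonyms are aggregated from
   symbol→synonym tables, cleaned against disease names, and assigned
   ambiguity classes (*nested*, *promiscuous*, *english*, *short*). A
   positive-unlabelled (PU) bagged random forest over engineered features
   (candidate counts, contribution, character information content, nesting,
   conditional co-mention probabilities) scores the remaining synonyms; a
   synonym is **unsafe** iff it is an English word, shorter than three
   characters, promiscuous, or scored above 0.5.
2. **Publication disambiguation.** Candidate publications (any synonym
   match in title/abstract/keywords, found with fuzzy boundary-guarded
   patterns) are joined into a weighted co-citation graph — the weight of
   an edge (u, v) counts the distinct third papers citing both u and v.
   Fast-greedy modularity maximisation splits components into communities;
   a community is linked to the gene when
   `#{members with ≥1 safe synonym} / #{members with only unsafe synonyms} > 0.1%`.
   Publications disconnected from the co-citation graph are linked directly
   if they carry a safe synonym, and otherwise classified by PU bagging of
   a logistic regression on TF-IDF features (1–4-grams, count ≥ 2,
   document frequency < 0.6) of the linked vs rejected communities.
3. **Trend forecasting.** Per-gene cumulative yearly series over ten
   categories (publications, reviews, trials, big/medium-pharma
   publications, and the five citation counterparts) are forecast from
   1980–2013 into 2014–2019 by a GRU encoder–decoder with an attention
   layer, trained with RMSprop on min–max-scaled series. Skill is measured
   with MASE (mean absolute scaled error; 1 = break-even with the
   repeat-last-value naive forecast).
4. **Trendiness.** Genes are binned into five volume bins (percentiles
   20..100 of the cumulative count at 2013); within each bin a Gaussian
   KDE (bandwidth 0.1) is fitted to f = log2((predicted+1)/(realised+1)),
   and trendiness(g) = P(F ≥ f_g) — the right-tail mass from the gene's
   own fold change. A gene whose reality outstrips its forecast gets
   trendiness near 1.
5. **Associations and topics.** Gene–gene/gene–disease co-occurrence
   (Jaccard) and normalised mutual information; mapping of genes to
   top-level disease ontology ancestors; NMF/LDA topic models over TF-IDF
   with per-year topic timelines and top-phrase summaries.
6. **Review recommendation.** PageRank over the gene's citation subgraph
   weights each publication; reviews and review combinations are ranked by
   the PageRank mass of the publications they cover (union semantics by
   default, so overlapping reviews gain nothing), normalised so a review
   citing everything scores 1.

Every stage is testable offline: the `synth` module generates corpora,
lexicons, citation graphs with planted community structure, count series
with planted bursts and topic documents with planted drift — each with its
exact ground truth.

## Worked example

```python
from litmine import (gen_field_corpus, disambiguate, gen_timeseries,
                     train_forecaster, compute_trendiness)

# A planted world: 3 research fields, 60 papers each; field 0 is truly
# about GENE0001, the other two use the ambiguous synonym 'orca'.
world = gen_field_corpus(seed=0)
ann = disambiguate(world.corpus, world.citations, world.dictionary,
                   "GENE0001", seed=0)
docs = ann.docs_of("GENE0001")
truth = world.gene_truth
print(len(docs), len(docs & truth))          # 60 60

# Forecast 500 synthetic genes and score trendiness.
series, burst = gen_timeseries(seed=1, n_genes=500)
pubs = {g: f[["publications"]] for g, f in series.items()}
fc = train_forecaster(pubs, train_end=2013, horizon_end=2019, seed=1)
table = fc.forecast(pubs)
print(round(table["mase"].median(), 3))      # 0.553
trend = compute_trendiness(table).set_index("gene")["trendiness"]
print(round(trend[trend.index.isin(burst)].median(), 3))   # 0.946
```

The disambiguation recovers all 60 field-0 publications with no false
positives on this seed; the forecaster halves the naive error on the
synthetic series, and the 50 genes with planted publication bursts have a
median trendiness of 0.946 — above the 90th percentile of the unbursted
genes (0.723).

A thin CLI mirrors the library (`litmine ingest`, `litmine synth`,
`litmine classify-synonyms`, `litmine tag`, `litmine disambiguate`,
`litmine topics-fit`); run `litmine --help`.

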