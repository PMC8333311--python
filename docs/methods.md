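# Methods

This note documents the models and procedures implemented in `litmine`,
the parameters that matter, the behaviour of the synthetic generators, and
the numerical and design choices made where the design was genuinely open.

## Text preprocessing dialect

Documents pass through seven steps, in order: (i) removal of
non-alphanumeric characters, (ii) whitespace tokenisation, (iii) stop-word
deletion, (iv) lower-casing, (v) deletion of tokens shorter than three
characters, (vi) deletion of integer tokens, (vii) stemming. Two details
pin down the dialect:

* **Stop words are matched case-insensitively at step (iii)** even though
  lower-casing is step (iv); otherwise capitalised stop words would leak
  through and violate the token-stream invariant (no stop word in the
  output). The stop-word list is a frozen copy of a standard 179-word
  English list bundled under `litmine/data/`.
* **The stemmer is Porter-style with one deliberate rule change**: step 4
  rewrites the suffix `ate` to `at` instead of deleting it. Textbook
  Porter maps *disambiguated / disambiguations / disambiguating* to
  `disambigu`; this dialect collapses the whole family onto `disambiguat`,
  which is the conformance anchor the package tests pin. Stemming is
  applied to the fixed point (a second pass changes nothing), which makes
  preprocessing a projection: `preprocess(preprocess(x)) == preprocess(x)`.
  The length/integer/stop-word filters are re-applied after stemming since
  stemming can shorten a token below three characters (`ties` → `ti`).

Reference behaviour worth recording: `"RNA-seq!"` → `['rna', 'seq']` —
both tokens are exactly three characters long, and the length rule only
removes tokens *shorter* than three.

## TF-IDF

N-grams for n = 1..4 over the token stream. A retained n-gram needs a
corpus count of at least 2 and a document frequency **strictly below**
0.6 (so two identical documents yield an empty vocabulary — every term
has df = 1.0). The ambiguity between corpus frequency and document
frequency is resolved as document frequency, the standard vectoriser
semantics. The IDF convention is smoothed add-one,
`idf(t) = ln((1+N)/(1+df)) + 1`, raw term counts, L2 row normalisation —
pinned by a hand-coded oracle test at 1e-9.

## Positive-unlabelled bagging

The Mordelet–Vert inductive scheme: each of `n_iterations` draws a
bootstrap of the unlabelled set (size = |positives|, balanced bags) as
provisional negatives, optionally augmented with known negatives, fits the
base model with balanced class weights, and scores the out-of-bootstrap
unlabelled examples. An example's final score is its mean held-out score;
an example never held out falls back to the full-ensemble mean with a
warning. Base models: logistic regression (default for document linking,
50 iterations) and random forest (synonym safety, 5 iterations). A
threefold cross-validation helper with weighted-F1 scoring
(`tune_base_model`) exposes hyper-parameter selection over a small default
grid; wider classifier sweeps are configuration, not defaults.

## Synonym safety

Classes: *nested* (word-bounded, case-insensitive containment in another
synonym), *promiscuous* (listed under ≥ 2 symbols), *english* (membership
in a bundled frozen word list of ~1,500 common words), *short* (< 3
characters). Engineered features per synonym: total candidate
publications of the symbol, the synonym's contribution to that total,
character length, summed character information content (Σ −log2 of the
character's relative frequency over the working corpus titles+abstracts;
characters unseen in the corpus contribute the surprisal of the rarest
observed character), nesting count, the two conditional co-mention
probabilities estimated over candidate documents, and the symbol flag.
The final label is the disjunction: english ∨ short ∨ promiscuous ∨
(PU random-forest score > 0.5). Rules (i), (ii), (iv) are classifier
independent, and lowering the threshold can only enlarge the unsafe set.
Disease-name filtering and the English list lookup are case-insensitive.
Interactive relabelling rounds are supported as an optional labels mapping
merged into the positive/known-negative pools.

## Entity tagging

Synonyms compile to case-insensitive patterns whose alphanumeric runs may
be joined by any single separator from {'', '-', ' ', '/'}; lookarounds
forbid matches that start or end inside a longer alphanumeric token.
Credit is longest-match exclusive across the whole dictionary: a match
strictly contained in another credited span is dropped, so `insulin` is
not credited inside a matched `insulin receptor`; two synonyms matching
the same exact span (promiscuous synonyms) are both credited. Keywords
are joined into the searchable text with `' ; '`, which cannot complete a
separator class match across keyword boundaries. Greek-letter expansion
is not performed.

## Disambiguation

Co-citation weights count distinct citing publications per unordered
candidate pair (the citer need not be a candidate). Communities come from
weighted fast-greedy modularity maximisation (igraph), with determinism
fixed by sorted node order; isolated candidates form singletons handled
separately. Community labelling uses the 0.1% rule with the boundary
cases defined as: no safe members → rejected; no unsafe-only members but
some safe → linked; a member with both kinds counts in the numerator
only. Note the rule is deliberately permissive: one safe-mention member
in a 1,000-member community clears the threshold.

Disconnected publications: safe mention → linked outright; the rest are
scored by PU bagging of a logistic regression over TF-IDF features fitted
on the linked ∪ rejected community documents (titles+abstracts+keywords,
keywords always included), linked at mean score > 0.5. When the
unlabelled pool is smaller than 1,000, an auxiliary negative class of up
to 1,000 publications mentioning other genes is added.

## Series and forecasting

Ten cumulative per-year categories. A citation event is dated by the
**citing** publication's year and categorised by the citing publication's
flags (a big-pharma paper citing an annotated paper adds one big-pharma
citation to the cited paper's gene; being cited by a non-pharma paper adds
nothing to the pharma categories).

The forecaster is a GRU encoder–decoder with an attention layer,
implemented directly on numpy with analytic backpropagation through time
(gradients verified against central finite differences at 1e-6 in the
tests). Attention is realised as a learned softmax weighting over encoder
states; the context vector is concatenated with the previous output value
as the decoder input, and decoding is teacher-forced during training,
closed-loop at prediction. Per-series min–max scaling is fitted on the
training window (a constant window scales to all zeros and is excluded
from the training loss with a warning); the loss is mean squared error on
log1p-transformed scaled values ("log error"), optimised with RMSprop
(lr 5e-3, ρ 0.9), 30% of series reserved for validation with
best-validation parameter restoration. The desk-scale default is one
5-unit GRU per side — the selected width at production scale — with
deeper stacks available via `n_layers`; all series are pooled into one
model. Desk-scale problem sizes used throughout (200–500 series, ~300
epochs) train in seconds on one CPU. Predictions are inverse-transformed
and clipped at zero.

MASE divides the mean absolute forecast error by the error of the naive
forecast repeating the last training value; break-even is 1 (a published
table caption reading "below 0" for this statistic is treated as an
erratum for "below 1").

## Trendiness

Genes are binned by the quintiles of their cumulative count at the end of
the training window; within each bin a Gaussian KDE (bandwidth 0.1) is
fitted to f = log2((predicted+1)/(realised+1)), with +1 pseudo-counts
guarding division by zero, and trendiness(g) = P(F ≥ f_g), evaluated in
closed form as the mean kernel survival function (cross-checked against
numerical quadrature at 1e-6). The fold-change direction follows the
predicted/real convention: a burst makes the ratio small and the
right-tail mass from it large, so trendiness is high exactly for genes
whose reality outstrips their forecast, is strictly decreasing in fold
change within a bin, and equals 0.5 for a gene alone at its own kernel
centre. The source descriptions of this statistic disagree between
realised/predicted and predicted/real; the implemented direction is the
one under which all three desiderata above hold simultaneously. The KDE
is fitted on the log2 scale (the quantity is multiplicative). Bins with
fewer than two genes are merged into their lower neighbour with a warning.

## Associations

Co-occurrence defaults to Jaccard (joint over union of the two tag sets;
the "total publications presenting those tags" normaliser read as the
union), with min-normalisation available as configuration. NMI treats the
two memberships as binary variables over the corpus and normalises mutual
information by √(H(A)·H(B)); either variable constant gives 0. Disease
terms map to their lowest ancestor directly under the given ontology root
(breadth-first over multiple parents, lexicographic tie-break); genes take
the ancestor with maximal summed co-occurrence, ties again lexicographic.

## Topics

NMF (default, nndsvda init, tolerance 1e-12, iteration cap 2000) or LDA
on the TF-IDF matrix. Topic "probabilities" are the L1-normalised rows of
W (NMF weights are not probabilities; all-zero rows become uniform).
Timelines report per-calendar-year mean ± std of these normalised
weights, so the per-year means sum to 1 across topics. Phrase summaries
hard-assign each document to its argmax topic and rank phrases by summed
TF-IDF within the topic's documents. K is user-chosen; no automatic
selection is implemented.

## Recommender

PageRank (damping 0.85, tolerance 1e-10, dangling mass redistributed
uniformly) runs on the citation subgraph with edges from citing to cited,
so heavily cited publications score high. Review scores are PageRank
sums over cited publications, normalised by the all-citing hypothetical
review (= 1). Combination ranking implements both the literal matrix
formula (which double-counts multiply-cited publications) and the
binarised union semantics; union is the default because it actually
rewards low overlap, which is the stated goal of combining reviews.
Exhaustive enumeration is used while the combination count is within a
cap (default 100,000); beyond it, greedy forward selection applies — in
union mode coverage is submodular, so greedy is within (1 − 1/e) of the
optimum. Each combination carries its score, the mean year of covered
publications, and the mean topic profile of covered publications (mean
over covered publications chosen as the aggregation).

## Synthetic generators: what they emulate, and what they do not

All generators are pure functions of (seed, parameters).

* **Lexicon** (`gen_lexicon`): each gene gets a unique two-pseudo-word
  synonym plus, at the ambiguity rate, one planted ambiguous synonym of a
  random type; English plants are drawn from the same bundled word list
  the classifier consults (that lookup is definitional, not
  circular — the classifier's rule (i) *is* list membership).
  `gen_safety_corpus` plants the corresponding document evidence: safe
  synonyms co-occur with their symbol (4 documents per gene), unsafe
  tokens also occur alone in 6 ambient documents, giving the conditional
  probability and contribution features genuine signal.
* **Field corpus** (`gen_field_corpus`): stochastic-block co-citation
  structure over fields with disjoint 30-word vocabularies plus 15 shared
  words; defaults 3 fields × 60 publications, within-field co-citation
  probability 0.2, cross-field 0.005, 60% of target-field documents
  carrying the safe synonym and 20% of each field disconnected. Real
  fields are not planted partitions and real citation graphs are not
  Erdős–Rényi within blocks; passing recovery tests shows the pipeline
  recovers clean planted structure, not that real-world fields are this
  separable.
* **Series** (`gen_timeseries`): yearly new publications are Poisson
  around per-gene exponential growth (rates 0.01–0.07/yr, log-uniform
  volume spread); citations Poisson at 6× publications; other categories
  binomial thinnings (reviews 12%, trials 5%, big pharma 8%, medium 6%).
  Bursts multiply new counts by the burst multiplier from a planted year
  inside the forecast window. Real publication dynamics have shocks,
  saturation and category correlations this ignores.
* **Topics** (`gen_topic_corpus`): disjoint per-topic vocabularies with
  Dirichlet document mixtures (concentration 8) around a year-indexed
  drift schedule; 40 words per document. Disjoint vocabularies make
  factor recovery well-posed; real topics overlap.

## Known limitations

* The 0.1% community rule propagates a single stray safe-mention member
  to its whole community; with small planted communities this occasionally
  links a wrong field wholesale (visible as a low-precision seed in the
  planted recovery distribution). This is the rule as specified, not a
  defect of the implementation.
* The scanner is regex-per-synonym over each document; it is linear in
  text length for a fixed dictionary but not optimised for
  hundred-thousand-synonym dictionaries against multi-gigabyte corpora.
* The forecaster pools all series into one model and forecasts each
  category independently; cross-category structure is not modelled.
* PageRank, community detection and NMF/LDA are delegated to networkx,
  igraph and scikit-learn respectively; independent oracles in the test
  suite (dense power iteration, brute-force enumeration) keep those
  delegations honest.
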