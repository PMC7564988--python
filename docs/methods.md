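# Methods

This note documents the models and procedures implemented in
`dialogforge`, their assumptions, the parameters that matter, and the
design decisions taken where the design was genuinely open.

## Data model

An ontology declares intents and entity slots.  Each intent is an action
verb plus an activity class (`add-vital` = *add* + a vital sign); the
activity slot is the verb's direct object, and record slots (measurement
values, materials, places, times, care targets) attach through
prepositional-phrase templates of two patterns: `preposition + slot` and
`preposition + modifier(s) + slot`.  Slot identifiers are lower-case
hyphenated (`@vital-value` style).  The packaged fixture ontology covers
six intents (`add-vital`, `clean-oral`, `assist-toilet`, `prepare-meal`,
`assist-bath`, `change-diaper`) with their sample value inventories plus
shared record slots `start-time`, `stop-time` and `target`.  Two fixture
choices were ours: `change-diaper` has no published activity-class
inventory, so a `diaper-type` slot is populated from its sample
utterances (*dirty diaper*, *soiled diaper*, *nappies*); and measurement
slots carry an optional `number_prefixes` list so that surfaces such as
"103 systolic blood pressure" are generated as number + unit with a
single entity span covering both.

## Augmentation

Generation composes three stages, each deterministic under an integer
seed:

* **Shuffling.**  All permutations of an intent's record phrases behind
  the fixed verb + activity head (subject–verb–object order preserved),
  skipping duplicates; *m* distinct phrases yield exactly *m*! orderings.
* **Filling.**  The Cartesian product of slot surfaces (values plus their
  declared synonyms, times number prefixes where present) is emitted
  exhaustively when it fits the budget, otherwise sampled uniformly
  without replacement under the seed.  Entity spans are 0-based,
  half-open character offsets, an internal convention validated after
  every transformation (`text[start:end] == surface`, no overlaps).
* **Paraphrasing.**  One variant per applicable rule: question form
  (modal yes/no or Wh- prefix, chosen by a seeded draw per utterance),
  politeness ("Please," / "I" prefix), active-to-passive (template-based
  over a closed verb-participle inventory; multi-word verbs are skipped
  with a warning rather than guessed at), and keyword-synonym replacement
  from a packaged static lexicon.  Spans are recomputed in every variant.

Per-intent budgets default to the reference corpus counts (876, 606, 408,
756, 560, 340 — 3,546 utterances in total).  The generator oversamples
base fillings (3x the budget, split across orderings), paraphrases them,
de-duplicates texts globally, and down-samples to the budget; if the
attainable unique variants fall short, the maximum is emitted and the
shortfall recorded on the corpus object.  Synonym lookup from trained
embeddings (`expand_synonyms`) strips special characters from the query,
keeps the top k = 10 neighbours with cosine similarity at or above 0.5,
and discards retrieved tokens shorter than four characters; the length
filter applies to retrieval only, never to generation or features, since
the corpus's own verbs ("add") and numbers are shorter.

Generated utterances are longer than hand-written nursing commands
(roughly 10–14 words against the reference corpus's ~7) because every
intent carries three record phrases; this affects style, not labels.

## Embeddings

Both trainers implement skip-gram with negative sampling in NumPy.
Defaults are the tuned values used for the generated corpus: dimension
32, minimum count 3, context window 6 (dynamic, uniform in [1, window]),
frequent-word downsampling 1e-3, 50 epochs.  Negative-sampling count (5),
the unigram^0.75 noise distribution and the linearly decayed learning
rate (0.025 → 1e-4) are standard word2vec practice, configurable because
no tuned values exist for them.  Training is single-threaded and
bit-reproducible per seed; the `threads` config field is advisory
metadata.

The subword model learns vectors for boundary-marked character n-grams
(default n = 3..6, configurable; only n = 3 has a documented example) and
defines a word vector as the **sum** of its n-gram vectors — an identity
that holds exactly on the returned table and lets out-of-vocabulary words
compose vectors from shared n-grams.  CBOW, GloVe and contextual
encoders are out of scope; any sentence encoder can be plugged in through
the `encode(text) -> vector` interface, and the packaged desk-scale
encoder is mean pooling of trained word vectors over sentence-level text.

## Features

Word-level normalisation runs contraction expansion → lower-casing →
tokenisation → stopword removal → lemmatisation → non-ASCII/punctuation
stripping, in that fixed order.  The stopword list, contraction table and
lemma exception table are packaged, versioned resources (no canonical
inventories exist for them); the lemmatiser is exception-table-first with
conservative suffix rules (regular plurals, long superlatives such as
*closest* → *close*), and unknown shapes pass through unchanged.
Sentence-level normalisation removes non-ASCII characters only, because
lemmatising would merge forms (*close*/*closer*/*closest*) whose meanings
differ.  The word-level feature is the arithmetic mean of token vectors;
tokens missing from a word-level table are skipped rather than
zero-imputed, since zero rows drag the mean toward the origin.

Entity candidates are noun phrases with head dependency tags.  The
packaged parser is a deterministic rule-based chunker covering the
corpus's sentence shapes — verb-object (dobj), preposition-object (pobj)
and number + unit (nummod) phrases, with leading determiners excluded —
so no statistical model download is needed; a full dependency parser can
be supplied through the same callable interface, with the chunker as its
logged fallback.  The chunker makes no claim to any particular parser's
tag set.

## Clustering and labeling

k-means minimises the within-cluster sum of squared Euclidean distances
from k-means++ initial centroids.  The implementation records the
objective after every Lloyd iteration (the trace is non-increasing),
re-seeds a cluster that empties at the point farthest from its centroid,
and runs 10 restarts by default, keeping the best final objective.
Features are used raw; an optional L2-normalisation flag exists but is
off by default.  Tie-breaks are deterministic: equidistant points go to
the lowest centroid index, tied majority labels to the lexicographically
smallest label.  k defaults to the gold number of classes — distinct
intents for intent clustering, distinct gold slot names for entity
clustering (entities always use word-level features; entity surfaces
whose tokens have no vectors are excluded rather than zero-imputed).

## Character language model

The model is embedding (256 dims) → one recurrent layer → dense softmax,
trained with categorical cross-entropy in mini-batches of 64 over 30
epochs.  The full profile uses 1024 LSTM units with dropout 0.2 on the
recurrent outputs; the desk profile used for routine runs keeps
everything but reduces the layer to 256 units.  The cell is configurable
(LSTM or GRU, identical interface); both backward passes are verified
against finite differences.

Training text is the corpus with `\n` terminating every utterance so the
model learns to end sequences.  The vocabulary maps `\n` to id 0 and the
remaining characters by descending frequency then codepoint — any fixed
rule would do, and only the consistency of the mapping (same character,
same id) is meaningful.  The text is split into **non-overlapping**
stride-L windows (L = 100) whose targets are the inputs shifted one
character; stride-L is a corpus-splitting reading of windowing (stride-1
is configurable but quadruples the work at no observed benefit here).

The optimiser is Adam (1e-3, the conventional default) with global-norm
gradient clipping at 5.  Reported accuracy is the running training
next-character accuracy over each epoch's batches, measured before each
batch's update — the quantity a framework progress bar prints; no
held-out split is taken.  Sampling scales logits by 1/temperature;
temperatures below 1e-6 are treated as the greedy argmax limit.
Generated lines can be labeled by the clustering pipeline to flag
ambiguous output automatically; no human adjudication step is modelled.

## Evaluation

* **Pair counting.**  TP/FP/TN/FN over all unordered item pairs,
  computed from the cluster-by-class contingency table; P = TP/(TP+FP),
  R = TP/(TP+FN), F1 = 2PR/(P+R), with zero conventions for empty
  denominators.  The counts always total n(n−1)/2.
* **Silhouette.**  S(i) = (b−a)/max(a,b) with Euclidean distances
  (matching the clustering metric), singleton clusters scoring 0; the
  computation is backed by scikit-learn and cross-checked against an
  independent brute-force oracle in the tests.
* **BLEU.**  4-gram modified precision with brevity penalty.  Orders
  unattainable for a short candidate are dropped from the geometric
  mean; zero-match higher orders get add-one smoothing; zero unigram
  overlap scores 0.  Generated utterances are scored against all
  reference utterances of their label and the best match kept; the
  corpus score is the mean of the maxima.  Order and smoothing are
  configurable since no canonical setting is documented for them.
* **Corpus statistics.**  Per-class utterance counts, whitespace word
  counts, and average length reported truncated (not rounded) to three
  decimals — the truncation convention matches the reference table rows
  exactly — with full precision retained internally.
* **Rating aggregation.**  Unweighted mean of per-group rating means,
  two decimals.  Collecting human ratings is out of scope; only the
  arithmetic is provided.

## Synthetic data and what the tests show

The fixture ontology mirrors the published six-intent inventory but
stands in for an unpublished facility ontology; generated text is
template-bred English, far more regular than real nurse speech (no
disfluencies, ASR errors, spelling variation or out-of-ontology
vocabulary).  Passing tests therefore demonstrate the correctness and
determinism of the machinery — span bookkeeping, combinatorial counts,
optimisation behaviour, metric arithmetic — and that the pipeline's
components interact as designed at realistic scale; they do not
demonstrate performance on real clinical recordings.  Clustering
accuracy on this corpus is near-perfect precisely because the generator
and the labeler share the ontology's vocabulary.

## Problem sizes and numerical choices

Routine test runs use corpora of tens of utterances per intent, toy
embedding corpora of a few hundred sentences, and a ten-utterance
memorisation fixture for the character model (window 40, aligned to
utterance starts so the zero-state sampling condition matches training).
The end-to-end run uses the full 3,546-utterance corpus (~240k
characters, ~2.4k windows) with the desk profile.  Floating point is
float32 in the recurrent model and float64 elsewhere; k-means tolerance
is 1e-8 on centroid shift; vector I/O round-trips to six significant
digits.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state is touched.

## Known limitations

* The passive rule handles only the corpus's verb-object sentence shape
  and a closed participle inventory; it skips rather than risks an
  ungrammatical rewrite.
* The rule-based chunker assumes imperative/question clause order and
  will mis-segment free text.
* Skip-gram training is vectorised per centre word, which is ample for
  desk-scale corpora but not for millions of tokens.
* The GRU cell is provided for architectural comparison; only the LSTM
  configuration is exercised at full scale.
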