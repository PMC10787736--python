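# Methods

`npnamematch` maps free-text natural-product (NP) name strings — the kind
found in the drug-name fields of spontaneous adverse-event reports — to
known NP names. It combines two matchers: a classical fuzzy string
matcher (Gestalt pattern-matching, with normalized Levenshtein distance
as a comparison baseline) and a learned metric (a Siamese neural network
over character sequences). This note documents the models, the synthetic
data used to exercise them, the numerical choices, and the limits of what
the test suite demonstrates.

## String normalization and encoding

Raw strings are reduced to the alphabet `{A–Z, space}`: non-alphabetic
characters are deleted (accented letters are first transliterated via
Unicode NFKD decomposition), the result is uppercased, and whitespace
runs collapse to a single space. Cleaning that leaves no letter is an
error rather than an empty string, so downstream name sets never contain
empties. Clean names are encoded position-wise as integers (`A`–`Z` →
1–26, space → 27) and right-padded with 0 to a fixed 65 positions; names
longer than 65 characters are rejected, not truncated, making the
encoding lossless on everything it accepts. The 65-character cutoff is a
configurable default chosen as roughly the mean plus one standard
deviation of observed report-string lengths.

## Fuzzy matchers

**Gestalt pattern-matching (GPM).** The similarity of `X` and `Y` is
`2·(|s1|+…+|sn|)/(|X|+|Y|)`, where the `s_i` are the common substrings
found by recursive anchoring: take the longest common substring, then
recurse on the text to its left and to its right. Ties among equally long
anchors break to the smallest start offset in `X`, then in `Y`, which
makes the decomposition deterministic. No "autojunk"/popularity
heuristics are applied. The implementation is verified exactly (1,000
random pairs) against both a brute-force recursive oracle and stdlib
`difflib` with autojunk disabled.

**Normalized Levenshtein distance (LED).** The minimum number of
single-character edits divided by the longer string's length, computed by
rolling-row dynamic programming and verified exactly against a
full-matrix DP oracle and `edlib`. Note the orientation difference: GPM
is a similarity (1 = identical), LED a distance (0 = identical).

**Retrieval.** `top_k` ranks a corpus per query (GPM descending, LED
ascending), breaking score ties by ascending candidate string. The
default similarity cutoff is 0 (a full top-20 is returned) to maximize
candidate recall; a floor can be raised via the API or CLI.

## Synthetic data

No real lexicon or report corpus ships with the package; everything the
tests exercise is generated:

* **Lexicon** (`synth_lexicon`): groups of equivalent names, each with a
  two-word pseudo-Latin binomial (syllable generator plus Latinate
  suffixes such as *-ensis*, *-oides*), a common name, and 2–5 variants
  derived from the two by the perturbation procedure below. This mirrors
  the structure of real NP synonym groups (preferred term + Latin
  binomial + spelling variants).
* **Perturbation** (`perturb_name`): select `k = max(1, round(0.4·n))`
  distinct character positions; for each, draw `u ~ U(0,1)` and apply:
  `[0,0.2)` substitute a random character/space, `[0.2,0.4)` delete,
  `[0.4,0.6)` insert a random character/space after the position,
  `[0.6,0.8)` transpose with the previous position, `[0.8,1]` no change.
  Positions are selected on the original string and edits applied
  right-to-left so indices stay valid; position 0 cannot transpose and
  becomes a no-op. Results are re-cleaned; empty or over-long outcomes
  are redrawn (bounded retries). In expectation 80% of selected positions
  receive a string-altering action.
* **Decoy corpus** (`synth_decoy_corpus`): pharmaceutical-style coinages
  (onset + infix + drug suffix, e.g. `CARBOXIAZOLE`) drawn from a
  different letter-statistics model than the botanical generator,
  emulating the fact that most unmapped report strings are conventional
  drug names, not NPs.
* **Plants for the mining benchmark** use the same perturbation machinery
  at `selection_rate = 0.05` (one edit for names up to ~30 characters):
  real-world misspellings are overwhelmingly single-edit typos, unlike
  the deliberately heavy 40% corruption used for training augmentation.
  Heavily corrupted short names are genuinely irrecoverable among
  thousands of decoys by *any* string matcher, so they would measure
  perturbation severity rather than pipeline correctness.

What the synthetic data does **not** emulate: brand names and ingredient
lists, real typo statistics (keyboard adjacency, phonetic errors),
multi-product strings, and the long-tailed length distribution of real
report fields. Passing tests therefore demonstrate correctness of the
algorithms and pipeline and qualitative behavior (retrieval, separation,
complementarity of the matchers) — not performance on real reports.

## Training pairs: balancing and splitting

From a lexicon, each group maintains a *query pool*: its names plus
perturbation-derived misspellings. Matching pairs (label 0) pair every
pool string with all names of its group, so pair counts are
combinatorial in pool size and the same query string recurs across many
pairs — the structure that lets a modest name set yield a large pair
set (and the reason the reference protocol's pair counts imply the same
name appearing on both sides of its train/validation split). Distant
pairs (label 1) pair a pool string from one group with a name from
another. Two balancing passes address the two
imbalances that arise: per-target balancing synthesizes new unique
matching pairs until every target's count is within ±10% of the maximum,
and label balancing synthesizes pairs until the matching fraction sits in
[0.49, 0.51] (the generator stops within ±0.003 of the midpoint so that
carving out a 50/50 holdout cannot push any split outside the band).
Duplicates are removed by exact `(query, target, label)` identity. A
label-stratified holdout is drawn first; the remainder splits 70/30,
also label-stratified. Balancing precedes splitting, so the same *name*
(not pair) may appear in more than one split — the pair counts imply the
same in the reference protocol; the manifest records this choice.

## The Siamese model

Each tower maps an encoded name to a summary vector; both towers are
literally the same parameter set (weight sharing is structural, not
synchronized copies). Architecture, with defaults:

1. **Per-character embedding network**: one-hot(28) → dense 130 (ReLU) →
   dense 130 (ReLU) → linear 30, applied identically at every position;
   padding positions are zeroed.
2. **Bidirectional LSTM**, 65 units per direction, over the 65-position
   sequence. Padded steps carry state unchanged, so computation can stop
   at the longest real length in a batch with identical results. The
   tower summary is the concatenation of the two directions' final hidden
   states (`pooling="final"`; a masked-mean alternative is available).
3. **Merge**: cosine distance clipped to the unit interval,
   `d = min(1 − cosθ, 1)`, evaluated in the algebraically identical
   chord form `CD = ||u − w||²/2` on the L2-normalized summaries — the
   chord form returns exactly 0 for identical inputs and is exactly
   symmetric, which the direct quotient form cannot guarantee in
   floating point. The clip, rather than a division by two, is what
   makes the fixed 0.5 threshold and unit margin geometrically sound:
   with `d = CD/2`, margin 1 demands *antipodal* cross-group embeddings
   and the 0.5 threshold demands pairwise-obtuse ones — impossible for
   more than `dim+1` groups and so restrictive that validation accuracy
   empirically plateaus near 0.80 on 60 groups. With the clip, margin 1
   asks cross-group pairs to be orthogonal-or-further (attainable for
   any number of groups up to the embedding dimension) and the 0.5
   threshold separates within-60° from beyond-60°.

**Loss.** Contrastive: matching pairs (label 0) incur `d²`; distant pairs
(label 1) incur `max(0, ε − d)²` with margin ε = 1.0 in output-distance
units, i.e. distant pairs are pushed to at least orthogonality. The 0/1
dataset labels map onto the matching/non-matching indicators of the
loss. A variant applying the contrastive terms to the raw Euclidean
distance between tower summaries (`loss_space="euclidean"`) is
implemented for completeness; empirically it does not transfer to the
cosine output at the 0.5 threshold (matched pairs collapse but
cross-group *angles* stay small, leaving accuracy near chance), so the
output-space loss is the default.

**Training.** Minibatch Adam (default lr 3e-3, batch 128), both pair
sides stacked through the shared encoder in one batch; defaults chosen
for single-CPU convergence speed and recorded in the model manifest.
Early stopping monitors validation loss with patience 5 and min-delta
1e-3 (absolute, on a loss bounded by the squared unit margin); the
weights of the epoch with the best validation *accuracy* — fraction of
pairs where `(d ≥ 0.5)` equals the label — are the ones kept. An
optional cosine learning-rate decay and inverted dropout on the embedded
characters are available. All forward/backward passes are hand-written
NumPy with float32 arithmetic (float64 for gradient checking); gradients
are verified against central finite differences to ~1e-6 relative error.

**Persistence.** A model directory holds `weights.npz` plus a JSON
manifest (format version, full config, seed, SHA-256 prefix of the
training data, best epoch, metrics) and per-epoch training curves as
CSV. Loading validates the manifest against the code and the stored
parameter shapes.

## Evaluation

**Mean reciprocal rank** over top-20 retrieval, in two modes: *exact*
(the literal target string) and *equivalent* (any name in the target's
synonym group; since equivalents ⊇ {target}, equivalent-mode MRR
dominates exact-mode MRR by construction). A query whose answer is
absent from the top-k contributes reciprocal rank 0 — the standard
retrieval convention for an otherwise undefined term. The reported SD is
the population standard deviation of per-query reciprocal ranks.

**Cohen's kappa** `κ = (p₀ − p_e)/(1 − p_e)` over a 2×2 two-annotator
table, verified against scikit-learn on random tables to 1e-12; κ is
undefined (error) when chance agreement is 1.

## Mining pipeline

`filter_corpus` cleans a raw corpus and drops empties, over-length
strings and exact post-cleaning duplicates, logging every removal so
that `input = kept + Σ removals` exactly. `mine_candidates` retrieves
the top-20 corpus strings per query under GPM and/or the Siamese model.
LED is deliberately excluded from mining: it is the default matcher in
many query systems (its finds are likely already mapped), it performed
comparably to GPM in the retrieval comparison, and including it would
inflate the manual-review burden with largely overlapping candidates.
Annotation is a human step: the exported sheet carries two annotator
columns, an adjudication column, and the review rules as guidance; the
package computes inter-annotator kappa and the per-method overlap
accounting (totals with duplicates, method-exclusive uniques) but never
adjudicates. `capture_gain` counts reports matching a name list by exact
cleaned-string equality (substring matching exists behind a flag,
default off).

## Problem sizes

The test suite and the acceptance script use a scaled-down study: a
60-group lexicon (~330 names), ~20,000 balanced pairs, a 1,000-pair
label-stratified holdout; the mining benchmark uses 70 products (140
queries) against a 5,000-string corpus with 200 planted typos. Under
these conditions the default model trains in roughly 35–40 epochs
(~10–13 s per epoch on one CPU) and reaches best-epoch validation
accuracy ≈ 0.99 at the 0.5 threshold. The reference protocol this
emulates used ~1.7M pairs; the combinatorial pair construction keeps the
scaled study's *structure* (recurring query strings, balanced targets
and labels) while shrinking its size.

## Limitations

* The Siamese model learns two tasks at once — denoising misspellings
  and linking semantically equivalent names — and, as in the reference
  protocol, it tightens matched pairs more effectively than it separates
  distant ones; in retrieval over many near-orthogonal distractors this
  costs it rank quality relative to GPM/LED on pure misspellings.
* Validation pairs are unseen *combinations* of strings that largely
  recur in training (the combinatorial pair construction); validation
  accuracy therefore measures within-distribution generalization, not
  performance on never-seen free text. Retrieval of genuinely novel
  strings is exercised separately by the MRR comparison and the mining
  benchmark.
* GPM's anchor recursion is brittle to transpositions in short strings;
  a single transpose can halve the similarity of a 5-character name.
  This is a property of the algorithm (reproduced exactly by the
  independent oracles), not of the implementation.
* The margin is demanded of every cross-group pair; with margin 1.0
  (orthogonality) the number of separable groups is bounded by the
  summary dimension (130 by default), which is ample for the study's 60
  groups but a real constraint for lexicons with thousands of products.
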