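# Methods

This note documents the models implemented in `ppitriage`, the choices
made where the design was genuinely open, and what the synthetic test
conditions do and do not establish.

## Priority Model

The gene-name detector assigns every token `t` a class probability `p_t`
(gene vs. not) and a reliability `q_t` (probability that `t` decides the
name's class rather than any token to its left).  A name `t_1 … t_k` is
scored by the forward recursion

```
s_1 = p_1 ,   s_i = q_i p_i + (1 − q_i) s_{i−1} ,
```

equivalent to the weight expansion `λ_i = q'_i Π_{j>i}(1 − q_j)` with the
leftmost reliability pinned to `q'_1 = 1`.  Pinning the leftmost weight is
what makes `Σ λ_i = 1`, so the score is a convex combination of the `p`
values and is bounded by their minimum and maximum — without it the
weights would not normalize and scores could leave `[0, 1]`.  This
normalization convention is our choice; any convention that makes the
rightmost tokens dominate and normalizes the weights yields the same
qualitative behavior.

Training maximizes the Bernoulli likelihood of gene / non-gene name lists
over `(p, q)` in logit space (all logits start at 0, i.e. p = q = 0.5,
making the fit deterministic) with L-BFGS-B and an analytic gradient
back-propagated through the recursion.  Fitted probabilities are clipped
to `[1e−6, 1 − 1e−6]`: a token occurring in only one class otherwise
drives its logit to ±∞.  Unseen tokens fall back to `p = q = 0.5`
(uninformative); no frequency smoothing is applied because the model is
only used to gate anonymization, not for mention-level evaluation.

Tagging restricts candidates to supplied phrase spans (a noun-phrase
chunker interface; a regex fallback takes maximal runs of capitalized or
digit-bearing tokens).  Two hard rules: an all-digit surface is never a
name, and overlapping accepted spans resolve leftmost-longest.  The
decision threshold defaults to 0.5 on the score, which is an operating
point, not a calibrated probability.  A variable-order Markov extension
of this model exists in the literature; it is deliberately out of scope.

## Feature extraction

* **Tokenization** lowercases, keeps internal hyphens and digits
  (`MEK-1`, `p53`) and splits sentences on `[.?!]` + space + uppercase.
  Title and abstract are concatenated with a sentence boundary between
  them — the two fields are not weighted separately.
* **Word n-grams** (`W1|`, `W2|`, `W3|`) never cross sentence boundaries.
* **Substrings** (`S|`): per-token character 6-grams (6 chosen over 4–7
  alternatives as the standard window for this task family), whole token
  when shorter.  Windows never span whitespace.
* **MeSH** (`M1|`, `M2|`): descriptor-internal unigrams/bigrams;
  qualifiers after `/` are treated as separate descriptors (included, not
  dropped — they carry topical signal such as `metabolism`).
* **Dependency relations** (`D|rel(head,dep)`): only *dependent*-position
  gene names are anonymized to `PTNWORD`; head-position genes stay
  verbatim.  With stemming enabled, the original 1980 Porter algorithm
  (implemented in `porter.py`, validated against hand-traced outputs of
  the published procedure) is applied to the head and to non-anonymized
  dependents; the tag itself is never stemmed or lowercased.  Relation
  labels are taken verbatim from the parse input — no tagset mapping.
* **Anonymization scope**: when anonymization is on, mention spans are
  collapsed to the tag *before* word-family extraction too, so documents
  differing only in gene surface forms produce identical feature sets.
  This is slightly broader than anonymizing only inside relations but
  keeps the invariance property uniform across families.
* **Feature cut**: "frequency" is read as *document* frequency (features
  are binary per document); `min_doc_freq = 4` removes DF ≤ 3 features
  from every family alike.  Survivors are indexed 1..V lexicographically,
  and the vocabulary is frozen — unknown features at predict time are
  dropped silently.
* Family prefixes prevent collisions between families; feature strings
  are otherwise raw surface material.

Parsing itself is out of scope: dependency relations are consumed as
pre-parsed input (flat TSV or CoNLL-X), with the parser pluggable.  The
synthetic generator ships template parses for testing.

## Huber classifier

The cost is the *unnormalized* loss sum plus `λ‖w‖²` with
`λ = λ′⟨|x|⟩²` (`λ′ = 0.0005` by default).  Both conventions here —
sum-vs-mean loss and the squared mean norm — are configurable
(`TrainSettings.loss_normalization`); with `λ′` retuned the alternatives
are equivalent up to a rescaling, so the defaults matter mainly for the
numeric value of `λ′`.  The margin convention is `z = y(w·X + θ)` with
an additive threshold.

The optimizer is deterministic full-batch gradient descent with an
Armijo backtracking line search from `w = 0, θ = 0` — order-independent
and reproducible, at the price of speed on large corpora (acceptable at
the corpus sizes used here; the loss and gradient are sparse
matrix-vector products).  Convergence: relative cost change below 1e−8
or 1000 iterations, whichever first.  The cost trace is non-increasing
by construction, and the analytic gradient is verified against central
finite differences in the test suite.  Binarization takes the sign of
the score with an exact 0 going to the negative class (conservative for
an imbalanced triage setting).

## Higher-order induction

Candidates are all unordered pairs of active features in misclassified
training documents; each pair's score is the gradient of the total
training loss with respect to the would-be conjunction weight evaluated
at 0, summed over the *misclassified* documents only (the summation set
follows the candidate-generation set).  Selection keeps pairs with count
≥ a and |sum| ≥ b, both inclusive; defaults a = 4, b = 340.  `b` scales
with corpus size — on synthetic corpora of a few hundred documents it
must be lowered (the tests use b = 1).  Pairs may span feature families.
One induction round is performed per run (iterating is possible but the
returns diminish and tuning is brittle).  The conjunction's activation
is exactly the AND of its constituents.

## Synthetic corpus generator

The generator emulates a labeled PPI/non-PPI abstract collection:
positive documents contain at least one `<GENE> <trigger> <GENE>`
sentence (triggers such as "interacts with", "binds", "phosphorylates");
negatives use non-trigger verb templates at the same gene-token rate, so
gene mentions alone carry no label signal; background tokens are
label-independent noise; MeSH terms are drawn label-conditionally with a
shared common pool; template parses emit `(subj, verb, gene1)` and
`(obj, verb, gene2)`.  Labels are assigned deterministically by document
index (first `⌈pos_fraction·n⌉` documents positive) so class counts are
exact; all token content derives from a single seeded generator, making
the corpus a pure function of its spec.

Defaults: 200 documents, half positive, 120 background word types, 5
trigger phrases, one gene template sentence expected per sentence slot
(`gene_token_rate = 1.0`), noise rate 0.3.  These produce a strongly
separable problem by design: the planted trigger vocabulary is disjoint
from the background lexicon.  Consequently, perfect held-out scores on
synthetic corpora verify the *plumbing* — tagging, anonymization,
vectorization, optimization, ranking — not the difficulty of real
literature, where trigger vocabulary is shared across classes, parses
are noisy, and class balance is heavily skewed.  Absolute performance on
the real curation corpora cannot be inferred from these tests.

## Problem sizes

The test suite and the acceptance script run the full pipeline at 60–400
documents with vocabularies of a few thousand features, chosen so the
whole verification cycle completes in seconds while still exercising
every stage end to end; table-metric recomputation uses the published
6000-document confusion counts directly.

## Known limitations

* The noun-phrase chunker is a regex stand-in; candidate quality on real
  text needs a proper chunker or parser integration.
* No score calibration: margins rank well but are not probabilities.
* No handling of class imbalance beyond what the loss provides
  (sampling/cost-sensitive schemes are known to be of limited benefit in
  this architecture and are not implemented).
* Full-batch training scales linearly in corpus size per iteration;
  PubMed-scale corpora would need a stochastic optimizer, which would
  sacrifice the determinism guaranteed here.
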