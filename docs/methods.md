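# Methods

`scramblex` implements the stimulus-construction and characterization
computations used in word-order-degradation studies of sentence processing:
two scrambling algorithms, two word-order distance metrics, windowed
pointwise-mutual-information (PMI) profiling, a synthetic template language
to exercise all of it without an external corpus, and a cluster-bootstrap
estimator of condition effects.

## Pair extraction and smoothed probabilities

Word pairs are extracted from each token string with a forward sliding
window of 4 words: every ordered pair at gaps 1–3 is collected, which is
the union of the bigrams, 1-skip-grams, and 2-skip-grams.  A 12-word string
therefore yields 11 + 10 + 9 = 30 pairs, and an n-word string 3n − 6 (for
n ≥ 4).  Pairs never cross string boundaries, and no padding is applied:
stimuli are isolated strings.

Probabilities are Laplace-smoothed with pseudo-count α (default 0.1):

    P(w) = (c(w) + α) / (N + αV)
    P(wi, wj) = (c(wi, wj) + α) / (M + αV²)

with N total tokens, M total extracted pairs, and V the vocabulary size.
The smoothed supports are the V unigrams and the V² ordered pairs, the
minimal reading under which both distributions normalize exactly.  Pair
counts are kept per gap; the joint used for PMI pools gaps 1–3 by default
(a single joint probability), with gap-specific joints available for
distance curves.  Tokens are lower-cased at ingestion (configurable):
association estimation is case-free even when stimuli are displayed in
capitals.

## PMI and the per-string statistic

PMI(wi, wj) = ln P(wi, wj) / (P(wi) P(wj)), in nats.  The log base is
fixed at e; every in-scope comparison (ratios, orderings, sign tests) is
base-invariant.  With α > 0 all PMI values are finite.

The per-string statistic is the arithmetic mean over the *positive* PMI
values of the string's 30 window pairs; repeated pair types count once per
occurrence.  A string with no positive pair scores 0, keeping the
statistic total.  Restricting to positive values indexes the evidence for
combinable material and down-weighs high-frequency closed-class words,
whose pairwise PMI is near zero or negative.

`pmi_by_distance` reports mean PMI per interword gap using gap-specific
joints.  Note a small-sample property: averaging PMI over *observed* pair
occurrences is upward-biased by roughly 1/(2λ), λ being the expected count
per pair type, because occurrence weighting correlates with positive
sampling fluctuations.  Independence checks in the test suite therefore
use corpora large enough that λ ≳ 20.

## Local-swap scrambling

A scramble of strength k applies k local swaps: a position is drawn
uniformly, and the token there is exchanged with an immediate neighbor
(endpoints have one neighbor; interior positions pick a side uniformly —
the neighbor-choice rule is a documented convention).  Because a random
swap can undo a previous one, the whole k-swap draw is rejected and
resampled until the inversion distance between the original and scrambled
orders equals k, computed on token indices so duplicate words are
distinguished.  Requested and realized degradation therefore agree
exactly, which is what separates, say, the 3-swap from the 1-swap
condition.  The sampler is deterministic given its seed; the retry cap
(10,000) is never approached in practice at k ≤ 7, n = 12.

Two metrics quantify degradation:

* **Inversion distance** — the minimum number of adjacent transpositions
  between two orders, i.e. the Kendall-tau inversion count of the relative
  permutation (merge-sort counting, O(n log n)).  Verified in the tests
  against a breadth-first-search shortest-path oracle over adjacent swaps.
* **Words moved** — the minimal number of displaced words, formalized as
  n minus the longest-common-subsequence length of the two surface
  strings.  LCS matching resolves duplicate words optimally, and the
  definition reproduces both published worked examples.  For any pair of
  orders, words moved ≤ inversion distance, since each displaced word
  costs at least one swap.

## The low-PMI (maximal-separation) scramble

Content words — adjacency defined on the original string (two content
words are adjacent if no content word lies between them) — are reordered
by the odd-then-even interleave: 1st, 3rd, 5th, … in original relative
order, then 2nd, 4th, ….  The function words are reordered the same way,
and the function block is inserted after the first ⌈c/2⌉ content words.
This is the canonical construction for these materials: it reproduces the
published worked example token for token, it separates every originally
adjacent content pair by at least ⌊(c−1)/2⌋ content positions, and with
the block embedded in the center *every* adjacent content pair straddles
the block, ending more than 3 positions apart — outside the 4-word PMI
window entirely.  Center insertion is optimal in that sense: it is the
unique insertion point that splits all adjacent pairs at once.

A caveat worth stating: the interleave does not globally maximize the
*summed* pairwise separation.  For c ≥ 4 a zigzag arrangement (alternating
ends toward the middle) attains a strictly larger sum (e.g. 39 vs. 36 at
c = 9), under both the content-only and the embedded-block readings of
the objective.  The interleave is retained because it is the construction
that generated the published stimuli and because its guarantee — every
locally combinable pair leaves the PMI window — is the property the
manipulation needs, not the sum itself.

## Synthetic template language

The generator emulates the statistical skeleton the pipeline needs,
not natural language.  Sentences fill a fixed 12-slot template
(Det Adj N V Det Adj N Prep Det Adj N Adv; 8 content and 4 function
slots).  Four *compatibility groups* — the originally adjacent content
pairs (Adj,N), (V,Adj), (N,Adj), (N,Adv) at slots (1,2), (3,5), (6,9),
(10,11) — each draw a latent class per sentence (20 classes, 2 words per
class within each 40-word content vocabulary), so within-group words
co-occur ~20× above chance, an association of ≈ 2–2.5 nats.  Groups are
restricted to originally adjacent pairs deliberately: the
maximal-separation scramble provably pushes every class-correlated pair
outside the sliding window, while local swaps leave almost all of them
inside it.  Function vocabularies are small closed classes; content
vocabularies are disjoint pronounceable pseudo-words, so adjacent slots
can never hold identical tokens and a single swap always displaces a
word.  Each slot ignores its category and class with probability
`noise_rate` (default 0.05) and samples from the union vocabulary; at
`noise_rate = 1` tokens are i.i.d. and association vanishes.

What the language does not emulate: morphology, agreement, variable
length, recursive structure, and frequency spectra (vocabularies are
near-uniform).  The fixed template itself contributes a baseline of
positional association (certain category pairs always co-occur at certain
gaps) that survives in the word-list condition — analogous to the residual
association in real word lists — so condition contrasts are assessed as
ratios to the intact condition, not against zero.  Passing tests show the
estimators and constructions behave correctly on a language with known
structure; they do not certify absolute PMI levels of any natural corpus.

Stimulus sets contain, per item: the intact sentence, one row per swap
level (default 1, 3, 5, 7), the maximal-separation scramble, and a
word-list row in which every token is replaced by a different
same-category word (per-position word class preserved, class coherence
destroyed).

## Response simulation

Responses are simulated as condition mean + participant intercept + unit
(item or ROI) intercept + Gaussian residual, all crossed; accuracy
outcomes pass the linear predictor through an inverse logit and a
Bernoulli draw.  Default generating values for the neural outcome are the
reported percent-BOLD condition estimates of the replication experiment
(intact 0.90; +0.03, −0.10, −0.02 for 1/3/5 swaps; −0.35 low-PMI; −0.46
word list) at its sample size (32 participants × 6 regions); noise SDs
are back-calculated from the reported standard errors (contrast SE ≈ 0.08
→ residual SD 0.8; intercept SE 0.18 → participant SD 1.0).  Rating
defaults encode the reported successive naturalness drops (−2.04, −1.42,
−0.56, −0.23 around a grand mean of 3.54) at 76 participants; accuracy
defaults encode the reported log-odds condition effects at 16
participants.  All values are configurable.

## Effect estimation

The estimator targets condition contrasts with a two-stage cluster
bootstrap: stage 1 collapses to per-participant condition means (for
accuracy, per-participant log-odds with a 0.5 continuity correction, so
perfect cells stay finite); stage 2 applies contrast weights to those
means and reports the across-participant mean with percentile bootstrap
95% CIs resampling participants (default 5,000 resamples; percentile
rather than BCa, as coverage at these sample sizes is already within
0.90–0.99 in the simulation checks).  Contrast weights are derived from
the coding matrix as the non-intercept rows of inv([1 | C]), so dummy
coding yields level-minus-reference and backwards-difference coding
yields successive differences.  Everything is deterministic given the
seed.

This estimator deliberately substitutes for Bayesian mixed models with
maximal random effects: it targets the same estimands (condition
contrasts clustered on participant) without a probabilistic-programming
dependency.  Agreement with any particular posterior summary is not
claimed; the simulation tests check sign, significance pattern, and CI
coverage under the generating model, and those are the properties relied
upon.  Random-slope structure and crossed item/ROI random effects are not
modeled beyond the participant clustering.

## Numerical and procedural choices

* 1-based token positions in all serialized permutations; 0-based
  internally.
* TSV everywhere, UTF-8, header required, strict field counts, errors
  report file and line number; count tables round-trip integers, V, and α
  exactly.
* Degenerate inputs: strings shorter than 2 tokens yield empty profiles
  with mean 0; all-content or all-function sentences degenerate to a
  single interleave; n_boot < 100 logs a warning rather than failing.
* Problem sizes in the test suite: ~10^5-token corpora, 150-item stimulus
  sets, 200-replicate coverage runs at 500 bootstrap resamples — sizes at
  which every qualitative property is stable across seeds while the whole
  suite stays fast.

## Known limitations

* The low-PMI construction is canonical, not sum-optimal (see above).
* The template language's positional baseline association means absolute
  PMI values are not comparable to natural-corpus values; only within-run
  condition ratios are interpretable.
* The estimator clusters on participants only; item-level dependence is
  averaged over in stage 1, which is anticonservative if item effects are
  large and items are few.
* Accuracy contrasts are on the continuity-corrected log-odds scale and
  are slightly attenuated toward zero for extreme cells.
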