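# Methods

## The model

`lexiprop` builds a two-polarity word lexicon by semisupervised label
propagation on a similarity graph.

**Seed scoring.** Corpus TF-IDF uses per-document relative term frequency
`tf(i,j) = n_ij / Σ_k n_kj` and unsmoothed natural-log inverse document
frequency `idf(i) = ln(D / DF(i))`, aggregated as the mean of per-document
tf·idf over all `D` documents (documents lacking the word contribute 0).
The mean — rather than the sum — keeps scores comparable across corpora of
different sizes; a word occurring in every document scores exactly 0.
One post is one document everywhere in the package.

**Candidate expansion.** A word joins the candidate set `C` when its cosine
similarity to some seed reaches the threshold `T_c` (default 0.5, the value
used for all methods in the package's own benchmarks); the extending seed
joins `C` too. After `C` is collected, *all* pairwise similarities within
`C` that reach `T_c` become edges, not just seed–word pairs. A pure
seed–star graph would make propagation a one-shot average and waste the
graph structure; the inter-candidate edges are what lets evidence flow
between candidates. Expansion is a single pass — newly added candidates do
not recruit further words.

**Propagation.** With edge weights `w_ij = sim(w_i, w_j)`, the transition
matrix is column-normalized: `T[i][j] = w_ij / Σ_k w_kj`, so each node's
incoming weights sum to 1 and the update
`Label[j] = Σ_i T[i][j] · V[i]` replaces node `j` by a convex combination
of its neighbours' labels. Seeds are reset to −1/+1 after every round.
Convex updates keep every label in [−1, +1] (the implementation clips the
~1e−16 float excess so the bound holds exactly), and on any connected
component containing a seed the iteration is a contraction with a unique
fixed point. `solve_exact` computes that fixed point directly:
`f_U = (I − M_UU)^{-1} M_UL f_L` over the unknown block, and serves as the
independent oracle for the iterative solver. A row-normalized variant is
exposed (`normalization="row"`) for sensitivity checks; column is the
default because it makes the update an average and guarantees boundedness.

Convergence means the maximum absolute per-node label change drops below
`tol` (default 1e−6; the oracle-comparison tests use 1e−8), with
`max_iter = 1000` as a guard; non-convergence returns the current state
with a warning rather than raising. Unknown nodes in seed-free components
have no unique fixed point; they keep label 0, are excluded by the cut, and
are reported in diagnostics.

**Thresholding.** A candidate enters the lexicon when `|label| > 0.5`
strictly; the strict inequality is deliberate so a label sitting exactly at
the cut (e.g. the symmetric two-seed chain) is excluded. Seeds are always
included at −1/+1: they are members of the candidate set and the natural
anchors of the output lexicon.

## Comparison methods

All three consume the same seed set and threshold as the propagation
method, so comparisons are like-for-like.

- **Nearest-seed inheritance (`w2v`)**: each extended word takes the
  polarity of its highest-similarity extending seed; an exact similarity
  tie across opposite polarities excludes the word.
- **Semantic orientation from embeddings (`so-w2v`)**:
  `score(w) = mean_{s∈nondep} cos(w,s) − mean_{s∈dep} cos(w,s)`; the mean
  (not the sum) keeps unbalanced seed sets from biasing the sign. Zero
  scores are excluded.
- **SO-PMI**: co-occurrence is counted binarily per document (one post),
  `PMI(w,s) = log2((c_ws + ε)·D / ((c_w + ε)(c_s + ε)))` with add-half
  smoothing `ε = 0.5` so zero counts stay defined, and
  `SO-PMI(w) = Σ_{s∈nondep} PMI(w,s) − Σ_{s∈dep} PMI(w,s)`. With count
  smoothing, PMI is invariant under document duplication only up to
  `O(ε/count)`; the tests assert label stability and near-invariance rather
  than exact equality. By default SO-PMI scores the same candidate pool as
  the embedding expansion so lexicon comparisons are aligned; scoring the
  whole corpus vocabulary is available as an option.

## Word vectors

Vectors are read and written in word2vec text format. The in-package
trainer is count-based: positive PMI over symmetric within-document context
windows (default width 5), factorized by truncated SVD with word vectors
`U·√S` — the classical spectral equivalent of skip-gram embeddings. It is
fully deterministic given its seed (single-threaded, fixed SVD seed), which
the neural alternative cannot cheaply guarantee. Words with no
positive-PMI context would receive a zero vector, undefined under cosine;
they get a tiny seeded random direction instead. Defaults:
`dim=100, window=5, min_count=5`.

## Evaluation

The positive class is *depressive* throughout: TP = depressive gold words
predicted depressive, FP = nondepressive gold predicted depressive, FN =
depressive gold predicted nondepressive. Predicted words absent from gold
are excluded and counted separately. Degenerate precision/recall
denominators yield NaN with a warning, never a silent 0. AUC is the
rank-based pair probability (ties ½) that a depressive word scores more
depressive (more negative) than a nondepressive one; it is checked against
brute-force pair enumeration.

Sweeps subsample balanced seed sets deterministically and *nested*: each
polarity list is shuffled once from the sweep seed and prefixes are taken,
so a larger seed budget always contains the smaller one. That makes
lexicon size provably monotone in seed size for the expansion step and
keeps sweep rows comparable.

## Detection features and classifiers

Per user, over the concatenated token stream: 30 TF-IDF topic-keyword
relative frequencies (keywords ranked on the depressed training split),
mean post length and post count, first-person pronoun rate per 1000 tokens
(default list covers English and Chinese), the mean embedding vector of the
user's in-vocabulary tokens ("linguistic style"), and two lexicon rates —
depressive-word and nondepressive-word tokens per 1000 tokens. The two
rates are the lexicon's entire contribution to the model, which makes the
ablation (`with_lexicon=False`, an exact column subset) clean and
interpretable.

Classifiers are scikit-learn defaults (LR and SVM behind a standard
scaler), evaluated by stratified 5-fold cross-validation with a fixed seed;
metrics are computed from pooled out-of-fold predictions. The imbalance
sweep keeps the full non-depressed pool and subsamples depressed users to
each target proportion, reporting cross-validated AUC.

In the detection benchmark the lexicon is an *external input* built
upstream on the construction benchmark, while the style embeddings are
trained on the detection corpus itself — mirroring how the method is
deployed: the lexicon comes from a dedicated construction corpus, and the
embedding features come from the data at hand. Reusing the construction
geometry for the style feature would leak the planted polarity axis
directly into the style vector and mask the lexicon's contribution.

## The synthetic benchmarks

The generator emulates a two-cohort microblog collection. Each post draws
`tokens_per_post` tokens from a mixture over a shared background
vocabulary (weight 1 per word), the cohort's own polarity words (weight
`enrichment`) and the opposite cohort's words (weight `1/enrichment`).
The companion geometric embedding space puts depressive words in a
Gaussian cluster at `+r·e1`, nondepressive at `−r·e1`
(`r = cluster_separation/2`, per-coordinate `noise_sd`), background
isotropic at the origin.

Two versioned parameter sets live in `data/benchmarks.yaml`:

- **lexicon** — 100 background + 30/30 polarity words, 50 users/group × 20
  posts × 15 tokens, enrichment 6, dim 50, separation 2√2, noise 0.1.
  With this geometry the expected within-cluster cosine is
  `‖c‖²/(‖c‖² + d·σ²) = 2/2.5 = 0.8` and the cross-cluster cosine ≈ −0.8,
  comfortably straddling `T_c = 0.5`: a clean recovery benchmark on which
  a correct implementation should reach F1 ≈ 1 from a 20-seed subset.
- **detection** — 100 users/group × 10 posts × 20 tokens, enrichment 1.2:
  roughly a 22% vs 16% polarity-token share between cohorts, so individual
  per-user features are noisy and the aggregate lexicon rates genuinely add
  information over the 30 keyword columns. Accuracies land in the
  0.75–0.95 range and the lexicon ablation shows a consistent positive gap
  for all five classifiers.

What the generator does **not** emulate: real word-frequency (Zipfian)
distributions, topic drift and burstiness, Chinese morphology and
segmentation errors, posting-time structure, or label noise in the cohort
assignment. Passing the benchmarks therefore demonstrates correctness of
the algorithms under planted structure, not performance on real microblog
data; on real corpora the separations are smaller and every method's
numbers drop.

## Numerical choices and degenerate inputs

- Cosine of a zero vector is a domain error; trained embeddings are nudged
  off zero (see above) and loaded spaces reject all-zero rows.
- Transition columns of isolated nodes are all-zero; such nodes keep label
  0 and are reported, not dropped silently.
- Tie-breaks: TF-IDF ranking orders equal scores by descending document
  frequency, then lexicographically; candidate edges are stored once with
  endpoints in sorted order; graph node order is seeds (dep, then nondep,
  lexicographic) before unknowns (lexicographic), which fixes the matrix
  indexing and makes runs bit-reproducible.
- Emoji stripping removes a fixed list of Unicode pictograph blocks plus
  variation selectors/ZWJ adjacent to a removed code point; it is
  idempotent and leaves ASCII emoticons untouched.
- Tokenization is pluggable (default: whitespace); user dictionaries
  protect multi-token entries by greedy longest match. A Chinese segmenter
  can be plugged in as a callable without touching the pipeline.

## Known limitations

- Expansion is single-pass; no snowballing from newly added candidates.
- Two polarities only; no neutral class or multi-class propagation.
- The SO-PMI window is fixed at one document; sub-document windows are not
  implemented.
- The detection module has no temporal features and no calibration; SVM
  AUC uses decision-function scores rather than calibrated probabilities.
- Seed curation itself is manual by design: the package ranks candidates
  and validates the curated lists, it does not choose seeds.
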