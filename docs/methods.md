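# Methods

This note documents the models implemented in `semspace`, their
assumptions, the defaults that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Corpus processing

Documents are classified as mathematical when their raw text contains at
least one portal tag string (the footer convention of French Wikipedia;
the default tag list covers the mathematics, geometry, analysis, algebra,
probability/statistics, number-theory, logic and theoretical-computer-
science portals). Classification is a pure string search: precision and
recall are whatever the tagging convention provides, and the partition is
exhaustive — every input document is labeled exactly once.

Test and synthetic corpora are tokenized by lowercased whitespace
splitting; real-corpus tokenizers are pluggable callables. Lemmatization
is a word-form → lemma mapping applied a configurable number of passes
(two by default, so that lemmas which are themselves inflected resolve),
with an identity fallback for unknown forms — token counts are therefore
invariant under lemmatization.

The vocabulary keeps words with at least `min_count = 5` occurrences,
sorted by decreasing count and truncated to `max_size = 50 000`. Ties in
count are broken lexicographically; the rule is arbitrary but makes ranks
reproducible. Log frequency is log₁₀ occurrences per million tokens and is
undefined (stored missing, never zero-filled) for absent words. The
annotation join is outer with an explicit missing flag: an unannotated
word is visible downstream, not silently dropped.

## Cooccurrence and embeddings

Two vocabulary words cooccur when they are within `window = 15` token
positions inside one document. Each unordered pair occurrence at distance
d adds 1/d (inverse-distance weighting; `uniform` is available) to both
symmetric cells; same-word pairs accumulate once on the diagonal, and the
diagonal is never consulted by similarity analyses. Out-of-vocabulary
tokens are skipped as pair members but still occupy positions, so they
count toward distances. Windows never cross document boundaries. The
vectorized scan is verified against an exhaustive pair-enumeration oracle
to 10⁻⁹.

Embeddings minimise the weighted least-squares objective
J = Σ f(X_ij)(w_i·w̃_j + b_i + b̃_j − log X_ij)² over the nonzero entries,
with f(x) = min((x/x_max)^α, 1). Defaults: x_max = 100, α = 0.75,
learning rate 0.05, 50 epochs — the standard choices for this model
family; the study-level design choices are only the window (15) and the
dimensionality (50 as the reference, a sweep over 1–50 and 100–500 in
steps of 50 available). The exported vector is w + w̃; whether to export
w, w̃ or their sum is a genuinely open choice and the sum is the common
convention.

Optimisation is mini-batch AdaGrad with the shuffle order drawn from the
seed and accumulator values frozen at batch start; duplicate indices
within a batch are handled by scatter-addition. This makes training
exactly reproducible on one CPU — a deliberate departure from asynchronous
per-sample SGD, whose results are machine-dependent. Accumulators start
at 1 so the first step is bounded by the learning rate. The epoch-level
loss trend is monitored (non-increasing on the test fixtures); per-step
monotonicity is not guaranteed, as with any stochastic method.
Vocabulary-constrained training on an alternate corpus gives words with
no cooccurrence mass a flagged zero vector that downstream correlations
exclude — coverage is reported, never imputed.

## Similarity analysis

Pair selection works within grade groups (the eight curricular grades
merged to five: primary, 6–9th, 10–12th, bachelor, licence+master). For
each target word the k = 3 candidates with maximal cosine (*close*),
minimal cosine (*opposite*), minimal |cosine| (*orthogonal*) and cosine
nearest the group's mean pairwise cosine (*mean*) are selected; ties break
lexicographically. Pairs are deduplicated on the unordered key, keeping
the first-encountered category and logging collisions. Selection is
verified against a brute-force oracle on small vocabularies.

Ratings are averaged per pair before correlation; the grand mean over
trials is kept separately since it differs from the mean of means under
unequal trial counts. All regressions operate on mean-tie ranks
(`scipy.stats.rankdata` semantics) with an explicit intercept; interaction
terms are products of main-effect ranks, re-ranked for scale
comparability. Exact collinearity is detected and reported by term, not
silently dropped.

The noise ceiling is leave-one-out: each participant's ratings are
Pearson-correlated with the mean rating of the remaining panel over the
pairs they share; the squared correlations are averaged. Participants
sharing fewer than 3 pairs, or with constant ratings, are skipped and
counted. For subgroup ceilings each member is referenced against the
leave-one-out mean of the *full* panel — subgroup-internal overlap alone
can be too sparse, and excluding the held-out rater avoids the small
self-correlation bias that including them would introduce. The estimator
converges to V/(V + σ²/(n−1))·V/(V + σ²) under an additive
signal-plus-noise model, which is how the calibration test computes its
analytic expectation; like any leave-one-out ceiling it is an
approximation that tends to be optimistic.

Model comparison uses AIC from the Gaussian likelihood of rank-OLS fits
(statsmodels' definition), ΔAIC relative to the best model, and the
evidence weight p = exp(−ΔAIC/2). Pairing a rank correlation with a
Gaussian AIC involves a choice of likelihood that the rank statistic
itself does not fix; the rank-OLS likelihood is the simplest coherent
option and is used consistently, so only *differences* between models
fitted to the identical response are ever interpreted. Category contrasts
use Kruskal–Wallis with tie correction followed by Dunn's z tests with
Bonferroni adjustment (implemented here; the pooled-rank variance includes
the tie term). Percentile binning defaults to 100 equal-count bins with
any remainder spread over the first bins.

## Item response theory

Familiarity (0–8) is dichotomized at ≥ 4 = "known" — the boundary is part
of the scale's labeled semantics (4 = "vague idea"). The 2PL model is fit
by marginal maximum likelihood: EM with a fixed quadrature grid of 61
equally spaced nodes on [−6, 6] carrying standard-normal weights
(renormalized), tolerance 10⁻⁵ on the maximal parameter change, at most
500 iterations. The M-step runs per-item Newton updates on the
(slope, intercept) parametrization with step-halving, so the expected
complete-data likelihood — and therefore the marginal likelihood — never
decreases; this is checked to 10⁻⁸ in the tests. Items whose observed
responses are constant are excluded before fitting and reported: a
constant margin leaves the item's parameters unidentified. Discrimination
is bounded in (0.05, 10]; an estimate pinned at a bound clears the item's
convergence flag (the Heywood-type analogue for this model). Abilities
are EAP scores (posterior mean over the grid) with posterior-sd
uncertainties; the standard-normal prior fixes the latent scale, which is
otherwise indeterminate (a ↦ 2a, (θ−b) spread halved leaves all response
probabilities unchanged). Standard errors come from the expected
information of the (slope, intercept) fit, delta-method-transformed to
(a, b).

Curation drops items above the 90th percentile of discrimination, then
items outside the central 95 % of difficulty among survivors. Percentiles
use linear interpolation and items tied with the cut are retained. The
high-discrimination subset stratifies difficulty into equal-count bins
(4 by default) and takes the top-discrimination items per bin with
largest-remainder allocation — deterministic given input order.

## Geometry

Anchor-axis projection is t(w) = ⟨v_w − v_a, d⟩ with d the unit direction
from anchor a to anchor b; it is translation-invariant and
scale-equivariant by construction. PCA projections are mean-centered with
components in decreasing explained-variance order; an optional ordered
word pair fixes each component's sign (PCA signs are otherwise arbitrary).
Analogy consistency is the mean pairwise cosine of offset vectors
(target − source): 1 for a perfect parallelogram, near 0 for unrelated
offsets in high dimension.

The semantic map runs spectral clustering (cosine affinity clipped at 0,
k-means label assignment, 10 restarts from the seed) for every k in range,
and selects k* by the elbow rule formalized as the maximal discrete second
difference of the within-cluster dispersion curve — the named method does
not fix a statistic, and the second difference is its standard
discretization. Points and the k* cluster centers are embedded jointly in
2-d by t-SNE (perplexity 30, capped at (n−1)/3 for small inputs, PCA
initialisation, fixed seed); Voronoi cells are computed around the
projected centers and require at least 4 centers (a qhull constraint) —
below that the map carries no cells and warns. Two-dimensional layouts
are indicative only; distances in the layout are not the distances in the
embedding space, and the full structure lives in high dimension.

The domain contrast pools within-domain pair cosines of both domains
against all cross-domain pair cosines and reports a pooled two-sample t
with df = n_intra + n_inter − 2 (for 8 + 8 words: 56 + 64 − 2 = 118).

## Synthetic data

The generator defines the study conditions under which the pipeline is
exercised. The default world has 5 topics × 40 words, 12 number words, 4
number–shape analogy quadruples, and 2000 documents of 100 tokens
(~2×10⁵ tokens, ~220-word vocabulary). Documents draw words within a
sampled topic with leakage probability `topic_mixing = 0.1`; number
documents center on a magnitude and draw magnitude-neighbouring numbers
(planting a quasi-logarithmic gradient, successive magnitudes ~0.3 log
units apart); analogy documents pair a number with its shape word amid
shared context tokens. Ground-truth similarity is the cosine of explicit
latent feature vectors (topic membership, Gaussian bumps over log
magnitude, domain indicators) — it is the quantity recovery is measured
against, not a byproduct of the corpus sampler.

Participants sample one of nine education levels from a distribution
heavily skewed toward the university-educated (as online math-interested
panels are); ability is a linear function of the standardized education
rank plus Gaussian noise (slope 1, sd 0.9), and self-assessment is a
decile-discretized noisy readout whose extra noise is calibrated by
bisection against an internal 20 000-draw sample so that
Spearman(self-assessment, education) hits a configurable target (default
0.55, reflecting the moderate link such surveys find).

Familiarity is generated polytomously — latent a(θ−b) plus standard
logistic noise, cut at 8 fixed thresholds with the 4th at zero — and
dichotomized downstream, deliberately exercising the dichotomization step;
placing the dichotomization cut-point at zero makes the planted b the
difficulty of the induced binary item. Item difficulties are either
uniform on [−2, 2] (recovery simulations) or planted as increasing in
word grade and decreasing in log frequency (effect-sign tests).

Similarity ratings apply a convex monotone link to the true cosine —
default g(s) = 5·max(s, 0)², matching the convex rating-versus-cosine
curves such experiments produce — plus Gaussian noise, clipped to [0, 5].
An optional `floor` mixes in a weak linear component over [−1, 1] so the
link is strictly monotone below zero (used where opposite-versus-
orthogonal ordering must be distinguishable). Noise can be calibrated
analytically to any target explainable variance
(sd = √(V·(1−c)/c)). Two ability-linked mechanisms are available:
`attention` shrinks rater noise with ability, and `tracking` blends the
rated similarity between the primary structure and an alternate one, with
the blend weight increasing in ability — the second survives averaging
within education groups and is what plants "the primary corpus fits
educated raters best". The trial design shows each participant 20 pairs
per grade group at or below their education level and 50 familiarity
words.

What the generator does **not** emulate: real lexical statistics (Zipfian
frequencies, syntax, polysemy), response times, item-order and fatigue
effects, dropout, cultural variation in grade of acquisition, or
disagreement about word meaning. Passing recovery tests therefore shows
the estimators are correct and well calibrated under the stated generative
assumptions; it does not certify effect sizes on real behavioral data.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run at the following sizes,
chosen so that a full pass takes a few minutes on one CPU while leaving
all recovery margins wide: cooccurrence-oracle corpora up to 10⁴ tokens
(20 random draws); embedding recovery on the default 2×10⁵-token world at
dimension 25; 2PL recovery at 1000 participants × 100 items; noise-ceiling
calibration at 1200 raters × 500 pairs; rank-GLM calibration at 5000
observations × 1000 null replicates; the end-to-end rehearsal at 400
participants with a dimensionality sweep over {1, 2, 5, 10, 25, 50}.
Every stochastic component takes an explicit seed; sub-seeds are derived
by fixed offsets, and identical seeds reproduce results bit-for-bit
(single-threaded).

## Known limitations

- The GloVe loss is non-convex; different seeds give different (equally
  valid) embeddings, and only seed-fixed properties are asserted.
- The rank-GLM's Gaussian AIC is a pragmatic likelihood for rank data
  (see above); absolute AIC values are not meaningful, only differences.
- The noise ceiling is an upper-bound approximation and overestimates
  explainable variance when raters share systematic biases.
- Spectral clustering with a cosine kernel assumes cluster structure is
  angular; embeddings with dominant norm structure would need a different
  affinity.
- The 2PL standard errors ignore the uncertainty of the ability
  distribution (standard for marginal maximum likelihood with a fixed
  prior).
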