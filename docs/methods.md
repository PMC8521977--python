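# Methods

## Problem and model

`epivec` estimates age-specific disease incidence rates (cases per
100,000 population per year) for (disease, country, age-band) cells
where no direct estimate exists. The working assumption is that freely
available text corpora encode epidemiologically relevant context about
diseases and countries, so that pretrained language-model embeddings of
their *names* can serve as features for a regression model trained on
cells that do have estimates.

The regressor input for a cell is

    x = s_d ‖ c_c ‖ onehot(a)

where `s_d` is a disease sentence embedding, `c_c` a country embedding,
and `onehot(a)` a binary indicator over the twenty 5-year age bands
(0–4 … 95+). The target is `y = log10(incidence)`; zero-incidence cells
are removed before the transform (they denote either missing data or a
true zero, and neither belongs in a log-space regression). Predictions
are mapped back with `I = 10^x` per 100,000, or `10^x / 100,000` as a
proportion.

### Sentence embeddings

Word-level providers (word2vec/GloVe text format) cannot embed a
multi-word name directly. Names are tokenized (lowercase; split on
whitespace, hyphens and slashes; punctuation stripped) and the bag of
word vectors is aggregated by element-wise **min, max and mean**,
concatenated in that fixed order, giving 3× the word dimension. The
order is recorded in provider metadata; the aggregation is permutation
invariant and idempotent on single-word names. Entity-level providers
(precomputed sentence-encoder exports, e.g. BioBERT or USE tables) are
looked up by full normalized name. Providers can be fused by
concatenation in a recorded order. Out-of-vocabulary handling defaults
to `error` — silent zero-substitution corrupts features — with `skip`
and `zero` available for real-world vocabulary gaps.

### The regressor

A feed-forward "funnel" network: five hidden blocks of widths
256, 128, 64, 16, 4, each an affine map followed by batch
normalization and a ReLU, then a single affine output with no
activation (log10 targets are signed, so the output must not be
clamped). Training minimizes the root-mean-squared error with Adam
(moment decays 0.9/0.999, initial learning rate 3·10⁻⁴). The
implementation is plain numpy in float32; for the layer sizes involved
this is matmul-bound and fast enough on one CPU core, and it keeps the
whole pipeline bit-reproducible from a seed.

Settings not pinned by the architecture: batch size 256, at most 200
epochs, early stopping with patience 10 on an inner holdout of 10% of
the training rows (carved from the training fold only, so the stopping
rule never sees validation data). Inputs are z-scored per feature using
training-fold statistics (default on, recorded in model metadata).
Batches with fewer than 2 rows are skipped because batch statistics are
undefined there.

### Baselines

* **Global** — mean log10 incidence per disease (optionally per
  disease-age cell). Not applicable to diseases absent from training.
* **RidgeReg** — ridge regression on the same embedding features,
  penalty chosen by inner 5-fold cross-validation over a log-spaced
  grid 10⁻³…10³ (7 points). The age one-hot block is included by
  default.
* **OneHot (d / c / dc)** — the same funnel network over one-hot
  disease and/or country indicators (vocabulary fixed on the training
  fold) plus the age one-hot. Entities outside the training vocabulary
  cannot be encoded; such rows are reported not-applicable, which is
  exactly why these baselines cannot generalize to unseen entities.

Not-applicable predictions are excluded from every metric and counted
separately (`n_not_applicable`), mirroring N/A table entries.

### Split schemes

Three leave-out schemes correspond to the three application scenarios:

* `pair` — distinct (disease, country) pairs are partitioned into k
  folds; all 20 age rows of a pair travel together (splitting ages of
  one pair across folds would leak near-duplicate rows).
* `country` — whole countries held out (unseen-country application).
* `disease` — whole diseases held out (unseen-disease application).

k defaults to 10; entity shuffling uses only the supplied seed. Every
plan is checked for coverage, train/validation disjointness and
scheme exclusivity; `validate_split` reports counter-examples instead
of raising. Independent-test-set evaluation is modeled as a one-fold
plan trained on the full development table.

### Metrics

* **MAE in log10 space**; the companion `error_factor = 10^MAE` is the
  typical multiplicative over/under-estimation (MAE 0.2 ⇒ 1.58-fold).
* **Inter-group concordance ρ_c** ∈ [0, 1]: within each group, every
  item pair scores 1 if predictions and truth order it identically,
  0 if reversed, ½ if either variable ties; the group score is the
  mean over pairs, and ρ_c the unweighted mean over groups. 1 is a
  perfect common ordering, 0 a full reversal. The published definition
  of this statistic lives in supplementary material that is not
  available to us; this implementation satisfies every property the
  main text states (bounded [0,1], rank-based, 0 worst / 1 best) and
  sits behind one function so an alternative can be swapped in. The
  default grouping key is `country` (ranking of disease-age cells
  within a country), configurable and recorded in each report.
* **Residual bins**: items binned by the floor of the predicted
  exponent; each bin reports signed-residual mean, MAE, standard
  deviation and count — the standard view of how error varies between
  rare and common diseases.

### Context evaluation

Before an embedding is used for regression, its contextual content is
measured directly: a linear SVM predicts disease groups from disease
embeddings (or country clusters from country embeddings) under
stratified 3-fold cross-validation repeated 10 times, reported as mean
(sd) accuracy. The regularization strength is selected from
{0.01, 0.1, 1, 10, 100} by nested stratified search inside each
training portion — selection on validation folds would bias the
estimate optimistically. Folds are stratified because many classes
with few members make unstratified 3-fold CV degenerate. Multi-class
handling is one-vs-rest; features are z-scored inside each training
portion.

## The synthetic world

Real development data (GBD exports) is licensed, so the package ships
a generator that emulates its structure at configurable scale. Default
scale is 50 diseases × 30 countries × 20 age bands — large enough for
the scheme-difficulty ordering to be measurable, small enough for
minutes-long desk runs; the full-scale regime would be 199 × 195 × 20.

The generative model is additive in log10 space with a bilinear
interaction:

    log10 I(d,c,a) = mu + m_d + m_c + <u_d, v_c> + age_d[a] + eps

* `u_d, v_c` — latent factors (q = 2 by default). Group centroids are
  placed evenly on a randomly oriented circle of radius √2 and entities
  scatter around their centroid with within-group sd 0.25
  (between:within 4:1); the even spacing guarantees the stated contrast
  is realized (independent Gaussian centroids collide by chance in low
  dimension), so group labels are linearly recoverable from factors.
* `m_d ~ N(0, 0.7), m_c ~ N(0, 0.3)` — diseases differ in overall
  rarity more than countries do.
* `age_d` — a per-disease Gaussian bump over age bands (random peak,
  width and amplitude 0.2–0.8, centred to mean zero): smooth,
  disease-specific age profiles.
* `mu = 1.0` (typical rate ≈ 10 per 100,000), `eps ~ N(0, 0.1)` in
  log10 units — roughly a ±26% rate perturbation, a plausible
  estimate-level noise floor.
* A fraction `zero_rate` of cells is overwritten with exact 0,
  **uniformly at random** — whether real zeros cluster by disease or
  country is not characterized in the source data, so no structure is
  claimed.

Synthetic embeddings are `informativeness · L([u; m]) +
(1−informativeness) · noise` with `L` a fixed seeded random linear map:
at 1 the latent structure is exactly linearly decodable, at 0 the
embedding is pure noise. A deterministic hash provider supplies the
fully uninformative control.

What the generator does *not* emulate: real incidence magnitudes per
disease, sex stratification, structured missingness, and the
train/test distribution shift of an independently collected literature
test set. Passing tests therefore demonstrate that the pipeline
recovers structure its features encode — not that real-world accuracy
at any particular level is attainable.

## Expected qualitative behavior (and why)

With informative embeddings, pooled validation MAE orders
pair ≤ country ≤ disease. Pair splits are easiest (both entities seen
in other combinations). Country generalization survives because
country embeddings encode `v_c, m_c`. Disease generalization is
hardest: even perfect disease embeddings do not carry the per-disease
age profile, which is unlearnable for an unseen disease — the synthetic
analogue of the real finding that unseen-disease error is markedly
higher. Replacing country embeddings with hash vectors collapses
country-scheme performance toward the global-baseline level, and the
SVM context accuracy rises monotonically with informativeness, sitting
at chance when the embedding carries nothing.

## Problem sizes used in the shipped checks

The acceptance checks run the full grid (3 schemes + hash + global
baseline) at 50×30×20 over three world seeds with k = 3 folds and a
training budget of max 80 epochs, patience 5 — a deliberate scale-down
of the exposed defaults (k = 10, 200 epochs, patience 10) chosen so a
complete run stays in the minutes range on a single core; the measured
orderings are stable across seeds at this size. The context-evaluation
checks use 100 diseases in 5 groups with the full 10-repeat protocol.

## Numerical choices and degenerate inputs

* Batch-norm epsilon 1e-5, running-statistic momentum 0.1; inference
  uses running statistics, so batch and single-row prediction agree.
* RMSE rather than MSE is the reported and minimized loss (identical
  optimum; the gradient is rescaled by 1/RMSE, guarded at 1e-12).
* Ridge solves use scikit-learn's closed-form path.
* Ties in concordance get half credit; groups with a single item are
  excluded with a warning, and an all-singleton input is an error.
* `fuse` requires ≥ 2 parts; an all-OOV name is an error under every
  OOV policy; `log_transform(0)` is a domain error by design — zeros
  must be filtered, not silently imputed.
* Stage seeds derive from the experiment seed as
  `crc32("stage:seed") mod 2^31`, so one config seed reproduces every
  artifact byte-identically.

## Known limitations

* The concordance definition is a faithful reconstruction from stated
  properties, not a verified transcription of the published formula.
* The numpy network trains on one core; no GPU path is provided and
  none is needed at desk scale.
* The CLI's `run` command covers train+evaluate in one step; there is
  no separate checkpoint-reload workflow.
* Age bands are fixed to closed 5-year intervals with an open last
  band; other banding schemes require passing `n_age` explicitly.
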