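# Methods

`vaforecast` forecasts the next decimal visual acuity (VA) of an eye with
age-related macular degeneration (AMD) from its previous clinic visits. A
visit carries the 22 numerical OCT scalars of the ETDRS macular grid
(central-point average / minimum / maximum thickness and total volume, plus
average thickness and volume for the nine zones C0, N1, N2, S1, S2, T1, T2,
I1, I2), an anti-VEGF treatment flag, the measured VA, and a grayscale
fundus image. Because follow-up visits happen at irregular intervals and
eyes contribute between 2 and 5 visits, the pipeline's core problem is
learning from short, irregular, variable-length multivariate series.

## Synthetic cohort

No public registry of this kind exists, so the package ships a seeded
generator that emulates the statistical shape such a cohort has: ~94
patients contributing one or both eyes (both-eyes probability 0.713, giving
161 eyes in expectation), 2–5 visits per eye at gaps drawn from a normal
(mean 60 d, sd 30 d) truncated at 14 days.

The latent state of an eye is its C0 (foveal) average thickness path
`c_t` (mm): a per-eye drift (worsening eyes thicken, improving eyes thin;
the mix is the `p_decline` parameter, default 0.5), an anti-VEGF thinning
of 0.03 mm per treated visit, and AR noise. VA follows

    VA_{t+1} = clip(VA_t − s·(c_t − c̄) + e·u_t + ε_t, 0, 1)

with slope `s` (`thickness_va_slope`, default 1.0 VA/mm), baseline
thickness `c̄` = 0.27 mm, treatment effect `e` (default +0.05 VA per
treated visit), treatment indicator `u_t`, and ε ~ N(0, `va_noise_sd`,
default 0.02). Initial VA is centred at 0.65 so the clip at [0, 1] rarely
binds and the law stays identifiable from observed transitions; with
`va_noise_sd ≤ 0.02` ordinary least squares of VA_{t+1} on
(VA_t, c_t, u_t) recovers `s` and `e` within 20 % relative error.

The other zone scalars share a common factor with the foveal deviation
(weight 0.6) plus their own AR(1) wobble, yielding cross-zone correlations
near 0.5 — correlated but not collinear, as real grids are. Volumes are
thickness times an effective zone area (0.785 / 1.57 / 1.90 mm² for the
centre / inner / outer rings), keeping magnitudes in the clinically
plausible 0.1–0.6 mm³ range.

Fundus images are deliberately schematic: a centred horizontal band whose
height is proportional to C0 thickness, a left stripe tracking N1
thickness, a background level tracking total volume, and salt-and-pepper
noise at a configurable fraction. They are *not* anatomically realistic;
they exist so that image embeddings provably carry retinal-state signal,
which is what the downstream ordering checks need. Passing tests therefore
show the pipeline's mechanics are sound, not that the models would reach
the same accuracy on clinical scans. Images default to 64×64 (32×32 in
most tests) rather than clinical 512×496 to keep a desk-scale CPU budget;
the size is configurable.

Ground truth (latent thickness path, pre-noise VA, per-eye decline flag)
is stored in a separate object/file that no model ever reads; only
recovery tests use it.

## Ingestion

The XML dialect mirrors the Spectralis ETDRS export (global
`CentralThickness`, `MinCentralThickness`, `MaxCentralThickness`,
`TotalVolume`; per-`Zone` `Name`, `AvgThickness`, `Volume`,
`ValidPixelPercentage`). Zones are keyed by name, missing tags are marked
missing rather than fatal, malformed numbers raise naming the tag.

VA notations are normalised to decimal: Snellen fractions by direct
division (20/40 → 0.5, 6/60 → 0.1), LogMAR x → 10^(−x), ranges by the mean
of the endpoint decimals. Values above 1.0 decimal (e.g. 20/16) are
clamped to 1.0 because the forecaster's output unit is sigmoid-bounded;
clamping is logged. Eyes with fewer than two visits are excluded.
Where the VA index and OCT files disagree, the default keeps the
intersection; union mode keeps index visits and marks OCT fields missing.

## Series preparation

One month is fixed at 30.44 days (mean Gregorian month); a visit's bin is
`floor(days_since_first / 30.44)`. Two encodings:

* **resampled** — one record per month bin from 0 to the last visit's bin;
  occupied bins take the visit's values (on collision the later visit
  wins — it is closer to the outcome), empty bins are filled feature-wise
  by linear interpolation `y = y1 + (t−t1)(y2−y1)/(t2−t1)` between the
  nearest occupied bins. The treatment flag is *not* interpolated: an
  injection only happens at a real visit, so synthetic months get 0.
* **timesteps** — real visits are kept and each gains an elapsed-time
  feature (months since first); every input row of a window also carries
  the target visit's timestamp, so the model knows the forecasting
  horizon.

Windows are cut by a stride-1 sliding window of length `k`: none when
`k > n`, the whole series when `k = n`, else the `n − k + 1` contiguous
slices. The first `k − 1` visits are the input block, the k-th visit's VA
the target, so `n_input_visits ∈ {1, 2, 3}` maps to `k ∈ {2, 3, 4}`.

Missing values are linearly interpolated along time; leading/trailing
gaps take the nearest valid value (the fill that adds no artificial trend
to the sequence); an all-missing feature stays missing and is flagged.

Min–max scaling is fitted on training data only and reused on
validation/test; a constant feature maps to 0. Splits are grouped by
patient everywhere (both eyes of a patient stay on one side), which is
stricter than splitting the augmented windows directly; a `paper_mode`
switch reproduces the ungrouped post-augmentation split for comparison,
with the caveat that overlapping windows then leak across splits.

## Image pipeline

Salt-and-pepper noise is removed by a true median filter (reflected
edges) — the median, not the mean, is the correct order statistic for
impulse noise. PCA cumulative explained variance quantifies how many
linear components a target variance fraction needs, which motivates the
autoencoder's code size.

The convolutional autoencoder (built on the package's NumPy reverse-mode
autodiff core, `vaforecast.nn`) uses three stride-2 3×3 convolutions
(8→16→32 channels, ReLU) and a dense map to the latent code (256 at
clinical scale; 16–64 at desk scale); the decoder mirrors them with
nearest-neighbour ×2 upsampling + convolution and a sigmoid output.
Training: Adam (lr 1e-3), MSE reconstruction loss, 60/20/20
train/val/test split, early stopping (patience 10) with best-weights
restore. Gradients are validated against finite differences in the test
suite. Reconstruction of a corrupted image lands closer to the clean
image than the corrupted input, so the model doubles as a denoiser.
Autoencoder training uses un-preprocessed images by default; denoising
remains available as an explicit step.

## Feature selection

Pearson's r and Spearman's ρ are computed from their defining formulas
(ρ via average ranks and the rank-difference form `1 − 6Σd²/(n(n²−1))`,
which assumes tie-free data; ties get average ranks, and the library
cross-checks in the tests are restricted to tie-free vectors). A feature
is dropped by the zero-variance filter only if constant in *every*
series. Multivariate selection wraps scikit-learn's RFECV (step 1,
gradient-boosted scorer, 10-fold CV) and LassoCV (zero-weight features
removed). Selection is off by default in the experiment runner — the
pipeline's best grids are obtained without it — but every method is
available and reported.

## Forecasting

Shallow models (linear regression, gradient boosting, random forest,
extremely randomised trees; library defaults, seeded) are evaluated by
patient-grouped 10-fold CV on flattened windows (feature × lag), with the
fold count reduced and logged when fewer patient groups exist.

The recurrent forecaster is a bidirectional recurrent layer (simple
tanh / LSTM / GRU unit, hidden size 64) over the input visits; the
concatenated final states pass through dropout (0.2) and a single
sigmoid unit, so predictions always lie in (0, 1) like decimal VA. Loss
is MSE; the LSTM variant adds an L1 penalty (α = 0.01) on its
input-feature weights. Training uses Adam (lr 1e-2), early stopping on a
patient-grouped validation split (60/30/10 overall protocol), patience
20, best-weights restore; all randomness flows from one seed, so runs
are bit-reproducible.

A caveat worth knowing: with the keras-style sum-form L1 at α = 0.01 the
penalty dominates the small VA MSE on synthetic cohorts and the LSTM
underfits badly (test R² ≈ −0.1 versus ≈ 0.95 at α = 0). The penalty is
kept as specified and configurable; the default runner model and the
recovery benchmark use the GRU, which carries no such penalty.

Metrics: MSE, MAE, RMSE = √MSE, R² = 1 − SS_res/SS_tot, and
RMSPE = √mean(((a−p)/a)²) computed only over actuals above ε = 1e-3
(decimal VA can be near 0 and the ratio is otherwise unbounded); if no
actual clears ε, RMSPE is reported undefined.

Experiments assemble four feature sets per window: (1) past VA +
treatment flags; (2) the 22 OCT scalars + treatment; (3) those plus the
image embeddings; (4) the union of all. The runner produces the full
model × encoding × window-size grid as CSV/JSON with a manifest (config
hash, seeds, per-stage record counts); identical configs reproduce
byte-identical results.

## Evolution analysis

An eye's evolution label compares first and last VA: label 1 (poor) iff
the last is strictly below the first, ties count as good; a slope-sign
strategy is available as an alternative. Unequal-length series are
compared by classic dynamic-programming DTW (squared pointwise cost,
symmetric steps, no warping window — series are at most a handful of
points); the test suite pins it to an exhaustive warping-path
enumeration. Clustering is k-means-style with medoid centres, exact
under the DTW metric; its within-cluster objective is non-increasing and
two-cluster assignments are scored by agreement with the evolution
labels (up to relabelling). Supervised evolution classification uses a
gradient-boosting classifier on a single prior visit's features
(min-max scaled — the normalised variant is the default and recorded),
grouped 10-fold CV, with the confusion matrix oriented columns = actual.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale as the package's own
default study conditions: cohorts of 12–120 patients, 32×32 images,
latent codes of 16, hidden sizes 8–32, and the window sizes 1–3 the
models support. Oracle comparisons use 1e-12 for closed-form quantities
and 1e-9 where a square root is involved. Degenerate inputs (constant
features, all-missing columns, single-class labels, all-tiny actuals for
RMSPE) are flagged rather than silently propagated. Window-bin
collisions keep the later visit; RFE uses step 1; DTW tie-breaks prefer
the diagonal step when backtracking.

## Known limitations

* The synthetic images are geometric schematics; embedding quality on
  real fundus scans is untested by construction.
* The VA law is first-order autoregressive with a linear
  thickness–acuity coupling; real acuity dynamics are nonlinear and
  treatment response is heterogeneous.
* The rank-difference Spearman deviates from the Pearson-on-ranks
  estimator under heavy ties.
* `paper_mode` reproduces an evaluation protocol that leaks overlapping
  windows across splits; its scores are optimistic and included only for
  comparison.
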