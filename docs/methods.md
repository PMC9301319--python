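# Methods

This note documents the models and procedures behind `timbrefuse`, the
assumptions they make, the defaults that matter, and the design choices
taken where more than one reasonable convention exists.

## The rating model and the synthetic experiment

Listeners rate each dyad on four attributes — fusion, segregation,
roughness, pleasantness — on a 9-category scale. The analysis assumes a
Thurstonian response process: stimulus *i* occupies a latent position
`X_i` on each perceptual continuum, a rater's momentary impression is
`X_i + ε` with homoscedastic normal noise ε, and the response is the
category *g* whose boundaries bracket it, `t_{g−1} < X_i + ε ≤ t_g`
(`t_0 = −∞`, `t_m = +∞`).

The synthetic generator (`synth.LatentPerceptModel`, `synth_ratings`)
implements exactly this process, with:

* **class means** per temporal-envelope class for fusion (defaults
  5.97 / 5.51 / 3.98 for S+S / N+N / S+N, matching the observed fusion
  summaries of the emulated experiment) and roughness (defaults
  5.6 / 4.9 / 4.3, chosen to reproduce the reported roughness ordering
  S+S > N+N > S+N at an effect size comparable to fusion's);
* **mirror coupling**: segregation and pleasantness are generated as
  `pivot + c·(source − pivot) + η` with negative coefficient `c`
  (default −1) around pivot 5, from fusion and roughness respectively,
  plus small independent noise (SD 0.15). This plants the near-mirror
  correlation structure the analysis is meant to detect;
* **spreads**: between-stimulus SD 0.8 within a class, rater noise
  SD 1.0 — values that give inter-rater reliabilities (Cronbach's α in
  the low-to-mid 0.9s with 32 raters) of the magnitude a well-run
  listening test produces;
* **boundaries** at the category midpoints 1.5 … 8.5, so the latent
  scale is directly in category units;
* a **complete design** (every rater rates every stimulus). The real
  experiment's subject/stimulus grouping is ambiguous; the scaling
  model needs complete proportions, so completeness is the default.

The default stimulus design is 518 dyads, 259 per instrument culture,
with envelope-class totals 226 S+S / 227 S+N / 65 N+N (split
113/113/33 and 113/114/32 across cultures; the within-culture split of
the odd totals is a package convention).

## Dyad synthesis

Each voice is an additive harmonic complex: partial *h* of fundamental
`f0` has amplitude `h^(−slope)` and a random phase. Sustaining voices
use attack → plateau → release (release over the last 5% of the note);
non-sustaining voices decay exponentially after the attack with
τ = duration/8, which takes the envelope below 10% of peak well before
half the note — the property that makes envelope classes measurable
from audio. Broadband Gaussian noise, shaped by the voices' combined
envelope, is mixed in at an exact target noise-to-total energy
fraction. Dyads are in pitch unison or octave. Loudness equalization is
RMS matching — a scalar gain — rather than an ITU-style loudness model;
for synthetic fixtures the distinction is immaterial and the simpler
operation is exactly invertible.

Default duration is 1 s at 44.1 kHz; long enough for stable frame
statistics and envelope measures, short enough that a 518-stimulus
experiment synthesizes and analyzes in about a minute.

What the generator does *not* emulate: real instrument spectra
(formants, inharmonicity, transients), room acoustics, and rater
idiosyncrasies (scale-use differences, drift). Passing tests therefore
demonstrate that the *analysis* recovers planted structure under the
model's assumptions — not that real listening data satisfies those
assumptions.

## Ratings QC

Cronbach's α is computed per attribute with **raters as items and
stimuli as cases**: `α = k/(k−1)·(1 − Σ item variances / total-score
variance)`. The validity filter removes, per stimulus × attribute,
ratings outside mean ± 1.5 SD (SD across raters, ddof = 1), in a
**single pass** (bounds are not recomputed after removal), and imputes
the mean of the retained ratings so the matrix stays complete for
scaling. Imputed values are real-valued by default — they feed the
scaling stage as proportions, where rounding would discard information —
with integer rounding available via `round_imputed=True`.

## Successive-categories scaling

For stimulus *j* and boundary *g*, the cumulative proportion
`P_gj` of responses ≤ *g* (a non-integer imputed response counts as
≤ *g* when it is < g + 0.5) is inverse-normal transformed:
`z_gj = Φ⁻¹(P_gj) = t_g − f(a_j)`. With the identifiability constraint
mean`f = 0`, the estimator is the row/column-mean solution

    t_g    = mean_j z_gj
    f(a_j) = mean_g t_g − mean_g z_gj

which coincides exactly with the least-squares solution of the additive
model on a complete z-table (verified against a brute-force solve in
the tests). Extreme proportions 0 and 1 have no finite z; they are
**clipped** to `[1/(2N), 1 − 1/(2N)]` for N raters (default), or
treated as missing cells with nan-aware means (`extreme="drop"`).
Clipping preserves the complete table the simple estimator wants but
biases the outermost boundary estimates slightly inward; interior
boundaries and scale differences are unaffected. Stimuli whose
responses are all in one extreme category carry no interior information
and are flagged. Boundary variances are not estimated; only locations
are used downstream.

`rescale_to_categories` maps z-units to 1–9 category units by the
least-squares affine map from estimated boundaries `t_g` to their
nominal positions `g + 0.5`; this is order-preserving and invariant to
affine changes of the latent scale.

## Perception statistics

* One-way ANOVA is a direct between/within sums-of-squares
  decomposition.
* The two-way envelope × culture ANOVA uses **Type III sums of squares
  with sum-to-zero contrasts** (via statsmodels OLS): the emulated
  design is unbalanced, and Type III matches the reporting style of the
  commercial packages this kind of study uses. When the interaction is
  not significant at α = 0.05 the model is refit with main effects
  only, and both results are returned.
* ANOVAs run on **stimulus-level scale values** (one value per
  stimulus), not rater-level responses; the residual degrees of freedom
  of the emulated study imply that reading.
* SNK homogeneous subsets: groups ordered by mean; a contiguous stretch
  of *r* means is homogeneous when its studentized range statistic is
  below `q(α, r, df_error)` with the harmonic-mean group size; subsets
  are formed greedily from the smallest mean upward, which yields an
  exhaustive, non-overlapping partition (the classic presentation can
  produce overlapping subsets; a partition is easier to consume and
  identical in the three-group cases at issue).
* The preference map (MDPREF) is **standardized principal components**:
  columns z-scored, SVD, attribute loadings reported as
  attribute–dimension correlations, class centroids projected into the
  space. Full optimal-scaling CATPCA is deliberately not implemented —
  scale values are already numeric at this stage, so the optimal
  scaling step would be near-identity — but sign/rotation of the
  dimensions may consequently differ from an optimal-scaling fit.
  Dimension 1 is oriented so fusion loads positively; each further
  dimension so its dominant attribute loads positively.

## Acoustic descriptors

Front end: Hann STFT with 23.2 ms window and 5.8 ms hop (1023/256
samples at 44.1 kHz), the frame conventions of the classic timbre
toolboxes. Conventions fixed for reproducibility:

* Spectral moments (centroid, spread, skewness, kurtosis) use the
  per-frame energy probability `P(E(n)) = |X(n)|²/Σ|X|²` on the
  **linear** frequency axis. (An auditory ERB-rate frequency axis is a
  plausible alternative; the linear axis keeps the analytic fixtures —
  tone at 440 Hz → centroid 440 Hz — exact.)
* Flatness is the geometric/arithmetic mean ratio of **band-averaged**
  power (32 equal-width bands). Raw periodogram bins are exponentially
  distributed, which caps raw-bin flatness near e^(−γ) ≈ 0.56 for white
  noise; band averaging restores the intended near-1 reading for noise
  and near-0 for tones.
* Roll-off is the smallest frequency whose cumulative energy reaches
  95% of the frame's energy; it is nondecreasing in that threshold.
* Partials are per-frame spectral peaks — deliberately **no single-f0
  harmonic sieve**, since dyads have two fundamentals. A peak must be a
  local maximum within 50 dB of the frame maximum *and* at least 8×
  above the frame's noise floor, estimated as median bin energy / ln 2
  (the median sits in the noise field; for exponential noise bins the
  mean is median/ln 2). Each spectrum bin within ±3 bins of a peak is
  assigned to its *nearest* peak (no double counting of overlapping
  lobes), and the noise-floor share is subtracted, so harmonic energy +
  noise energy reconstructs total frame energy to ~1%. Noisiness =
  noise/total; on synthesized dyads it tracks the generator's planted
  noise fraction within ±0.05.
* Tristimulus and the odd-to-even ratio are energy ratios over the
  detected partials. A spectrum with no even-partial energy leaves the
  odd-to-even ratio undefined per frame; if that holds for every frame
  of a stimulus the summary reports a fixed cap (10.0) rather than
  failing.
* Envelope measures use rectification + zero-phase 20 Hz low-pass:
  attack = 10% → 90% of peak; log attack time = log10(attack);
  effective duration = span above 40%; release = last point above 50%
  to last above 5%; decrease slope = log-envelope slope from peak to
  the last point above 10%. AM is the relative envelope fluctuation
  depth in the 4–8 Hz band over the sustained (≥ 50%) segment; FM is
  the SD in Hz of the lowest-partial frequency track.
* IQR uses linear-interpolation quartiles (`numpy.percentile`
  defaults): the series 1…100 has mean 50.5 and IQR 49.5.

The 45-value summary takes mean + IQR of 18 frame-varying parameters
and mean only of 9 single-note parameters. Tristimulus contributes its
first component to the 45-set (all three components are exported in the
per-frame tables); one slot per named parameter is what makes
27 parameters → 45 statistics come out exactly. The screening operation
builds the full 8-statistic × 27-parameter candidate set (216), ranks
candidates by |Pearson r| with the target, and applies the retention
rule mean + IQR (54) minus the nine single-note IQRs (45); single-note
parameters enter the candidate set as degenerate constant series whose
spread statistics are dropped as uninformative.

## Fusion models

Features are z-standardized inside every fit, so linear coefficients
are per-SD and the |coefficient| > 4 extraction rule is scale-free
(the rule is meaningless on raw feature scales, which span orders of
magnitude). The lasso penalty is chosen by inner 4-fold
cross-validation on the training folds (no penalty value is otherwise
given); the reported equation coefficients come from an unpenalized
least-squares refit on the lasso support by default
(`refit_ols=True` in the pipeline), with raw lasso coefficients
available. Random forest: 10 trees, max 6 features per split. MLP: one
hidden layer of 32 ReLU units (width otherwise unspecified; exposed in
config), SGD with learning rate 0.001, max 500 iterations. Evaluation
is seeded 4-fold cross-validation; fold R² is `1 − SSE/SST` on the
held-out fold and may legitimately be negative. Grouped runs fit every
model kind on the pooled, Chinese-only and Western-only subsets and
emit the 3 × 3 mean-R² grid.

## Orchestration and reproducibility

`run_pipeline` derives one sub-seed per stage from the master seed
(`numpy.random.SeedSequence`), so re-running a single stage does not
perturb the others; stages communicate through files only, and the
manifest records versions, seeds and record counts. Identical configs
reproduce identical outputs byte-for-byte.

Problem sizes used in the shipped checks: the recovery simulation uses
60 stimuli × 32 raters; the calibration study 2000 null ANOVA datasets;
coefficient recovery 100 replicates at n = 518; and the end-to-end
synthetic experiment the full 518-dyad / 32-rater design with 1 s
stimuli.

## Known limitations

* The scaling estimator's outer boundaries are biased inward by
  proportion clipping; category-unit values compress slightly at the
  scale extremes (visible as planted class means of 5.97/3.98 coming
  back around 5.8/4.3 end-to-end).
* The MDPREF approximation may differ in rotation from an
  optimal-scaling CATPCA on ordinal data.
* Descriptor accuracy degrades for fundamentals below ~200 Hz at the
  default 23.2 ms window (harmonic spacing approaches the analysis
  bandwidth and partials merge); the window is configurable.
* The MLP at these sample sizes is sensitive to its random
  initialization; only seeded results are comparable.
* Model R² values on synthetic experiments characterize the generator,
  not real dyad audio, and are not comparable to values measured on
  listening-test data.
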