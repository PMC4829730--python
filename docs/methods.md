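# Methods

This note records the statistical model behind `uema`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Study design being modeled

A cohort of participants (default 27) is followed for `n_days` (default 42).
Each day carries up to `ratings_per_day` (default 5) diary prompts at fixed
clock hours (09/12/15/18/21, ±15 min jitter) collecting a one-dimensional
mood rating (integer 1–10) and circumplex valence and arousal (integers
−2..2). Six passive channels are logged continuously: call events
(direction, contact, duration), SMS events (contact), screen on/off events,
app-launch events (app id, duration), camera events, and hourly
accelerometer summaries (fraction of time above a high-activity variance
threshold, with the number of contributing samples). Day boundaries are
local midnight; a record belongs to the calendar day of its timestamp.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is demonstrated.

**Event streams.** Per participant-day, channel event counts are Poisson
with configurable daily rates (defaults: 5 calls, 2 SMS, 60 screen
sessions, 120 app launches, 3 photos — the order of magnitude typical of
student smartphone logs). Contact and app identities follow a Zipf-like
law (weights ∝ 1/rank^1.2), so "top 5" entities are well defined and
dominate interaction counts. Call durations are log-normal (median ≈ 74 s);
screen-session and app-usage durations are exponential (means 150 s and
60 s), with screen sessions truncated so on/off events stay ordered and
inside the day. Hourly activity fractions are a participant-day Beta level
modulated by a fixed diurnal profile (sleep trough, daytime plateau).

**Missingness.** Whole days drop out independently with
`missing_day_prob` (default 0.10: neither sensor data nor ratings that
day, emulating phone-off/upload-failure days), and individual prompts with
`missing_rating_prob` (default 0.08). These defaults give ≈ 38 observed
days per participant and ≈ 68% of days with all five ratings, matching a
well-run student cohort.

**Latent mood.** Each participant carries one latent daily deviation
process

    dev_d = ar · dev_{d−1} + effect · f_d + ε_d,  ε_d ~ N(0, noise_sd²)

where `f_d` are that participant's standardized day-d sensor features
(computed by the same feature pipeline the analysis uses, then z-scored
across the participant's active days) and `effect` is the configured
coupling vector in standardized-feature units. The one-dimensional mood
latent is `7.0 + dev_d`; valence and arousal share the same deviation,
rescaled by 0.66 and 1.05 around means 0.7 and −0.1 — locations and
dispersions typical of mildly positive student samples on these scales.
Sharing one latent across measures is a deliberate simplification
(circumplex and single-item mood are strongly correlated in practice);
only the mood-measure formula above is treated as the generator's
contract. Each rating is the latent value plus N(0, `measurement_sd`)
rating noise (scaled per measure), rounded and clipped to its scale.
Defaults `ar = 0.3`, `noise_sd = 0.8`, `measurement_sd = 0.7` yield daily
mood means with SD ≈ 0.9 and a weak day-to-day autocorrelation — weak
enough that the lag-based history model gains little over the mean model,
the regime observed in real student diary data. Coupling the latent to
mood-history lag *features* is disallowed (it would be circular); the AR
term is the generator's mood-history structure.

**Determinism.** Participant *i* uses `default_rng([seed, i])`, so a
single participant regenerates identically regardless of cohort size, and
the whole artifact directory is a pure function of (config, seed).

**What passing tests on these data do not show.** The generator's channels
are conditionally independent given the latent mood and have stationary
rates; real logs have weekday/weekend structure, bursty contacts, app
ecosystems that drift over six weeks, and informative missingness
(mood-related nonresponse). Results on synthetic data therefore
demonstrate the *procedures* (feature construction, selection, validation
logic) and their statistical behavior under known ground truth — not the
real-world predictability of mood.

## Feature engineering choices

* **3-day window = days d−2..d inclusive.** The window ends on the
  predicted day: passive data for day *d* exist when predicting day *d*'s
  (self-reported) mood.
* **"Normalized" histograms = divide by the window total** (sum-to-one
  over the 5 slots or 11 categories); an all-zero window stays all-zero.
  This keeps every histogram variable in [0, 1].
* **Top-5 rankings are computed once over the full study** (count-ranked;
  ties by earliest first occurrence, then lexicographic id) so each
  variable keeps a stable identity across days. Call-duration histograms
  reuse the count-based ranking; calls, SMS and apps rank separately.
* **Screen sessions** pair on→off events; sessions spanning midnight are
  split at the boundary, a trailing unmatched "on" is closed at the next
  midnight, a leading unmatched "off" is dropped, and a repeated "on"
  closes the previous session at its timestamp. Daily on-counts and
  summed durations are z-scored within participant (sample SD; constant
  series → 0).
* **Zero-event days get zeros, not missing values**, for sensor-derived
  variables; only a missing mood target or missing lag days make a row
  non-modelable. Modeling starts at day 3 (both lags must exist).
* **App categories** come from a static id→category lookup over the 11
  standard store categories, shipped with the generated data; unmapped
  apps fall into "unknown".

## Modeling and validation choices

* **Standardization uses each participant's full observed series**, so a
  small amount of target information leaks into LOOCV folds. This
  replicates the common practice in personalized-EMA analyses and is kept
  deliberately; the alternative (train-fold-only standardization) would
  change the benchmark as much as the personalized models.
* **Sample SD (ddof = 1)** everywhere a within-participant z is taken.
* **Complexity cap** `⌊n_train/5⌋` applies to both step families, computed
  from the rows actually used by the fit at hand (39 inside a 42-day LOOCV
  fold → 7; the full-series fit at 42 → 8).
* **AIC convention:** Gaussian profile form `n·ln(SSE/n) + 2(k+2)`,
  counting intercept and variance; additive constants cancel in
  comparisons.
* **Selection ties** (criteria within 1e−12) break by schema column
  order; collinear candidates and candidates producing leverage ≈ 1 are
  skipped rather than aborting selection; stepCV requires strict
  improvement to continue.
* **The selection loop** maintains an orthonormal basis of the current
  design and scores all remaining candidates with two matrix products per
  step; its residual/leverage updates are verified against brute-force
  per-candidate refits and explicit per-fold LOOCV in the test suite.
* **Wilcoxon signed-rank:** zero differences dropped; exact null
  distribution for ≤ 12 untied pairs, normal approximation with tie
  correction otherwise. The Pratt zero-handling alternative would be a
  one-line change at the `scipy.stats.wilcoxon` call.
* **Margin:** a prediction is "correct" when its absolute cross-validated
  residual is ≤ 0.5 on the standardized scale, for all three measures;
  the boundary is inclusive.
* **Incremental assessment:** training uses modelable days strictly
  before the predicted day; days 1–7 are never prediction targets.
  Per-day metrics aggregate across participants, and the
  personalized-minus-mean gap is regressed on intercept + study day
  (statsmodels OLS; intercept = relative performance at the study's
  start, slope = change per day of accrued data).
* **95% CIs** across participants are mean ± 1.96·SE; single-participant
  cells are flagged undefined.

## Problem sizes used by the test and acceptance runs

Unit tests run on 1–8 participants and 10–42 days. The end-to-end checks
use a 27-participant × 42-day null-coupling cohort (the package's
canonical demo seed 11), a 20-replicate coupling-recovery study at 40
days, 100–120 random instances for the PRESS-versus-refit oracle, and a
6-participant × 42-day double run for byte-level reproducibility. These
sizes were chosen as the smallest at which the cohort-level claims are
stable.

## Known limitations

* Per-participant pct_correct differences between families have binomial
  noise of the same order as the typical family gap at ~35 predictions
  per participant, so participant-share statements (e.g., "the benchmark
  is at least as accurate for X% of participants") are noticeably
  seed-sensitive even when the paired MSE comparison is decisive.
* The generator emits hourly activity summaries directly rather than raw
  accelerometer traces; the variance-thresholding step that produces them
  on-device is out of scope.
* No imputation: missing days simply shrink a participant's usable series,
  as in the pruning rule (≥ 20 complete days to be included, where a
  complete day has both a mood target and sensor data).
* Only forward selection is implemented; backward/bidirectional stepwise,
  regularized regression and tree ensembles are out of scope.
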