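# Methods

This note documents the models, the defaults and why they were chosen,
the numerical decisions, what the synthetic generator does and does not
emulate, and the known limitations.

## Acoustic index

The index implemented is the pair-normalised ACI: for each frequency
bin and each pair of adjacent STFT frames, |ΔP| / (P_i + P_{i−1}),
summed over bins and pairs within a window, then summed over windows
for a file total. Two properties follow directly and are enforced by
tests: the index is invariant to any positive rescaling of the signal
(each term is a ratio), and a constant spectrogram scores exactly 0.

- **Zero denominator.** A pair with P_i + P_{i−1} = 0 contributes 0.
  Silence carries no complexity; this keeps the index finite and
  monotone in signal presence.
- **Relation to the classical form.** The classical soundscape-ecology
  ACI normalises the per-bin sum of |ΔP| by the bin's total intensity
  over the window. That form is available via `classical=True`; the
  pair-normalised form is the default because it is the definition this
  pipeline is built around. The two differ: the pair-normalised index
  saturates for wideband noise (each noise pair contributes on average
  0.5 — for independent exponentially distributed powers the ratio is
  uniform on [0, 1]), so *steady* tones lower it and *modulated* sounds
  raise it. Consequently it tracks pulsed, amplitude-modulated calls
  well but is insensitive to long flat tones.
- **STFT.** Hann window, frame 1024 samples, hop 512 at 48 kHz (≈21 ms
  frames, 50% overlap); no padding, so a file yields
  ⌊(n − frame)/hop⌋ + 1 frames. Configurable; the desk-scale preset
  keeps the same frame *duration* at 8 kHz (frame 256, hop 128),
  because the index responds to power changes per frame interval and
  comparability across sample rates requires fixing the interval, not
  the sample count.
- **Windows and aggregation.** 600-s windows; a trailing remnant with
  fewer than two frames is dropped rather than rescaled so per-window
  summand counts stay comparable. Hourly ACI is the mean of member
  windows, assigned by window start time.
- **Band limit.** Default 0–24 kHz (the species' vocal range); rows are
  kept when their bin overlaps the requested interval.

## Vocal events and contexts

Calls under 5 s apart merge into one event (a gap of exactly 5 s
separates events — "less than" is strict). Merging is global by default
because caller identity is usually unknown at night; per-caller merging
is available when attribution exists. Context windows are closed
intervals [start − 10 s, start] and [end, end + 10 s]; behaviors falling
strictly inside the event go to a separate `during` bucket that the
context tables exclude. Hour binning covers 17:00–06:00 (end
exclusive), ordered 17…23, 0…5; internally hours are "hours since
17:00" to make the midnight wrap explicit. Events outside the window
are dropped and counted in a log message. The ethogram dictionary maps
21 behavior names to four categories; unknown names raise rather than
defaulting to "other" so log typos surface.

## Social metrics

- **DAI** = D_ab / (D_a + D_b − D_ab), validated to [0, 1]; a
  non-positive denominator is an input error naming the dyad.
- **Eigenvector centrality** is computed by power iteration on the
  weighted DAI matrix (uniform start, tolerance 1e−12). The iteration
  runs on A + sI with s = max row sum: the diagonal shift leaves
  eigenvectors unchanged but prevents the oscillation that bipartite
  components (e.g. star-shaped association graphs) would otherwise
  cause. Disconnected graphs are solved per component and normalised by
  the single global maximum, with a warning; isolated individuals score
  0. Weighted input is the default; binarising first is a caller
  decision.
- **David's Score** uses raw win proportions P_ij with non-interacting
  dyads contributing 0; the dyad-count-corrected variant
  (P − (P − 0.5)/(n + 1)) is behind `dyad_corrected=True`, default off.
  Scores sum to zero by construction, which the tests assert to 1e−9.
- **Rank tiers**: 1-D K-means with k = 3, 50 restarts, fixed seed;
  clusters relabeled high/medium/low by descending mean. On sorted 1-D
  data optimal k-means partitions are contiguous, which is what the
  exhaustive-search oracle in the tests exploits.
- **Kinship**: number of roster members related by the configured
  relation set, default parents, offspring, and siblings sharing a
  known parent. Links may reference non-roster individuals (they still
  create sibling links but are not counted). Cyclic pedigrees are
  rejected.

## Temporal patterns

Peaks are hours strictly above Q3, troughs strictly below Q1, with
linear-interpolation quantiles (the common statistical-software
default); boundary values are "normal" because the rule says above and
below. The labeling is descriptive and the report output says so. The
count-vs-ACI validation always reports Spearman's ρ and records the
Shapiro–Wilk gate outcome rather than switching estimators silently.
The hour-of-night test fits count ~ s(hour′, k = 8) with a thin-plate
basis on the wrapped hour index and Poisson family, pooled over nights;
k = 8 leaves the smooth room for two peaks and a trough across 13
hours.

## Count GLMM

Poisson log-link mixed model with a random intercept per individual,
fitted by lme4 (Laplace). One row per individual-night; an optional
log-exposure offset accounts for unequal recording time. Sex is coded
female = 1 against a male reference; continuous predictors (rank score,
age, centrality, relatives) are z-scored, and the synthetic generator
applies the same standardisation when running the model forward, so
planted and recovered coefficients live on the same scale. Wald 95%
CIs. When individuals have a single observation the random intercept is
inestimable and the fit degrades to a plain Poisson GLM with a warning.
VIF is computed as 1/(1 − R²) per predictor with categorical expansion;
perfect collinearity reports ∞ and names the column.

## Weather GAM

Hourly ACI is modelled with Gaussian GAMs in mgcv (REML): thin-plate
smooths (k = 8) for temperature, humidity, precipitation, zonal wind,
meridional wind, surface wind speed and surface radiation, a cyclic
cubic smooth for wind direction with knots at 0° and 360°, and
tensor-product interaction smooths `ti(temperature, humidity)` and
`ti(temperature, precipitation)` (k = 5 per margin). `ti` rather than
`te` because the univariate smooths are already in the model: a full
`te` surface re-spans the main effects and leaves the decomposition
unidentifiable, which a pilot fit confirmed (inflated main-smooth
statistics).

Selection runs in two stages. Four candidates — main effects only, each
interaction alone, both — are fitted and the lowest AIC wins (the audit
trail for this choice is the reported candidate-AIC table). Then
non-significant smooths are removed one at a time, largest p first,
ties broken by term order, until all retained terms are significant.
**"Significant" is family-wise across the candidate's m₀ smooth terms
(Bonferroni, threshold α/m₀, α = 0.05).** The plain per-term threshold
is available as `multiplicity="none"`, but it is not the default for a
measured reason: per-term p-values under the null are well calibrated
(≈6–7% below 0.05), yet backward elimination selects the minimum of ~10
of them, and with a plain 0.05 threshold roughly a third of pure-noise
datasets end with a spuriously retained smooth. The family-wise
threshold restores the property one wants from the procedure — a noise
input yields an empty model ≈95% of the time — while planted effects
(p ≈ 10⁻³⁰) are unaffected. Shrinkage selection (`select=TRUE`) was
evaluated and rejected: its p-values were anti-conservative in the same
pilot.

## Friedman test

Blocks are night hours, treatments are behavior categories; counts are
ranked within each hour with average ranks for ties (tie-corrected
chi-square, df = k − 1). Sleep is excluded from the default three-way
comparison (aggression / social / other) and can be included by passing
the category list. A constant table carries no rank information and
returns statistic 0, p = 1. Note the test detects *consistent* level
differences across blocks; two categories in opposite phase across the
night can balance out.

## Synthetic generator

The generator is the package's ground-truth instrument, not a fixture.
What it emulates: a 17:00–06:00 night with an inhomogeneous-Poisson
call process whose per-hour expectations are bimodal (peaks 18–19 and
21–23, ≈5× the late-night trough); calls as pulsed harmonic stacks
(fundamental 650 Hz, 6 harmonics, 0.4 s, 12 Hz pulse rate) — the
pulsing matters, because the pair-normalised ACI responds to
frame-to-frame modulation, not to steady tones; Gaussian noise whose
level rises with surface wind speed; behavior logs whose category mix
is aggression-heavy near 18:00 and social-heavy near 21:00–22:00 with
sleep rising late; a linear dominance hierarchy (higher rank wins a
bout with probability 0.9, ≈6 bouts per dyad); kin families of 3 with
≈12× higher within-family co-proximity; attributes and counts from the
forward Poisson mixed model (default coefficients: intercept 7.748,
rank −0.285, sex −1.909, age −1.342, centrality −2.163, relatives
0.249; random-intercept SD 0.5); and AR(1) hourly weather (φ = 0.8)
with wind speed/direction derived from the zonal and meridional
components and a planted ACI coupling (Gaussian bump in meridional
wind, a negative temperature×humidity product on z-scales so cold-humid
hours raise ACI, noise SD 0.3).

What it does not emulate: realistic macaque call types or repertoire,
sound propagation and attenuation, recorder frequency response,
non-target species, missing data, observer error in logs, or any
dependence of the social covariates on each other (attributes are drawn
independently). Passing tests therefore show the *pipeline* recovers
what was planted under clean conditions; they do not certify detection
or attribution performance on field recordings.

All generator defaults live in `config/defaults.yaml`. Problem sizes:
study scale is 48 kHz audio, 3600-s hours and 600-s ACI windows;
analyses in the test suite and examples use the desk-scale preset
(8 kHz, 90-s hour-blocks, 30-s windows, same frame duration), which
keeps hourly call counts, coefficients and weather at study magnitude
while audio volume shrinks ~270×. Simulation studies use 50
individuals × 30 nights for the count model and 400 weather hours for
the GAM, sizes at which coverage and selection behaviour are stable.

## Known limitations

- The GAM and GLMM stages shell out to R (mgcv, lme4); without an R
  installation those two stages are unavailable, though everything else
  works.
- The pair-normalised ACI saturates under broadband noise, so its
  dynamic range across hours is narrow (see the worked example: hourly
  values differ by ~0.5%); ranks are informative, absolute differences
  are not.
- Backward selection after AIC candidate choice is a greedy procedure;
  it is deterministic and auditable (the removal trace is returned) but
  not guaranteed to find the best subset.
- The quartile peak rule is descriptive; formal bimodality testing is
  out of scope.
- Centrality on a disconnected association graph is normalised by the
  global maximum, which makes cross-component comparisons ordinal at
  best (a warning is emitted).
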