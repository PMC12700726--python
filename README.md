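# nocturne

Analysis pipeline for **nocturnal vocal activity of a diurnal primate
group** monitored with passive acoustic recorders and synchronized
infrared video. Field teams studying Tibetan macaques (*Macaca
thibetana*) — or any group-living species whose calls dominate the night
soundscape — get a tested, reproducible path from raw WAV files and
delimited observation logs to hourly activity patterns, social-network
and dominance metrics, and the two inferential models that ask *who*
vocalizes and *under which conditions*.

## What it computes

**Acoustic Complexity Index (ACI).** Audio is divided into 600-s
windows; within each window, for the power spectrogram *P*(*f*, *t*ᵢ)
band-limited to the species' vocal range (0–24 kHz),

    ACI = Σ_f Σ_i |P(f, tᵢ) − P(f, tᵢ₋₁)| / (P(f, tᵢ) + P(f, tᵢ₋₁))

Transient, modulated sounds (calls) change power between adjacent frames
and score high; steady noise scores low. Window values aggregate to an
hourly series and a whole-file total.

**Vocal events and behavioral context.** Calls separated by less than
5 s merge into one vocal event; every logged behavior within 10 s before
the first call and 10 s after the last is attached as the event's
context and mapped to the four ethogram categories (aggression-, social-,
sleep-related, other). Events are binned by clock hour over the night
window 17:00–06:00.

**Social metrics.** Dyadic association index
DAI = D_ab / (D_a + D_b − D_ab) from co-proximity and focal times;
eigenvector centrality of the weighted DAI matrix; David's Score
DS = w + w₂ − l − l₂ from the agonistic win matrix, cut into
high/medium/low tiers by 1-D K-means; kinship as the number of direct
relatives within the group.

**Temporal patterns.** Hours above the upper quartile of the series are
labeled peaks, below the lower quartile troughs (descriptive, not a
bimodality test); hourly ACI is validated against manual counts with a
Spearman correlation (Shapiro–Wilk normality gate reported); a Poisson
GAM smooth over the wrapped hour axis tests for a non-linear
hour-of-night effect.

**Inference.** A Poisson GLMM (log link, random intercept per
individual) models per-individual vocal counts on rank (David's Score),
sex, age, centrality and relatives, with a VIF collinearity screen. A
Gaussian GAM models hourly ACI on eight weather covariates (thin-plate
smooths; cyclic smooth for wind direction) with candidate tensor-product
interactions temperature×humidity and temperature×precipitation: the
lowest-AIC candidate is reduced by backward removal of non-significant
smooths. A Friedman test compares behavior-category counts across night
hours. The mixed/additive fits run on lme4 and mgcv through R, the same
engines a field ecologist would use directly.

**Synthetic data.** Every input can be generated from known ground
truth: night soundscapes with pulsed harmonic-stack calls following a
planted bimodal hourly profile over wind-dependent noise, behavior logs
whose category mix shifts across the night, proximity/agonistic/pedigree
records with a planted hierarchy and kin clusters, attributes and counts
drawn from the forward count model, and AR(1) hourly weather with
planted weather→ACI coupling. Same seed, same bytes.

## Worked example

```
python examples/01_simulate_and_analyze_night.py
```

```
175 calls -> 170 vocal events

 hour  count      aci count_label aci_label
   17      5 120631.9      normal    trough
   18     28 121114.5        peak      peak
   19     24 120849.5        peak      peak
   20     17 120700.5      normal    normal
   21     20 120644.4      normal    normal
   22     28 120831.8        peak      peak
   23     15 120633.1      normal    normal
    0      7 120713.0      normal    normal
    1      5 120698.2      normal    normal
    2      4 120607.2      trough    trough
    3      6 120784.6      normal    normal
    4      4 120589.1      trough    trough
    5      7 120778.8      normal    normal

count peaks at hours [18, 19, 22] (quartile rule, descriptive)
Spearman(count, ACI): rho = 0.754, p = 0.0029
```

The simulated night plants elevated call rates at 18:00–19:00 and
21:00–23:00; the quartile rule recovers peaks in both windows, and the
hourly ACI tracks the manual counts (ρ = 0.75), which is what justifies
using the index as an activity proxy. The other examples cover ACI from
a WAV file (`02`), the social metrics (`03`), the count GLMM (`04`), the
weather GAM with stepwise selection (`05`), and behavioral contexts with
the Friedman test (`06`); each prints the numbers it computes and one
line on what they mean. A thin CLI wraps the same stages
(`nocturne simulate|aci|events|social|patterns|model`).

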