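# Methods

## Model overview

`prostasim` is an individual-level discrete-event model of prostate cancer
natural history and PSA-based early detection. Each simulated man is healthy
at age 35 and may experience, in continuous age-time: latent cancer onset,
progression through localised T-stages (T1–T2 → T3–T4) to metastatic
disease, clinical presentation, screen detection via PSA testing and biopsy,
treatment assignment, prostate-cancer death and death from other causes.

### Onset and grade

Onset has hazard λ_o(t) = γ_o (t − 35), i.e. a Weibull time-to-event with
shape 2 and cumulative risk R_o(t) = 1 − exp(−γ_o/2 · (t − 35)²). With the
packaged γ_o = 1.0·10⁻³ the median latent onset age is ≈ 72 and roughly
46% of men develop latent disease by 70 — deliberately high, as latent
onset includes small foci that autopsy series detect but that rarely
surface clinically. A Gleason band (≤6, 7, ≥8) is assigned at onset from a
multinomial logistic model in onset age with fixed intercepts α₇ = log 0.2
and α₈ = log 0.002 (not identifiable from the calibration targets) and
calibrated slopes β₇, β₈. Grade never changes after onset.

### PSA growth

Log PSA is piecewise linear in age: intercept b₀ ~ N(μ₀, σ₀²), pre-onset
slope b₁ ~ TN(μ₁, σ₁²) and a Gleason-specific post-onset slope increment
~ TN(μ_k, σ₂²), both zero-truncated so median PSA never decreases.
Measured PSA multiplies the median by exp(ε), ε ~ N(0, φ²), drawn
independently per test; the noise-free median drives all hazards.

### Progression and clinical presentation

Every post-onset transition hazard is proportional to median PSA,
λ(t) = γ·ỹ(t): γ_t for T1–T2 → T3–T4, γ_m for T3–T4 → metastasis,
γ_lc (pooled over Gleason ≤6 and 7, separate field for ≥8) for clinical
presentation from the localised states and γ_mc after metastasis. Because
log ỹ is linear on the post-onset segment, cumulative hazards are available
in closed form and event times are drawn by exact inverse transform
(`Λ(s,t) = γ/b·(y(t) − y(s))`, solved with `log1p` for numerical safety);
the slope→0 limit reduces to a constant-hazard exponential. A thinning
sampler exists in the test suite as an independent oracle. Competing risks
are resolved by sampling each marginal hazard on the same age clock and
taking the minimum; clinical presentation is sampled through the piecewise
(γ_lc, γ_mc) cumulative hazard along the progression trajectory, so the
latent history always carries a (possibly counterfactual) clinical
diagnosis age a_c.

### Testing, detection, treatment

First PSA test uptake is a log-logistic cure model — age-based for cohorts
born ≥1960, calendar-based (anchored 1995) for cohorts born <1932, a
cohort-weighted mixture between (the printed mixture weight (1960−c)/28 is
used as stated; a `cohort_mixture_reversed` switch exposes the
complementary reading). Re-testing is a Weibull cure model stratified by
5-year age group and PSA band at the previous test. A measured PSA ≥ 3
ng/mL refers the man to biopsy; compliance comes from an age × PSA table
(flat 0.856 in the trial emulation). Biopsy sensitivity is 0 until a
fraction φ_lag of the T1–T2 sojourn has elapsed and 1 afterwards
(detectability never reverts; after T3–T4 it is always 1). A negative
biopsy simply returns the man to the re-testing stream — no deferral rule.
Clinical-presentation hazards stay active during the φ_lag window (the lag
affects biopsy sensitivity only). Treatment (AS/RP/RT/ADT) is a multinomial
draw from an age × Gleason table at the detection age.

### Survival and the stage shift

Prostate-cancer survival runs from the clinical diagnosis age a_c — never
from the screen-detection age — with stage, PSA band, age band and
treatment frozen at the detection age (a_s for screen detection, a_c
otherwise). Screening therefore helps only through the earlier frozen
stratum and treatment (stage shift); lead time itself confers no benefit.
Curative treatment (RP or RT; ADT is grouped with non-curative management)
raises the survivor function to the power 0.56. Baseline curves are
cure-mixture Weibulls S(t) = c + (1 − c)·exp(−(t/b)^k) per stratum
(metastatic status × Gleason × PSA <10/≥10 × 10-year age group), and
per-stratum calibration hazard ratios apply as further powers. A
screen-detected man whose a_c exceeds his other-cause death age can never
die of his cancer — the overdiagnosis pathway. Other-cause death is drawn
from a Gompertz life table (annual q = 2.3·10⁻⁵·e^{0.095·age} with a mild
cohort improvement, closing at 105).

## Calibration

Step 1 estimates θ = (β₇, β₈, γ_t, γ_m, φ_lag) by minimising
−l₁ + w₂l₂ + w₃l₃ (w₂ = 1, w₃ = 10⁴), where l₁ is the multinomial
log-likelihood of the age × staging distribution of incident cancers (seven
classes: six loco-regional Gleason × T-stage combinations plus metastatic;
empty simulated cells get the half-cell floor 0.5/m), l₂ the squared
deviation of the mean onset-to-metastasis time from 25.9 years (computed
with clinical diagnosis disabled, uncensored), and l₃ the squared log
deviation of the emulated trial incidence rate ratio from 1.57. Each
evaluation reruns three simulations with seeds derived only from the
calibration seed, so the objective is deterministic in (θ, seed) — the
common-random-number property Nelder-Mead needs. The search runs on
transformed coordinates (log hazards, logit φ_lag) with a wide initial
simplex (±25% per parameter) because simulation noise can trap a small
simplex. Standard errors come from a central finite-difference Hessian
with a relative step of 0.01 per parameter (an absolute step would exceed
γ_t itself). α₇ and α₈ are fixed, never estimated.

Step 2 holds θ fixed and matches simulated Kaplan-Meier 10/15-year
survival per stratum to observed points via
log HR = ½·log(log S_obs(10)/log S_sim(10)) + ½·log(log S_obs(15)/log S_sim(15)),
applied as a power to the simulated curves; a stratum with a single
available horizon falls back to the single-horizon HR with a warning.

## Trial emulation and predictions

The two-arm screening-trial emulation uses a flat population with entry
ages uniform on 55–69, eligibility requiring the man to be alive and
undiagnosed at entry, 13 years of follow-up, an unscreened control arm and
4-yearly PSA tests from entry while aged ≤ 69 in the screening arm
(threshold 3 ng/mL, flat compliance 0.856). Arms are paired person by
person: latent histories, other-cause deaths and treatment/survival
uniforms are shared, so arm contrasts are driven by screening alone.
Incidence and mortality rate ratios are maximum-likelihood Poisson rate
ratios over one-year attained-age strata, computed by profile likelihood
(closed-form stratum rates, bisection on the log rate ratio); incidence
uses diagnosis-free person-time, mortality uses all person-time.

Policy predictions simulate a closed multi-cohort population (integer birth
cohorts uniform on 1935–1980 by default) over calendar years 2015–2034.
Organised testing (2- or 8-yearly, ages 55–69, from 2015, cohorts ≥1960)
replaces opportunistic testing inside the rollout window and only reaches
men who would test under the current pattern; cessation stops asymptomatic
testing in 2015. Outcomes aggregate into (age × year × batch) cells;
Monte-Carlo intervals are 2.5/97.5 percentiles over 50 person-batches.
Overdiagnosis is flagged when a screen-detected cancer's counterfactual
clinical diagnosis age exceeds the other-cause death age.
Age-standardised rates use a configurable standard population (weights
summing to 1).

## Packaged parameterisation and synthetic inputs

The calibrated vector ships at β₇ = 0.064, β₈ = 0.19, γ_t = 9.7·10⁻⁴,
γ_m = 1.5·10⁻³, φ_lag = 0.53. The longitudinal PSA constants
μ₀ = −1.609, σ₀ = 0.2384, μ₁ = 0.04463, σ₁ = 0.0430, μ₄ = 0.5628 are
transcribed external estimates. The remaining natural-history constants
are not published; they were fixed once so that the packaged registry is
internally consistent with its own calibration constraints at the
calibrated θ — the mean onset-to-metastasis time (25.9 years) and the
trial incidence rate ratio (1.57): γ_o = 1.0·10⁻³, the Gleason ≤6/7 split
of the pooled post-onset slope μ₂ = 0.066 / μ₃ = 0.150, σ₂ = 0.0597,
φ = 0.3, γ_lc = 8.9·10⁻⁴ (both localised bands) and γ_mc = 0.05. Every
registry value carries a provenance tag recording which of these classes
it belongs to.

All tables (life table, biopsy compliance, treatment assignment,
re-testing, survival baselines) are synthetic stand-ins generated by the
fixtures module: realistic in shape and ordering (compliance falls with
age and rises with PSA; high-grade and metastatic survival is worst;
re-test gaps shorten with higher PSA) but not estimated from person-level
records. The survival baselines in particular are parametric cure-mixture
Weibulls whose scale was chosen to give plausible cancer-specific survival
and to reproduce the reference mortality rate ratio (≈0.78) of the trial
emulation through the stage-shift mechanism. Consequently, passing tests
demonstrate the internal consistency of the machinery — calibration
closure, stage-shift behaviour, estimator correctness — not agreement with
any real population's absolute incidence or mortality rates.

## Numerical choices and problem sizes

Event times are exact inverse transforms; truncated normals use the
inverse-CDF method (`ndtri`), robust for the mild truncations used here.
Band lookups treat the last band as open-ended; values below the first
edge raise. The trial emulation clips the stratum-lookup age at the life
table's closing age. Simulation sizes are chosen for desk use: 5·10⁵ men
per arm for incidence contrasts (Monte-Carlo SE of the rate ratio ≈ 0.02),
10⁶ per arm for mortality contrasts, 10⁵ histories for sojourn means, and
a two-stage calibration recovery (coarse search at ~3–4·10⁴ per objective
simulation, polish at ~1.6·10⁵) that recovers all five parameters within
20%. Larger runs improve precision but change nothing structurally.

## Known limitations

- The synthetic uptake surface and compliance/treatment tables mean
  absolute incidence and mortality rates are illustrative; only relative
  contrasts under controlled conditions are meaningful.
- Tumour volume is not modelled; biopsy detectability is the φ_lag
  time-fraction surrogate.
- Gleason misclassification at biopsy, MRI-era diagnostics and
  negative-biopsy deferral rules are out of scope.
- The calibration's staging age-grouping (5-year groups, ages 50–74) and
  the treatment-switch rule for men progressing on active surveillance
  (re-assignment at clinical presentation) are configurable design choices
  where no single canonical rule exists.
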