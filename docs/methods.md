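# Methods

## Data model

Four tables drive everything: tag deployments (one row per shark:
transmitter type V9/V16 with 365/540-day battery, attachment, tagging date
and coordinates, sex, length, maturity), receiver stations (coordinates,
one of three habitat classes, possibly several operational intervals
separated by refurbishment gaps), a raw detection log (timestamp, receiver,
transmitter), and BRUV deployments (site, reserve flag, presence, Nmax,
Nmax-A, environmental covariates).  Timestamps are interpreted on a single
logger-local clock with no DST arithmetic; a "day" is a calendar date on
that clock.  Ingest validates invariants row by row (battery consistent
with tag type, non-overlapping receiver intervals, presence = 1 iff
Nmax ≥ 1, Nmax-A ≥ Nmax) and never silently drops or coerces: bad rows are
reported with row and column, duplicate detections are collapsed with a
count, unresolvable ids are quarantined.

Distances are great-circle (haversine) with R = 6371.0088 km.  The original
study measured map distances in a GIS; at atoll scale (≤ 40 km) the
difference is far below 1%, and haversine is reproducible without GIS
software.  Whether lagoon paths should be routed around land is unknowable
from the published record; we use straight great-circle throughout.

## Detection-string QC

Only strings of ≥ 2 consecutive detections of one transmitter at one
receiver are trusted.  "Consecutive" is not defined in the published
record; we use a 720 s gap threshold — twice the 360 s maximum nominal
pulse delay, so a single missed pulse does not split a string.  Singletons
are discarded and counted.  The collision screen examines only
receiver-time windows where ≥ 3 transmitters overlap (padded by half a
600 s simultaneity window) and flags strings whose largest internal gap
exceeds 2 × 360 s; both constants are package choices since only the
criterion's logic, not its numbers, is documented.  On default synthetic
data the report is empty, matching the published outcome.

## Fidelity metrics

RI = eligible detected days / eligible days, where a day is eligible when
the battery window (tag date .. tag date + battery days, closed) covers it
and at least one receiver interval is active.  Detections after nominal
battery expiry are *retained* in the daily-presence structure with an
`eligible=False` flag: they never enter RI, but monitoring duration (days
from tagging to the last detected date) deliberately includes them, because
transmitters often outlive their rating.  A shark with zero eligible days
raises an undefined-metric error rather than returning 0.  MLD is the
maximum pairwise receiver distance over stations with ≥ 1 detection and is
0 for a single-station shark (the published minimum of 1.25 km suggests
every real shark hit ≥ 2 stations; the 0 case is synthetic-only).  Group
summaries cover detected sharks only, grouped by transmitter type.
Monthly occurrence counts detected days per calendar month, binned
none / 1–7 / 8–14 / >14.

## Delta-lognormal detection model

One row per shark × receiver pair, keeping pairs whose receiver was
operational at least one day while the tag was active.  `days` is that
operational overlap in days; `ldist` = ln(distance from tagging point to
receiver), floored at 0.05 km before logging so a shark tagged on top of a
receiver has a defined value; `frac_days` = detected days / `days`, defined
only when detected.  Habitat enters as a treatment-coded factor with ocean
reef as the reference level; shark type is the 2 × 2 life stage × sex
factor.  Maturity is an input column; a helper can assign it from length
cut-offs (165 cm for males, 200 cm for females, chosen to reproduce the
published 6 mature males and 2 mature females) because the study judged
maturity from claspers and size without printing thresholds.

The binomial stage is a logit GLM (statsmodels IRLS) with a sequential
(type-I) analysis of deviance in declared term order — term deviances plus
the final residual always reconstitute the null deviance, and "percent
deviance" is each term's share of the null.  χ² p-values for binomial
terms, F for gaussian, matching how such tables are conventionally printed.
Quasi-separation (coefficients drifting past ±30 on the logit scale) is
caught and stabilized with a 1e-6 ridge, flagged on the fit.  Rank
deficiency raises an error naming the aliased columns.

Random effects (shark and receiver intercepts, `ldist` random slopes by
either) are *crossed*, so the mixed model uses a Laplace route implemented
in-package: for candidate log-SDs, the joint penalized log-likelihood over
(fixed effects, spherical random effects) is maximized by damped Newton
iterations, the marginal likelihood is approximated at the mode
(log f − ½‖v‖² − ½ log|Z̃ᵀWZ̃ + I|), and a Nelder-Mead search runs over the
variance parameters.  Gaussian responses profile the residual SD through
the same path, where the approximation is exact — the gaussian fit matches
statsmodels MixedLM (ML) to numerical precision in the tests, and forcing a
variance to zero reproduces the fixed-effects GLM to 1e-6.  AIC/BIC count
fixed effects plus variance parameters and are comparable within a
candidate set; published mixed-model AIC/BIC values are not reproduction
targets because the raw data are unavailable and mixed-likelihood
conventions differ across implementations.

Model selection applies a three-clause rule per candidate term in declared
order: include if (significant at α = 0.05 AND explaining > 2% of the null
deviance) OR improving AIC OR improving BIC, with the admitting clause
recorded per term.  The 2% clause is read against null deviance,
consistent with printed percent-deviance columns.

The combined prediction is E[fraction] = π̂ · exp(μ̂ + σ̂²/2) with the
standard lognormal bias correction (the delta-lognormal tradition; a flag
disables it for sensitivity analysis since the original choice is not
recorded), clipped into [0, 1] with a logged clip count.  Presence is
predicted by rounding π̂ at 0.5 with ties going to present.

## Monthly retention model

Month *i* for a shark is days [30(i−1), 30i) after its tagging date —
block months keep "month 3" comparable across sharks tagged in different
seasons (calendar alignment is available behind a flag).  Only months 1–12
enter so both battery lives are comparable; externally tagged sharks are
excluded (tethered tags shed on their own schedule); months with the whole
array down are dropped, not scored absent.  The logistic fit is
`detected ~ sharkmonth + taglife`; the retention curve is the inverse-logit
of the linear predictor on months 1–12 per tag life with a ±2 SE
delta-method band, which by construction stays in (0, 1) and contains the
point estimate.

## BRUV analysis

The reserve GLM is logistic presence on the reserve factor plus location
nested within reserve status (within each stratum the alphabetically first
site is baseline, giving the conventional two-df nested term); a stratum
with a single site drops the nested term with a warning.

The area-proportional bootstrap resamples deployments **with replacement**
within site at sizes TU 50 / SWC 30 / GRMR 25 / CCMR 25, refits
presence ~ reserve, and records the likelihood-ratio χ²₁ p-value of the
reserve term against the null; reported is the fraction of replicates with
p < 0.05.  With a single binary factor the logistic MLEs are the group
proportions, so the per-replicate test is computed in closed form from the
2 × 2 counts — the tests verify it equals the statsmodels GLM deviance test
to 1e-10.  Plain without-replacement subsampling is available
(`replace=False`); it produces a noticeably higher significant fraction
because full-strength subsamples carry less resampling variance.  The
per-replicate model omits the nested location term by default since
resampling can empty a location's cells.

Environmental comparisons are one-way ANOVA by site plus Tukey HSD
(statsmodels), on deployments with the covariate observed; missing
covariates are flagged at ingest, never imputed.  The reserve-subset
environmental GLM uses the two reserve sites with complete covariates and
fits location, flow, start temperature and all pairwise interactions
sequentially.

## Synthetic-data generator

The telemetry generator emulates the study design: 21 receivers (15 on a
30 × 10 km ellipse at reef depth, 3 deep- and 3 shallow-lagoon interior),
a 1460-day window, sharks tagged near a random receiver (home centre =
tagging point, which the study's own capture pattern supports), V9 under
110 cm and V16 otherwise, lengths N(134, 39²) clipped to the observed
66–214 cm.  Ever-detection per pair is Bernoulli with logit
β₀ + β_ldist·ldist + habitat + shark effect, defaults β₀ = 1.5,
β_ldist = −1.2, habitat offsets (0, −0.5, −1.0), shark SD 1.0; the day
fraction given detection is lognormal with μ = ln 0.08 − 0.7·ldist and
σ = 0.6, clipped to ≤ 1 with clip events logged.  These defaults were set
once to reproduce the qualitative published structure — roughly a quarter
to a third of pairs detected, log distance carrying the dominant deviance
share, and combined expected fractions below 10% beyond 1 km from the
tagging site — and are not tuned thereafter.  Detected days are scattered
uniformly over the eligible window and realized as pulse trains of 2–8
whole-second pulses with U(180, 360) s delays, so the string filter sees
realistic input and retains every train.

What the generator does *not* emulate: temporal emigration or behavioral
seasonality (detected days are exchangeable within the window, so monthly
retention saturates near 1 where real sharks showed 70–80% at month 12),
receiver range variation with sea state, tag loss, and spatial
autocorrelation between neighboring receivers beyond the shared distance
trend.  Passing recovery tests therefore demonstrate that the estimation
machinery is unbiased and calibrated under the assumed model, not that the
model captures every feature of field data.

The BRUV generator draws per-site Bernoulli presence at the observed rates
(0.32, 0.26, 0.12, 0.04), Nmax = 2 with probability 0.375 given presence
(6 of 16 reserve detections saw two sharks), Nmax-A ≥ Nmax by construction,
and gaussian covariates with SWC shifted warmer (+1.8 °C) and more
oxygenated (+1.2 mg/L), mirroring the published environmental contrast.

## Numerical choices and problem sizes

GLM fitting is statsmodels IRLS; mixed models use the in-package Laplace
path (inner Newton tolerance 1e-9, outer Nelder-Mead xatol 1e-5).  All
simulation randomness flows through one seeded `numpy.random.Generator`;
same seed, byte-identical CSVs.  AIC ties resolve to the first-declared
candidate.  The recovery harness runs the full pipeline
(simulate → strings → daily presence → pair summary → fit) per replicate;
the shipped driver uses 15 sharks × 400 days × 60 replicates and the test
suite 200 replicates with the shark SD at zero to isolate the marginal
fixed-effects pathway (the shark-level variance is recovered separately in
a 50-replicate mixed-model test at 30 × 20).  Published group means are
compared at one unit in the last published digit because the packaged
per-shark metrics are themselves rounded to that precision.

## Known limitations

- The published mixed-model information criteria and the reserve GLM's
  deviance on its (unprintable) 120-deployment subset are not reproducible
  without the raw data and are deliberately out of scope.
- The RI-on-length regression from the packaged table gives r² = 0.010;
  the published 0.02 evidently reflects unrounded RI values that the table
  does not carry.
- The Laplace approximation can understate variance components for very
  sparse binary groups; the gaussian path is exact and the binomial path is
  validated by simulation, not against a closed form.
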