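# reeftrace

Do reef sharks stay put, and do marine reserves hold more of them?
`reeftrace` implements a two-part analysis of Caribbean reef shark
(*Carcharhinus perezi*) ecology on the Belizean barrier reef:

1. **Site-fidelity from passive acoustic telemetry.** Sharks carrying coded
   transmitters are logged by an atoll-scale array of moored receivers.
   Raw pings are filtered into *detection strings* (runs of ≥ 2 consecutive
   detections, screening out signal collisions and noise), collapsed to
   daily presence, and summarized per shark as
   - **RI** (residency index) = detected days / days the shark *could* be
     detected (battery alive, receivers in the water), in [0, 1];
   - **MLD** (minimum linear dispersal) = distance between the two furthest
     receivers with a detection;
   - monitoring duration, monthly occurrence, and OLS regressions of RI and
     MLD on body length.

   Fine-scale fidelity is modeled **delta-lognormally** per shark × receiver
   pair: a logit-link binomial model for *ever detected*
   (terms: receiver effort `days`, log distance from the tagging site
   `ldist`, habitat, shark type; shark/receiver random intercepts and
   `ldist` random slopes via a Laplace-approximate GLMM) times a lognormal
   model of the *fraction of days detected given any*, so that
   E[fraction] = π̂ · exp(μ̂ + σ̂²/2).  A month-scale logistic GLM
   (`detected ~ sharkmonth + taglife`) tracks retention over the first year.

2. **Relative abundance from baited remote underwater video (BRUV).**
   200 deployments across two reserve and two fished reefs, scored for shark
   presence and Nmax / Nmax-A counts.  A logistic GLM tests the reserve
   factor with location nested in reserve status; because the fished sites
   cover more reef area, an **area-proportional bootstrap** (2000 replicates
   resampled per site at TU 50 / SWC 30 / GRMR 25 / CCMR 25, reserve term
   re-tested by likelihood-ratio χ² at α = 0.05) checks that unequal sample
   density does not drive the result.  One-way ANOVA + Tukey HSD compare
   environmental covariates between sites.

The raw detection logs are not public, so the package ships (a) the
published 33-shark monitoring table as a fixture and (b) a seeded
synthetic-data generator (`reeftrace.simulate`) that reproduces the
statistical structure of both survey types — home-centred sharks whose
detection decays with log distance, lognormal day fractions, 180–360 s
pulse trains, battery expiry, and per-site BRUV presence with environmental
covariates — so every stage is testable end to end and parameter recovery
is checkable.

## Worked example

```python
import reeftrace as rt

metrics, tags = rt.fidelity.glover_metrics()          # packaged 33-shark table
summ = rt.fidelity.summarize_fidelity(metrics, tags).set_index(["group", "metric"])
print(round(summ.loc[("all", "ri"), "mean"], 2))      # 0.44
print(round(summ.loc[("V9", "mld_km"), "mean"], 1))   # 9.4
r = rt.fidelity.size_regression(metrics, tags, "mld_km")
print(round(r.r_squared, 2))                          # 0.04
```

The average tagged shark was detected inside the array on roughly 4 of
every 10 days it could have been (mean RI 0.44 from the table's 2-dp
values), small-tag sharks ranged over ~9.4 km of reef, and body length
explains essentially none of the variation (r² = 0.04 for MLD, 0.01 for
RI) — fidelity is high across life stages.

```python
from reeftrace.bruv import (OBSERVED_SITE_COUNTS, AREA_PROPORTIONAL_N,
                            deployments_from_counts, bootstrap_density)
dep = deployments_from_counts(OBSERVED_SITE_COUNTS)   # 29/100 reserve, 8/100 fished
boot = bootstrap_density(dep, AREA_PROPORTIONAL_N, n_reps=2000, seed=17)
print(f"{boot.fraction_significant:.0%}")             # 83%
```

Even after shrinking each site's sample in proportion to its area, the
reserve factor stays significant in ~83% of 2000 resampled surveys: the
reserve/fished contrast is not an artifact of unequal sampling density.

The numbered drivers under `analysis/` run the full pipelines (synthetic
telemetry workspace → string filtering → fidelity metrics → delta-lognormal
and monthly models → BRUV analysis → parameter recovery) and write their
tables under `results/`.

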