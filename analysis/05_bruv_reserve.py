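"""Reserve effect on reef-shark presence from 200 BRUV deployments.

Part 1 works from the published per-site tallies (two reserve sites at
32%/26% presence, two fished sites at 12%/4%): site summaries, the logistic
reserve + nested-location GLM, and the area-proportional bootstrap that
equalizes sample density across sites of unequal area.

Part 2 uses a synthetic survey with environmental covariates to exercise the
environmental comparisons (ANOVA/Tukey) and the reserve-subset environmental
GLM.  Outputs under results/bruv/.
"""

from pathlib import Path

import pandas as pd

import reeftrace as rt
from reeftrace.bruv import (
    AREA_PROPORTIONAL_N, OBSERVED_SITE_COUNTS, bootstrap_density,
    compare_environments, deployments_from_counts, fit_env_glm_reserve_subset,
    fit_reserve_glm, summarize_sites,
)

SEED = 17
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "bruv"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # --- observed tallies ------------------------------------------------
    dep = deployments_from_counts(OBSERVED_SITE_COUNTS)
    summ = summarize_sites(dep)
    summ.to_csv(OUT / "site_summary.csv", index=False)
    by = summ.set_index("site")
    print(f"presence: reserve {by.loc['reserve', 'n_present']:.0f}/100, "
          f"fished {by.loc['fished', 'n_present']:.0f}/100")

    fit = fit_reserve_glm(dep)
    fit.deviance_table.to_csv(OUT / "reserve_glm_deviance.csv", index=False)
    tab = fit.deviance_table.set_index("term")
    print(f"reserve term: deviance {tab.loc['reserve', 'deviance']:.2f}, "
          f"p = {tab.loc['reserve', 'p']:.4f}; nested location p = "
          f"{tab.loc['location_nested', 'p']:.2f} (no within-stratum difference)")

    boot = bootstrap_density(dep, AREA_PROPORTIONAL_N, n_reps=2000, seed=SEED)
    pd.DataFrame([{
        "n_reps": boot.n_reps, "alpha": boot.alpha, "seed": boot.seed,
        "replace": boot.replace, **{f"n_{k}": v for k, v in boot.site_n.items()},
        "fraction_significant": boot.fraction_significant,
    }]).to_csv(OUT / "bootstrap_result.csv", index=False)
    print(f"area-proportional bootstrap ({boot.n_reps} reps, per-site n "
          f"{boot.site_n}): reserve significant in "
          f"{boot.fraction_significant:.0%} of replicates")

    # --- synthetic survey with environmental covariates -------------------
    cfg = rt.simulate.BruvSimConfig()
    syn = rt.simulate.simulate_bruv(cfg, seed=SEED)
    env_rows = []
    for var in ("flow_velocity", "salinity", "depth_m", "visibility_m",
                "temp_start", "dissolved_oxygen"):
        anova, tukey = compare_environments(syn, var)
        env_rows.append(anova.iloc[0])
        tukey.to_csv(OUT / f"tukey_{var}.csv", index=False)
    env = pd.DataFrame(env_rows)
    env.to_csv(OUT / "environment_anova.csv", index=False)
    hot = env[env["p"] < 0.001]["variable"].tolist()
    print(f"environmental ANOVA on the synthetic survey: strong site "
          f"differences only for {hot} (SWC runs warmer / more oxygenated "
          f"by construction)")

    envfit = fit_env_glm_reserve_subset(syn)
    envfit.deviance_table.to_csv(OUT / "reserve_subset_env_glm.csv", index=False)
    worst = envfit.deviance_table.sort_values("p").iloc[0]
    print(f"reserve-subset environmental GLM: smallest p = {worst['p']:.2f} "
          f"({worst['term']}) -- no covariate rivals the reserve factor")


if __name__ == "__main__":
    main()
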