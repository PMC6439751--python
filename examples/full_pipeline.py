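"""End-to-end run: synthetic registry -> cohort -> matched case-control
-> heritability.

Generates a registry of 20 000 adoptive families (h2 = 0.32, c2 = 0,
2% liability prevalence), applies the exclusion rules, classifies
parental exposures, matches each case adoptee to 4 controls on sex,
education, county and birth year +/-1, fits conditional logistic odds
ratios, and converts the biological-parent OR to heritability.
"""

from adoptherit import RunConfig, SimulationConfig, run_pipeline

cfg = RunConfig(
    simulation=SimulationConfig(
        n_adoptees=20_000, h2=0.32, c2=0.0, prevalence=0.02, seed=1
    ),
    seed=1,
)
tables = run_pipeline(cfg)

print("Prevalence by role:")
print(tables["table1"].to_string(index=False))

print("\nConditional logistic odds ratios (1:4 matched):")
cols = ["exposure", "odds_ratio", "ci_low", "ci_high", "n_sets",
        "n_unmatched_cases"]
print(tables["case_control"][cols].round(2).to_string(index=False))

print("\nHeritability estimates:")
print(tables["heritability"].round(3).to_string(index=False))

print(
    "\nThe biological-parent OR exceeds 1 while the adoptive-parent CI"
    "\nstraddles 1, and both estimators land near the simulated h2 of"
    "\n0.32 (sampling noise at this cohort size is substantial; the"
    "\nregistry censoring also attenuates the observed association)."
)
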