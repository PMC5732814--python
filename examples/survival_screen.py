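"""Spearman screen of features against survival on a synthetic cohort.

Simulates a 277-patient phantom cohort in which tumor texture
heterogeneity raises the hazard of death in the LCC subgroup only, imputes
censored survival times, and screens every (subtype, feature) cell with
Holm-Bonferroni correction over the 4 x 25 = 100-test family.
"""

from radsurv import SimulationConfig, screen_group, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_patients=277, seed=1))
print(f"{len(cohort)} patients, {1 - cohort['event'].mean():.0%} censored")

screen = screen_group(cohort, "subtype")
significant = screen[screen["significant"]]
print(f"\n{len(significant)} of {len(screen)} cells significant "
      f"(corrected P < 0.05, family m={screen['family_size'].iloc[0]}):\n")
print(significant[["group", "feature", "rho", "p_adj"]].to_string(index=False))
print(
    "\n|rho| in 0.3-0.5 is the moderate-correlation regime; the planted"
    "\ntexture-hazard coupling is confined to LCC, and only LCC cells"
    "\nshould appear above (negative rho: finer texture, shorter survival)."
)
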