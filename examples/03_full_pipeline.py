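"""Run the complete pipeline on a simulated cohort and fit the headline
models.

A 10-infant cohort (5 per age group) is simulated, preprocessed, screened
with the five rejection criteria and the 70% participant-inclusion rule,
and the three headline mixed models are fitted: volume -> pupil dilation,
age -> first-look latency, and age -> face selection (logistic).
"""

from popgaze import SimulationParams
from popgaze.pipeline import analyze_simulated_cohort, recover_effects

params = SimulationParams(n_infants_per_age=5)
table, summary = analyze_simulated_cohort(params, seed=11)

print("rejections per criterion:")
for k, v in summary.items():
    print(f"  {k}: {v}")
print(f"\nanalysis table: {len(table)} valid trials, "
      f"{table['infant_id'].nunique()} infants")

effects = recover_effects(table)
print("\nestimated effects (injected truths: 0.02 mm, -0.09 s, 0.94 log-odds):")
for name, value in effects.items():
    print(f"  {name}: {value:+.4f}")
# With only 10 infants the estimates are noisy; the acceptance script
# averages 25+ replicates of the full 46-infant design.
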