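"""Intraindividual variability of daily MET sums, compared across sex.

Per participant we compute the SD, CV, PV and CDI of daily 24-hour MET
sums, then compare the CDI distribution between female and male
participants with the Kruskal-Wallis protocol and report the modified
Cohen d effect size when significant.
"""

from actvar import CohortSpec, generate_cohort
from actvar.inference import compare_groups
from actvar.metrics import variability_profile
from actvar.summaries import summarize_cohort

spec = CohortSpec(n_participants=60, days=120, seed=2, missingness=[])
series, metadata, _ = generate_cohort(spec)

profile = variability_profile(summarize_cohort(series))
cdi24 = (profile[profile["state"] == "24h"]
         .merge(metadata, on="participant_id"))
print(cdi24.groupby("sex")[["mean", "sd", "cv", "pv", "cdi"]]
      .median().round(4).to_string())
print()

result = compare_groups(cdi24["cdi"], cdi24["sex"], n_comparisons=3)
print(f"Kruskal-Wallis H = {result.h:.2f}, p = {result.p:.4f} "
      f"(threshold {result.alpha_corrected:.4f})")
if result.significant:
    (pair, es), = result.effect_sizes.items()
    print(f"significant; larger median: {result.larger_median[pair]}, "
          f"Cohen d_m = {es.d_m:.2f}")
else:
    print("not significant at the Bonferroni-corrected threshold")

# The generator's male dispersion targets sit above the female ones, so the
# CDI of daily sums separates the sexes while the mean daily sums do not.
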