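"""Fit the factor-term GAM predicting per-participant CDI.

G(E(CDI)) = beta0 + f_sex(sex) + f_WR(weekend rhythm) + f_age(age bin),
identity link, sum-to-zero coded factors (equivalent to least squares).
Model selection compares main effects against models with 2- and 3-way
interactions and drops factors whose terms are indistinguishable from 0.
"""

from actvar import CohortSpec, generate_cohort
from actvar.gam import feature_importance, select_model
from actvar.imputation import fill_series
from actvar.metrics import variability_profile
from actvar.pipeline import build_gam_table
from actvar.rhythms import assign_weekend_rhythm
from actvar.summaries import summarize_cohort

spec = CohortSpec(n_participants=150, days=140, seed=3)
series, metadata, _ = generate_cohort(spec)
daily = summarize_cohort([fill_series(s) for s in series])
profile = variability_profile(daily)
labels = assign_weekend_rhythm(daily, k=5)
table = build_gam_table(profile, labels, metadata)

selection = select_model(table)
print("pseudo-R2 by interaction order:",
      {k: round(v, 1) for k, v in selection.pseudo_r2_by_order.items()})
print("factors dropped as null:", selection.dropped or "none")

fit = selection.final_fit
print(f"final model explains {fit.pseudo_r2:.1f}% of the null deviance")
for factor, effects in fit.effects.items():
    pretty = {k: round(v, 4) for k, v in sorted(effects.items())}
    print(f"  f_{factor}: {pretty}")
print("feature importance (pseudo-R2 drop when left out):",
      {k: round(v, 2) for k, v in feature_importance(fit, table).items()})

print("\nthree lowest- and highest-variability phenotype cells:")
preds = fit.phenotype_predictions()
print(preds.head(3).to_string(index=False))
print(preds.tail(3).to_string(index=False))
# Each predicted value is beta0 plus the cell's factor effects: the CDI the
# model expects for a person with that sex, rhythm and age combination.
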