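"""Which variables drive the totals?  Removal influence and UOG-only scores.

Removing a variable can only lower a catchment's role total; the influence
statistic is the per-catchment percent change of S (or E), averaged per play.
"""

import catchvuln as cv
from catchvuln.influence import UOG_VARIABLES

profiles = [cv.PlayProfile(p.play_name, 200, p.variables) for p in cv.default_profiles()]
table = cv.generate_table(profiles, seed=42)
scores = cv.score_table(table)

road = cv.removal_effect(scores, "road_density")
print("Removing road density (percent drop in exposure E, mean +/- SD per play):")
for _, row in road.iterrows():
    print(f"  {row.play:<13} {row.mean_pct_change:5.1f} +/- {row.sd_pct_change:4.1f} "
          f"(n={row.n_included})")

uog = cv.removal_effect(scores, list(UOG_VARIABLES))
print("\nRemoving all four well metrics together (percent drop in E, All plays):"
      f" {uog.loc[uog.play == 'All', 'mean_pct_change'].iloc[0]:.1f}")

only = cv.uog_only_scores(scores)
print("\nUOG-only exposure (non-vertical density + proximity scores, max 8):")
print(only.groupby("play")[["E_uog", "V_uog"]].mean().round(2))
# Play-level differences show which stressors dominate each play's exposure;
# E_uog isolates the unconventional-development footprint.
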