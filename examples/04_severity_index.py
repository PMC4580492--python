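"""Play-level severity-weighted vulnerability for the flow-regime effect.

Plays are ranked 1-6 per variable, exposure ranks are weighted by the
author-averaged 1-3 severity scores and rounded half-up, and each play's
total is (sensitivity rank sum) x (weighted exposure sum).
"""

import catchvuln as cv
from catchvuln.severity import SEVERITY_WEIGHTS

print("Flow-regime totals from the shipped reference rank block:")
for play, res in cv.flow_regime_totals().items():
    print(f"  {play:<13} rank sum {res.sens_rank_sum:2d}  weighted exposure "
          f"{res.weighted_exposure_sum:2d}  total {res.total:3d}")

ranks = cv.rank_plays(cv.play_means("nonvertical_well_density"))
w = SEVERITY_WEIGHTS["flow"]["nonvertical_well_density"]
print(f"\nNon-vertical well density ranks (weight {w}):")
for play, r in sorted(ranks.items(), key=lambda kv: kv[1]):
    print(f"  {play:<13} rank {r} -> weighted cell {cv.weighted_exposure_score(r, w)}")
# The Bakken's 459 is the worked flow-regime example: rank sum 9 (4 for
# precipitation + 5 for stream density) times weighted exposure sum 51.
# Hilliard's computed 198 differs from its published total (192), which does
# not recompose from its published cells.
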