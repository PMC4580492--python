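"""Score catchments 0-4 per variable and total S, E and V = S x E.

Quartile breaks are pooled across all plays; inverted variables
(precipitation, well proximity) score the smallest values highest.
"""

import catchvuln as cv

profiles = [cv.PlayProfile(p.play_name, 200, p.variables) for p in cv.default_profiles()]
table = cv.generate_table(profiles, seed=42)
scores = cv.score_table(table)

print("Play means of total sensitivity (S, 0-28), exposure (E, 0-40) and")
print("vulnerability (V = S x E, 0-1120):")
print(scores.groupby("play")[["S", "E", "V"]].mean().round(1))

top = scores.nlargest(3, "V")[["huc12_id", "play", "S", "E", "V"]]
print("\nMost vulnerable catchments:")
print(top.to_string(index=False))

flags = cv.screen_correlations(table, threshold=0.6)
print(f"\nCollinearity screen (|Spearman rho| > 0.6): {len(flags)} pair(s) flagged")
# A high-V catchment combines naturally sensitive terrain with heavy
# anthropogenic exposure; the screen lists variable pairs a configuration
# might drop before scoring.
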