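"""Compare encoding percentages between two recorded areas.

Counts for the second area are user-supplied (they come from a separately
recorded dataset and are never recomputed here). Each (window, variable)
cell is tested with a Pearson chi-square on the 2x2 table area x
encodes/does-not-encode, df = 1, no continuity correction.
"""

from costchoice import stats

# chosen-value encoding, one window: 45 of 224 neurons vs 23 of 220
out = stats.area_comparison(45, 224, 23, 220)
print(f"area 1: {out['pct_1']:.1f}%   area 2: {out['pct_2']:.1f}%")
print(f"chi2(1) = {out['chi2']:.2f}, p = {out['p']:.4f}")
print()
print("a p below 0.05 indicates the encoding prevalence differs between areas.")
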