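"""Chao1 richness estimation on a synthetic fossil-record sample.

Builds an abundance vector with known singleton/doubleton structure,
estimates total richness with Chao1, and shows a short accumulation curve.
"""

from paleonull import accumulation_curve, chao1_estimate, make_abundances, tally_frequencies

# 23 recorded species, 10 singletons and 5 doubletons, as a generated sample
abundances = make_abundances(sobs=23, f1=10, f2=5, seed=42)
sobs, f1, f2 = tally_frequencies(abundances)
est = chao1_estimate(abundances)

print(f"observed species  S_obs = {sobs}, singletons F1 = {f1}, doubletons F2 = {f2}")
print(f"Chao1 estimate    {est.chao1:.2f}  (S_obs + F1^2 / 2 F2)")
print(f"95% interval      [{est.ci_low:.1f}, {est.ci_high:.1f}]")

curve = accumulation_curve(abundances, n_rand=200, seed=0)
for level in (10, curve.levels[-1]):
    k = list(curve.levels).index(level)
    print(f"after {level:3d} records: mean S_obs = {curve.mean_sobs[k]:5.2f}, "
          f"mean Chao1 = {curve.mean_chao1[k]:6.2f}")

# The estimate exceeds the observed count because rare species (many
# singletons) signal that more species remain unsampled; the curve shows
# how both quantities grow as fossil records accumulate.
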