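"""Bound-fraction estimate from uniform HSQC cross-peak attenuation.

Simulates 50 matched (free, fibril-mixed) cross-peak intensities with a
true bound fraction of 10% at S/N 30, estimates the bound fraction, and
checks it against an independently measured 95% soluble fraction.
"""

from fibrilbind import binding
from fibrilbind.synthetic import SyntheticConfig, gen_intensity_pairs

raw = gen_intensity_pairs(50, attenuation=0.10, snr=30.0,
                          cfg=SyntheticConfig(rng_seed=7))
pairs = [binding.IntensityPair(*r) for r in raw]
result = binding.bound_fraction(binding.intensity_ratios(pairs))

print(f"mean intensity ratio: {result.mean_ratio:.3f} +- {result.ratio_err:.3f}")
print(f"bound fraction:       {result.bound_fraction:.3f}  (truth 0.100)")
print(f"uniformity chi2/dof:  {result.uniformity_stat:.2f}")

check = binding.supernatant_consistency(result.bound_fraction, 0.95, tolerance=0.06)
print(f"consistent with {check.soluble_fraction:.0%} soluble fraction: {check.passed}")
# A uniformity statistic near 1 means every peak attenuates by the same
# factor, as expected when a rigid chaperone simply leaves solution upon
# binding rather than exchanging at specific sites.
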