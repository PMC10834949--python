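"""Solvent-PRE analysis: R1 fits, Monte-Carlo errors, condition differences.

Simulates inversion-recovery series for doped (paramagnetic CuEDTA) and
undoped samples with and without a bound chaperone.  Binding buries
residues 26-29 (lower PRE) and releases the C-terminal residue 42 (higher
PRE); the difference profile recovers those segments.  A 2-sigma cut flags
about 5% of unaffected residues by chance, so this demo uses 3 sigma.
"""

import numpy as np

from fibrilbind import relaxation
from fibrilbind.synthetic import SyntheticConfig, gen_inversion_recovery

delays = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0])
base = {i: 0.30 for i in range(1, 43)}  # 15N R1, 1/s
apo_pre = {9: 0.3, 16: 0.3, 26: 0.3, 27: 0.3, 28: 0.3, 29: 0.3, 42: 0.3}
holo_pre = {**apo_pre, 26: 0.05, 27: 0.05, 28: 0.05, 29: 0.05, 42: 0.6}


def profile(site_pre, tag, seed):
    doped_map = {i: base[i] + site_pre.get(i, 0.0) for i in base}
    fits = {}
    for kind, rmap, s in (("doped", doped_map, seed), ("undoped", base, seed + 1)):
        series = gen_inversion_recovery(
            rmap, delays, SyntheticConfig(rng_seed=s, noise_sd_relaxation=0.02)
        )
        fits[kind] = []
        for x in series:
            fit = relaxation.fit_inversion_recovery(x)
            fit.r1_err = relaxation.mc_error(x, fit, n_sim=500, seed=s + x.residue_index)
            fits[kind].append(fit)
    return relaxation.compute_pre(fits["doped"], fits["undoped"], condition=tag)


apo = profile(apo_pre, "apo", 100)
holo = profile(holo_pre, "holo", 200)
report = relaxation.delta_pre(apo, holo, k_sigma=3.0)

print(f"PRE at residue 27 (apo):  {apo.values[27][0]:.3f} +- {apo.values[27][1]:.3f} 1/s")
print(f"PRE at residue 27 (holo): {holo.values[27][0]:.3f} +- {holo.values[27][1]:.3f} 1/s")
print(f"flagged segments: {report.segments}")
# A decreased PRE means the dopant no longer reaches the site (buried under
# the bound chaperone); the increase at residue 42 signals a more
# solvent-exposed C-terminus after the K28-A42 salt bridge is disturbed.
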