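# Methods

This note records the models, estimators, numerical choices and
limitations behind each analysis stage, and what the synthetic-data
generator does and does not emulate.

## Two-phase SPR kinetics

The model assumes two independent classes of binding site on the
immobilized fibril surface. During injection each class fills with an
observed rate `k_obs = c·k_on + k_off` toward a saturating amplitude;
after the injection stops the response decays as a weighted sum of two
exponentials with weight `a ∈ [0, 1]`. The printed form of the observed
rates pairs `k_on1` with `k_off2` and `k_on2` with `k_off1`. That crossed
pairing is unusual for independent sites and may be typographical, so both
conventions are implemented (`pairing="crossed"` default,
`pairing="paired"` for `k_obs,i = c·k_on,i + k_off,i`); the test suite
exercises both and neither is asserted as the source's intent. Apparent
dissociation constants are formed by the off/on ratio within the selected
pairing (crossed: `k_off2/k_on1` and `k_off1/k_on2`), and the smaller is
reported as the strong site. Which phase index carries the strong constant
is arbitrary; results are canonicalized so phase 1 is the strong one.

### Global fit

All retained curves share `(k_on1, k_on2, k_off1, k_off2, B_max1, B_max2,
a)`; each curve keeps its own dissociation amplitude `R_0` and its
injection stop `t_0` comes from metadata, not estimation. The lowest
`exclude_lowest` (default 2) concentrations are dropped before fitting,
matching the protocol of excluding injections too weak to constrain the
model. The objective is unweighted least squares over concatenated
association and dissociation residuals (optional per-point weighting was
considered unnecessary: no noise model is stated for the source data).

Numerically the fit uses variable projection: for fixed rates and `a` the
model is linear in `(B_max1, B_max2)` (solved by non-negative least
squares over all association points) and in each `R_0` (scalar projection
with a non-negativity clamp), leaving a five-parameter nonlinear problem
in `(log10 k_on1, log10 k_on2, log10 k_off1, log10 k_off2, a)` solved with
bounded trust-region least squares. Starting points are a data-driven
heuristic (half-rise time of the highest-concentration association phase;
early/late log-slopes of its dissociation tail) plus seeded log-uniform
multistart draws (default 8) over the rate bounds (`k_on` ∈ [1e1, 1e8]
M⁻¹s⁻¹, `k_off` ∈ [1e-6, 1e1] s⁻¹). Non-convergence of every start raises;
a dubious best solution is flagged `converged=False`, never silent.

Parameter uncertainties are asymptotic: the Jacobian of the full model in
the natural parameters (rates, amplitudes, `a`, all `R_0`) is evaluated
numerically at the optimum and the covariance is `σ²(JᵀJ)⁻¹` with `σ²`
the residual variance. Replicate-spread errors would be an alternative;
the covariance route is used because single-series fits must still report
uncertainties.

## Chemical-shift-perturbation mapping

Combined shifts use `|δ_comb| = sqrt((δ_het/s)² + δ_H²)` with `s = 2`.
The scale is written for ¹³C; it is applied to ¹⁵N as well unless
overridden, a deliberate simplification (common alternatives use ~5 for
nitrogen).

Peak matching is per (residue, atom pair). "At the reference position"
means within `(radius_hetero, radius_H) = (0.2, 0.05)` ppm, configurable.
One query peak → `unique`; two query peaks with exactly one at the
reference position → `doubled`, with the shift difference taken from the
shifted twin; reference peaks lying within the radii of each other →
`overlapped` (excluded from statistics — their assignment is not
resolvable); other multi-candidate patterns → `ambiguous` (the largest
candidate shift is recorded); no query peak → `missing`.

The significance rule defaults to `δ_comb > mean + 1·SD` over assessable
(unique/doubled/ambiguous) residues, strict inequality; no cutoff is
stated for the original residue calls, so the rule is configurable
(absolute ppm or mean + k·SD) and echoed in the output. Ambiguous residues
are included in the restraint set by default, matching the coloring of
ambiguous assignments alongside confident ones; `include_ambiguous=False`
excludes them. Restraint export replicates the fibril residues over
`n_subunits` (default 3) central chains, since a fibril binding site spans
neighbouring subunits along the axis.

## Inversion recovery, Monte-Carlo errors, PRE

R1 is fitted per residue with `I(t) = offset + amplitude·exp(−r1·t)`
(3 parameters), which covers inversion recovery (`amplitude < 0`),
saturation recovery, and imperfect inversion. Initialization scans a
25-point geometric grid of `r1` spanning 0.05–50 times the inverse delay
span, solving the two linear parameters exactly at each grid point, then
polishes with Levenberg–Marquardt. Flat series are flagged
`converged=False` (or carry an error exceeding the estimate) rather than
raising. The asymptotic (covariance) error is returned by the fit;
`mc_error` resimulates the best-fit curve at the series' noise floor
(default 500 simulations, seeded) and reports the SD of refitted rates.
The two agree asymptotically; the Monte-Carlo route honours the original
error protocol and is used wherever a noise floor is supplied.

PRE is the doped-minus-undoped R1 difference with quadrature errors;
condition differences (holo − apo) are flagged when exceeding `k_sigma`
(default 2) propagated errors. Under a correct error model a 2σ two-sided
cut flags ≈ 4.6% of truly null residues; the calibration test checks this
on 1000 null residues using the covariance errors (a 500-draw Monte-Carlo
per residue would be equivalent but ~100× slower). Users scanning whole
sequences for segments should either expect that false-positive rate or
raise `k_sigma` (the examples use 3σ for clean segment pictures).

## Bound fraction

Per-peak ratio errors are first-order S/N propagation,
`err = ratio·sqrt(snr_free⁻² + snr_mixed⁻²)`. The summary is the
1/err²-weighted mean (falling back to the plain mean if any error is
zero); both the propagated error of the mean and the SD across peaks are
reported since either could stand behind a "± " on an attenuation figure.
The reduced chi-square of ratios about the mean tests uniformity of the
attenuation — the premise that signal loss reflects a population leaving
solution rather than site-specific exchange broadening (which is ignored,
as no line-width change accompanies the attenuation in the motivating
data). `bound = 1 − mean_ratio` is clamped to [0, 1].

## Morphometry

Summaries use the sample SD (n−1). Tests are the classical unpaired
two-tailed t (Student pooled-variance default, matching the common
default of graphing software; Welch–Satterthwaite available), computed
through `scipy.stats.ttest_ind_from_stats` with degrees of freedom
reported explicitly. Zero variance in both groups is handled as a
degenerate case (t = 0, p = 1 when means agree; p = 0 flagged degenerate
otherwise). The cross-section boundary of 11 nm is the midpoint of the
observed class means (8.4 vs 13.8 nm); a mean exactly on the boundary is
left unclassified.

## Synthetic data: what it emulates and what it does not

The generators produce tabular derivatives only — no spectra, lineshapes
or micrographs. Sensorgrams follow the kinetic model exactly, with the
dissociation amplitude tied to the association value at `t_0` (continuity;
how the two phases were tied in the original fits is not stated) and
additive i.i.d. Gaussian noise. Recovery series follow the
mono-exponential model with additive noise at a stated fraction of the
initial intensity. Peak tables place one deterministic cross-peak per
residue of the 42-residue Aβ42 sequence (serines at 8 and 26) and
shift/double a chosen subset; peak positions are synthetic, not database
chemical shifts. Diameters are normal draws truncated at zero (negligible
at realistic parameters).

Noise defaults are artifact choices, not measured values: 0.5% of the
maximal response for sensorgrams (typical of a well-behaved instrument),
2% of initial intensity for recovery series, and S/N 30 for intensity
pairs. A green recovery test therefore establishes estimator correctness
and calibration under the stated model, not instrument fidelity: real
data add baseline drift, mass-transport limitation, spectral overlap, and
non-Gaussian artefacts that are out of scope here.

Determinism: every generator draws from `numpy.random.default_rng` seeded
from its config, and the pipeline derives per-stage seeds from the global
seed by SHA-256 hashing, so stage-subset runs reproduce full-run results
bit for bit.

## Known limitations

- No mass-transport or bivalent-analyte SPR models; instrument binary
  formats are not parsed.
- The crossed/paired pairing ambiguity is surfaced, not resolved.
- PRE values are not converted to distances and no spectral-density
  modelling is attempted.
- The significance thresholds (CSP rule, `k_sigma`) are configurable
  conventions; the original numeric cutoffs are unknown.
- Exchange contributions to HSQC attenuation are ignored by design.
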