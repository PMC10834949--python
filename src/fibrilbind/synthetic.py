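"""Synthetic input generation with known ground truth.

Every analysis stage in this package consumes tabular inputs (sensorgrams,
peak lists, inversion-recovery series, diameter samples) that in the
original experiments come from instruments.  This module emulates all four
input kinds from an explicit generative model so each downstream fit can be
validated against a known truth:

* sensorgrams follow the two-phase kinetic model exactly (continuous at the
  injection stop) plus i.i.d. Gaussian noise;
* inversion-recovery series follow a three-parameter mono-exponential;
* peak tables place one reference cross-peak per residue and shift (or
  double) the peaks of a chosen perturbed subset;
* fibril diameters are drawn from normal populations truncated at zero.

All generators are deterministic in (config, arguments): the same seed
gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csp import AssignedPeak
from .relaxation import RelaxationSeries
from .morphometry import DiameterSample
from .sequences import AB42
from .spr import Sensorgram, TwoPhaseKineticParams, eval_sensorgram

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "gen_sensorgram_series",
    "gen_inversion_recovery",
    "gen_peak_tables",
    "gen_intensity_pairs",
    "gen_diameters",
]


@dataclass
class SyntheticConfig:
    """Noise levels and seed for all generators.

    Noise SDs: sensorgram in response units, relaxation as a fraction of
    the initial intensity, shifts in ppm.  The original study reports no
    acquisition noise figures, so these are artifact defaults, not claims.
    """

    rng_seed: int = 0
    noise_sd_sensorgram: float = 0.0
    noise_sd_relaxation: float = 0.0
    noise_sd_shift_H: float = 0.0
    noise_sd_shift_C: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "noise_sd_sensorgram",
            "noise_sd_relaxation",
            "noise_sd_shift_H",
            "noise_sd_shift_C",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class GroundTruth:
    """Generative counterparts of every fitted quantity."""

    kinetic_params: TwoPhaseKineticParams
    r1_map: dict[str, dict[int, float]] = field(default_factory=dict)
    perturbed_residues: set[int] = field(default_factory=set)
    bound_fraction: float = 0.0
    diameter_populations: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must lie in [0, 1]")
        for cond, rmap in self.r1_map.items():
            if any(r <= 0 for r in rmap.values()):
                raise ValueError(f"r1 rates must be > 0 (condition {cond})")
        for mean, sd, n in self.diameter_populations:
            if mean <= 0:
                raise ValueError("diameter means must be > 0")


def gen_sensorgram_series(
    params: TwoPhaseKineticParams,
    concentrations: list[float],
    t_grid: np.ndarray,
    cfg: SyntheticConfig,
    duplicates: int = 1,
    pairing: str = "crossed",
) -> list[Sensorgram]:
    """Simulate a sensorgram concentration series.

    Each trace follows the association closed form before ``params.t_0``
    and the dissociation form after, with the dissociation amplitude fixed
    to the association value at ``t_0`` (continuity), plus additive
    Gaussian noise of SD ``cfg.noise_sd_sensorgram``.  ``duplicates``
    replicate injections are generated per concentration, each with
    independent noise.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if not (t_grid[0] < params.t_0 < t_grid[-1]):
        raise ValueError("t_0 must be interior to t_grid (both phases sampled)")
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be positive")
    rng = cfg.rng()
    out = []
    for c in concentrations:
        clean = eval_sensorgram(params, c, t_grid, params.t_0, pairing)
        for rep in range(duplicates):
            noisy = clean + rng.normal(0.0, cfg.noise_sd_sensorgram, t_grid.size) \
                if cfg.noise_sd_sensorgram > 0 else clean.copy()
            out.append(
                Sensorgram(
                    concentration=c,
                    times=t_grid.copy(),
                    responses=noisy,
                    t_0=params.t_0,
                    reference_subtracted=True,
                    curve_id=f"c{c:g}_r{rep + 1}",
                )
            )
    return out


def gen_inversion_recovery(
    r1_map: dict[int, float],
    delays: np.ndarray,
    cfg: SyntheticConfig,
    amplitude: float = -2.0,
    offset: float = 1.0,
    condition: str = "undoped",
) -> list[RelaxationSeries]:
    """Simulate per-residue inversion-recovery intensity series.

    Intensities follow I(t) = offset + amplitude*exp(-r1*t); the default
    (offset 1, amplitude -2) is the ideal inversion-recovery profile
    running from -1 at zero delay to +1 at full recovery.  Additive
    Gaussian noise of SD ``cfg.noise_sd_relaxation * |I(0)|`` is applied.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("delay list must be non-empty")
    if np.any(delays < 0) or len(set(delays.tolist())) != delays.size:
        raise ValueError("delays must be non-negative and unique")
    if any(r <= 0 for r in r1_map.values()):
        raise ValueError("r1 rates must be > 0")
    rng = cfg.rng()
    i0 = abs(offset + amplitude)
    noise_sd = cfg.noise_sd_relaxation * (i0 if i0 > 0 else abs(amplitude))
    out = []
    for res_idx in sorted(r1_map):
        clean = offset + amplitude * np.exp(-r1_map[res_idx] * delays)
        noisy = clean + rng.normal(0.0, noise_sd, delays.size) if noise_sd > 0 else clean
        out.append(
            RelaxationSeries(
                residue_index=res_idx,
                condition=condition,
                delays=delays.copy(),
                intensities=noisy,
                noise_sd=noise_sd,
            )
        )
    return out


def _base_shifts(i: int, aa: str) -> tuple[float, float]:
    """Deterministic, well-separated synthetic (heteronucleus, H) positions."""
    w_het = 40.0 + (i * 3.1) % 25.0  # carbon-like, ppm
    w_h = 3.0 + (i * 0.37) % 2.2
    return round(w_het, 3), round(w_h, 3)


def gen_peak_tables(
    sequence: str = AB42,
    perturbed_residues: set[int] | None = None,
    doubling: bool = False,
    attenuation: float = 0.0,
    cfg: SyntheticConfig | None = None,
    perturbation_H: float = 0.08,
    perturbation_hetero: float = 0.6,
    intensity: float = 1.0e6,
    snr: float | None = None,
) -> tuple[list[AssignedPeak], list[AssignedPeak]]:
    """Generate reference (fibril alone) and query (chaperone present) peak tables.

    One H-C cross-peak per residue at a deterministic position.  Perturbed
    residues appear in the query either shifted by
    (``perturbation_H``, ``perturbation_hetero``) (doubling off) or as both
    the reference-position peak and a shifted twin (doubling on).  Query
    intensities are scaled by (1 - attenuation); if ``snr`` is given,
    Gaussian intensity noise of SD intensity/snr is added.  Shift noise
    follows ``cfg.noise_sd_shift_H`` / ``noise_sd_shift_C``.
    """
    cfg = cfg or SyntheticConfig()
    perturbed = set(perturbed_residues or ())
    n = len(sequence)
    if any(r < 1 or r > n for r in perturbed):
        raise ValueError("perturbed residue outside sequence")
    if not 0.0 <= attenuation < 1.0:
        raise ValueError("attenuation must lie in [0, 1)")
    rng = cfg.rng()

    def _noise(sd):
        return rng.normal(0.0, sd) if sd > 0 else 0.0

    reference, query = [], []
    for i, aa in enumerate(sequence, start=1):
        w_het, w_h = _base_shifts(i, aa)
        reference.append(
            AssignedPeak(
                residue_index=i, residue_name=aa, atom_pair="C-H",
                w1=w_het, w2=w_h, intensity=intensity,
            )
        )
        q_int = intensity * (1.0 - attenuation)
        if snr is not None:
            q_int += rng.normal(0.0, intensity / snr)
        if i in perturbed:
            shifted = AssignedPeak(
                residue_index=i, residue_name=aa, atom_pair="C-H",
                w1=w_het + perturbation_hetero + _noise(cfg.noise_sd_shift_C),
                w2=w_h + perturbation_H + _noise(cfg.noise_sd_shift_H),
                intensity=q_int,
            )
            if doubling:
                query.append(
                    AssignedPeak(
                        residue_index=i, residue_name=aa, atom_pair="C-H",
                        w1=w_het + _noise(cfg.noise_sd_shift_C),
                        w2=w_h + _noise(cfg.noise_sd_shift_H),
                        intensity=q_int,
                    )
                )
            query.append(shifted)
        else:
            query.append(
                AssignedPeak(
                    residue_index=i, residue_name=aa, atom_pair="C-H",
                    w1=w_het + _noise(cfg.noise_sd_shift_C),
                    w2=w_h + _noise(cfg.noise_sd_shift_H),
                    intensity=q_int,
                )
            )
    return reference, query


def gen_intensity_pairs(
    n_peaks: int,
    attenuation: float,
    snr: float,
    cfg: SyntheticConfig,
    intensity: float = 1.0e6,
) -> list[tuple[str, float, float, float, float]]:
    """Simulate matched (free, mixed) cross-peak intensities.

    Mixed intensities are the free ones scaled by (1 - attenuation); both
    members get Gaussian noise of SD intensity/snr, mimicking a uniform
    solution-state attenuation read at a given signal-to-noise.  Returns
    tuples (peak_id, intensity_free, intensity_mixed, snr_free, snr_mixed).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if not 0.0 <= attenuation < 1.0:
        raise ValueError("attenuation must lie in [0, 1)")
    if snr <= 0:
        raise ValueError("snr must be > 0")
    rng = cfg.rng()
    sd = intensity / snr
    out = []
    for k in range(n_peaks):
        free = intensity + rng.normal(0.0, sd)
        mixed = intensity * (1.0 - attenuation) + rng.normal(0.0, sd)
        free = max(free, sd)
        mixed = max(mixed, sd)
        out.append((f"peak{k + 1}", free, mixed, free / sd, mixed / sd))
    return out


def gen_diameters(
    populations: list[tuple[float, float, int]],
    cfg: SyntheticConfig,
    labels: list[str] | None = None,
) -> list[DiameterSample]:
    """Draw fibril-diameter samples from normal populations truncated at 0.

    ``populations`` is a list of (mean nm, SD nm, n).  Truncation is by
    resampling; at realistic fibril parameters (mean >> SD) it is
    negligible.
    """
    rng = cfg.rng()
    out = []
    for k, (mean, sd, n) in enumerate(populations):
        if mean <= 0 or sd < 0 or n < 2:
            raise ValueError("need mean > 0, sd >= 0, n >= 2")
        if sd == 0:
            vals = np.full(n, float(mean))
        else:
            vals = rng.normal(mean, sd, n)
            while np.any(vals <= 0):
                bad = vals <= 0
                vals[bad] = rng.normal(mean, sd, int(bad.sum()))
        label = labels[k] if labels else f"population{k + 1}"
        out.append(DiameterSample(condition=label, diameters=vals))
    return out
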