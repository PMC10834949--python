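"""Chemical-shift-perturbation mapping and peak-doubling classification.

Binding of a partner to a fibril surface perturbs the local environment of
the contact residues.  In dipolar-correlation spectra this shows up either
as a shifted cross-peak or as *peak doubling* — coexistence of the
unshifted (apo-like) resonance and a shifted twin, indicating two local
environments.  Shift changes on the two dimensions of a cross-peak are
combined into a single per-residue magnitude

    |delta_comb| = sqrt((delta_het / s)^2 + delta_H^2),    s = 2 by default,

and residues whose combined change is significant form the interacting set
used to restrain docking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssignedPeak",
    "CSPRecord",
    "ActiveResidueSet",
    "ThresholdRule",
    "combined_shift",
    "match_peaks",
    "classify_significant",
    "select_interacting_residues",
    "export_restraints",
]


@dataclass
class AssignedPeak:
    """One assigned cross-peak: residue, atom pair and two shift axes (ppm)."""

    residue_index: int
    residue_name: str
    atom_pair: str  # e.g. "C-H" or "N-H"; w1 is the heteronucleus axis
    w1: float
    w2: float
    intensity: float = 0.0
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if not (math.isfinite(self.w1) and math.isfinite(self.w2)):
            raise ValueError("shifts must be finite")


@dataclass
class CSPRecord:
    residue_index: int
    delta_H: float
    delta_het: float
    delta_comb: float
    category: str  # unique | doubled | overlapped | ambiguous | missing
    hetero: str = "C"


@dataclass
class ActiveResidueSet:
    residues: list[int]
    threshold_ppm: float
    rule: str

    def __post_init__(self) -> None:
        self.residues = sorted(set(self.residues))


@dataclass
class ThresholdRule:
    """Significance rule: absolute cutoff or mean + k*SD over assessable residues."""

    kind: str = "mean_sd"  # "absolute" | "mean_sd"
    value: float = 1.0  # ppm if absolute, k if mean_sd

    def cutoff(self, deltas: np.ndarray) -> float:
        if self.kind == "absolute":
            return float(self.value)
        if self.kind == "mean_sd":
            return float(np.mean(deltas) + self.value * np.std(deltas, ddof=0))
        raise ValueError(f"unknown rule kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "absolute":
            return f"|delta_comb| > {self.value} ppm"
        return f"|delta_comb| > mean + {self.value}*SD"


def combined_shift(delta_H: float, delta_hetero: float, hetero_scale: float = 2.0) -> float:
    """Combined shift magnitude sqrt((delta_hetero/scale)^2 + delta_H^2).

    The default scale of 2 down-weights the wider heteronucleus (13C or
    15N) dispersion relative to 1H.
    """
    if hetero_scale <= 0:
        raise ValueError("hetero_scale must be > 0")
    return math.hypot(delta_hetero / hetero_scale, delta_H)


def _hetero_label(atom_pair: str) -> str:
    return "N" if atom_pair.upper().startswith("N") else "C"


def match_peaks(
    reference: list[AssignedPeak],
    query: list[AssignedPeak],
    radius_H: float = 0.05,
    radius_hetero: float = 0.2,
    hetero_scale: float = 2.0,
) -> list[CSPRecord]:
    """Match query peaks to reference peaks per residue and classify.

    Per (residue, atom pair): no query peak -> ``missing``; one query peak
    -> ``unique`` (delta from its displacement); two query peaks, one
    within (radius_hetero, radius_H) of the reference position and one
    shifted -> ``doubled`` with delta taken from the shifted member; other
    multi-peak patterns -> ``ambiguous``.  Reference peaks lying within the
    match radii of one another are mutually unresolvable -> ``overlapped``.
    Matching is independent of input row order.
    """
    if radius_H <= 0 or radius_hetero <= 0:
        raise ValueError("match radii must be > 0")
    ref_by_key: dict[tuple[int, str], AssignedPeak] = {}
    for p in reference:
        key = (p.residue_index, p.atom_pair)
        if key in ref_by_key:
            raise ValueError(f"duplicate reference row for {key}")
        ref_by_key[key] = p

    # reference-side overlap: peaks of the same atom pair closer than the radii
    overlapped_keys: set[tuple[int, str]] = set()
    ref_items = sorted(ref_by_key.items())
    for i, (k1, p1) in enumerate(ref_items):
        for k2, p2 in ref_items[i + 1 :]:
            if p1.atom_pair != p2.atom_pair:
                continue
            if abs(p1.w1 - p2.w1) <= radius_hetero and abs(p1.w2 - p2.w2) <= radius_H:
                overlapped_keys.update((k1, k2))

    q_by_key: dict[tuple[int, str], list[AssignedPeak]] = {}
    for p in query:
        q_by_key.setdefault((p.residue_index, p.atom_pair), []).append(p)

    records = []
    for key, ref in sorted(ref_by_key.items()):
        res_idx, atom_pair = key
        het = _hetero_label(atom_pair)
        qs = sorted(q_by_key.get(key, []), key=lambda p: (p.w1, p.w2))
        if key in overlapped_keys:
            records.append(CSPRecord(res_idx, 0.0, 0.0, 0.0, "overlapped", het))
            continue
        if not qs:
            records.append(CSPRecord(res_idx, 0.0, 0.0, 0.0, "missing", het))
            continue

        def _delta(p: AssignedPeak) -> tuple[float, float]:
            return p.w2 - ref.w2, p.w1 - ref.w1

        def _at_ref(p: AssignedPeak) -> bool:
            return abs(p.w1 - ref.w1) <= radius_hetero and abs(p.w2 - ref.w2) <= radius_H

        if len(qs) == 1:
            dh, dhet = _delta(qs[0])
            records.append(
                CSPRecord(res_idx, dh, dhet, combined_shift(dh, dhet, hetero_scale),
                          "unique", het)
            )
        elif len(qs) == 2 and _at_ref(qs[0]) != _at_ref(qs[1]):
            shifted = qs[1] if _at_ref(qs[0]) else qs[0]
            dh, dhet = _delta(shifted)
            records.append(
                CSPRecord(res_idx, dh, dhet, combined_shift(dh, dhet, hetero_scale),
                          "doubled", het)
            )
        else:
            # >2 candidates, or two peaks neither/both at the reference position
            deltas = [_delta(p) for p in qs]
            dh, dhet = max(deltas, key=lambda d: combined_shift(d[0], d[1], hetero_scale))
            records.append(
                CSPRecord(res_idx, dh, dhet, combined_shift(dh, dhet, hetero_scale),
                          "ambiguous", het)
            )
    return records


_ASSESSABLE = {"unique", "doubled", "ambiguous"}


def classify_significant(
    records: list[CSPRecord], rule: ThresholdRule | None = None
) -> dict[int, bool]:
    """Flag residues whose combined shift exceeds the threshold rule.

    Overlapped and missing residues are excluded from both the threshold
    statistics and the flags.  The comparison is strict, so a flat table
    (SD = 0) flags nothing under a mean + k*SD rule.
    """
    rule = rule or ThresholdRule()
    usable = [r for r in records if r.category in _ASSESSABLE]
    if not usable:
        raise ValueError("no assessable residues (all overlapped/missing)")
    deltas = np.array([r.delta_comb for r in usable])
    cutoff = rule.cutoff(deltas)
    flags: dict[int, bool] = {}
    for r in usable:
        flags[r.residue_index] = flags.get(r.residue_index, False) or (
            r.delta_comb > cutoff
        )
    return flags


def select_interacting_residues(
    records: list[CSPRecord],
    rule: ThresholdRule | None = None,
    include_ambiguous: bool = True,
) -> ActiveResidueSet:
    """Residues with significant shift changes, for use as docking restraints."""
    rule = rule or ThresholdRule()
    flags = classify_significant(records, rule)
    ambiguous = {r.residue_index for r in records if r.category == "ambiguous"}
    chosen = [
        idx
        for idx, flagged in flags.items()
        if flagged and (include_ambiguous or idx not in ambiguous)
    ]
    usable = [r.delta_comb for r in records if r.category in _ASSESSABLE]
    return ActiveResidueSet(
        residues=chosen,
        threshold_ppm=rule.cutoff(np.array(usable)),
        rule=rule.describe(),
    )


def export_restraints(
    fibril_set: ActiveResidueSet,
    partner_set: ActiveResidueSet,
    n_subunits: int = 3,
) -> list[dict]:
    """Tabulate active residues for docking, replicating fibril residues
    across the central fibril subunits.

    Returns rows with molecule / chain / residue columns; fibril residues
    appear once per subunit chain (A, B, C, ...), partner residues once on
    chain X.  Suitable for TSV export and manual transfer into docking
    software.
    """
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    if not fibril_set.residues or not partner_set.residues:
        raise ValueError("both restraint sets must be non-empty")
    rows = []
    for k in range(n_subunits):
        chain = chr(ord("A") + k)
        for res in fibril_set.residues:
            rows.append({"molecule": "fibril", "chain": chain, "residue": res})
    for res in partner_set.residues:
        rows.append({"molecule": "partner", "chain": "X", "residue": res})
    return rows
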