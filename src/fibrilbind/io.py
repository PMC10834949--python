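"""Readers and writers for the package's tabular formats.

Every writer has a matching reader and round-trips losslessly at the
stated precision: Sparky-style peak lists ("Assignment w1 w2 Height"),
sensorgram CSV, relaxation CSV, diameter CSV, and TSV exports for CSP
tables and docking restraints.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .csp import AssignedPeak, CSPRecord
from .morphometry import DiameterSample
from .relaxation import RelaxationSeries
from .spr import Sensorgram

__all__ = [
    "PeakList",
    "read_sparky_list",
    "write_sparky_list",
    "write_peaks_tsv",
    "read_peaks_tsv",
    "write_sensorgrams_csv",
    "read_sensorgrams_csv",
    "write_relaxation_csv",
    "read_relaxation_csv",
    "write_diameters_csv",
    "read_diameters_csv",
    "write_csp_table",
    "write_restraints_tsv",
]

# e.g. "G25N-H", "S26CA-HA", "A42C-H2"
_ASSIGNMENT_RE = re.compile(r"^([A-Z])(\d+)([A-Z][A-Z0-9]*)-([A-Z][A-Z0-9]*)$")


class PeakList(list):
    """List of AssignedPeak with a ``rejects`` report of unparseable rows."""

    def __init__(self, peaks=(), rejects=None):
        super().__init__(peaks)
        self.rejects: list[tuple[int, str]] = rejects or []


def _format_assignment(p: AssignedPeak) -> str:
    het, proton = (p.atom_pair.split("-") + ["H"])[:2]
    return f"{p.residue_name}{p.residue_index}{het}-{proton}"


def write_sparky_list(peaks: list[AssignedPeak], path: str | Path) -> None:
    lines = ["      Assignment         w1         w2   Height"]
    for p in peaks:
        lines.append(
            f"{_format_assignment(p):>16s} {p.w1:10.4f} {p.w2:10.4f} {p.intensity:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sparky_list(path: str | Path) -> PeakList:
    """Parse a Sparky-style list; malformed rows go to ``.rejects``.

    Assignment strings like ``S26N-H`` decompose into residue name (S),
    index (26) and atom pair (N-H); w1 is the heteronucleus axis and w2
    the proton axis.  An empty file yields an empty list with a warning.
    """
    text = Path(path).read_text().splitlines()
    peaks = PeakList()
    body = [
        (i, ln) for i, ln in enumerate(text, 1) if ln.strip()
    ]
    if body and "Assignment" in body[0][1]:
        header = body[0][1]
        if "w1" not in header or "w2" not in header:
            raise ValueError(f"unparseable header in {path}: {header!r}")
        body = body[1:]
    if not body:
        warnings.warn(f"empty peak list: {path}")
        return peaks
    for lineno, line in body:
        fields = line.split()
        m = _ASSIGNMENT_RE.match(fields[0]) if len(fields) >= 3 else None
        if not m:
            peaks.rejects.append((lineno, line))
            continue
        name, idx, het, proton = m.groups()
        try:
            w1, w2 = float(fields[1]), float(fields[2])
            height = float(fields[3]) if len(fields) > 3 else 0.0
        except ValueError:
            peaks.rejects.append((lineno, line))
            continue
        # atom pair keyed by nucleus type, not the specific atom name
        pair = f"{'N' if het.startswith('N') else 'C'}-H"
        peaks.append(
            AssignedPeak(
                residue_index=int(idx), residue_name=name, atom_pair=pair,
                w1=w1, w2=w2, intensity=height,
            )
        )
    return peaks


def write_peaks_tsv(peaks: list[AssignedPeak], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "residue_index": p.residue_index,
                "residue_name": p.residue_name,
                "atom_pair": p.atom_pair,
                "w1": p.w1,
                "w2": p.w2,
                "intensity": p.intensity,
            }
            for p in peaks
        ]
    ).to_csv(path, sep="\t", index=False)


def read_peaks_tsv(path: str | Path) -> list[AssignedPeak]:
    df = pd.read_csv(path, sep="\t")
    return [
        AssignedPeak(
            residue_index=int(r.residue_index), residue_name=str(r.residue_name),
            atom_pair=str(r.atom_pair), w1=float(r.w1), w2=float(r.w2),
            intensity=float(r.intensity),
        )
        for r in df.itertuples()
    ]


def write_sensorgrams_csv(series: list[Sensorgram], path: str | Path) -> None:
    frames = []
    for sg in series:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sg.times,
                    "response": sg.responses,
                    "concentration_M": sg.concentration,
                    "curve_id": sg.curve_id or f"c={sg.concentration:g}",
                    "t0_s": sg.t_0,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_sensorgrams_csv(path: str | Path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    out = []
    for cid, grp in df.groupby("curve_id", sort=True):
        out.append(
            Sensorgram(
                concentration=float(grp["concentration_M"].iloc[0]),
                times=grp["time_s"].to_numpy(),
                responses=grp["response"].to_numpy(),
                t_0=float(grp["t0_s"].iloc[0]),
                reference_subtracted=True,
                curve_id=str(cid),
            )
        )
    return out


def write_relaxation_csv(series: list[RelaxationSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "residue": s.residue_index,
                    "condition": s.condition,
                    "delay_s": s.delays,
                    "intensity": s.intensities,
                    "noise_sd": s.noise_sd,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_relaxation_csv(path: str | Path) -> list[RelaxationSeries]:
    df = pd.read_csv(path)
    out = []
    for (res, cond), grp in df.groupby(["residue", "condition"], sort=True):
        out.append(
            RelaxationSeries(
                residue_index=int(res),
                condition=str(cond),
                delays=grp["delay_s"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                noise_sd=float(grp["noise_sd"].iloc[0]),
            )
        )
    return out


def write_diameters_csv(sample: DiameterSample, path: str | Path) -> None:
    pd.DataFrame({"diameter_nm": sample.diameters}).to_csv(path, index=False)


def read_diameters_csv(path: str | Path, condition: str = "") -> DiameterSample:
    df = pd.read_csv(path)
    return DiameterSample(
        condition=condition or Path(path).stem,
        diameters=df["diameter_nm"].to_numpy(),
    )


def write_csp_table(
    records: list[CSPRecord], flags: dict[int, bool], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "residue": r.residue_index,
                "delta_H": r.delta_H,
                "delta_het": r.delta_het,
                "delta_comb": r.delta_comb,
                "category": r.category,
                "significant": bool(flags.get(r.residue_index, False)),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_restraints_tsv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
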