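"""End-to-end orchestration of the five analysis stages.

``run_pipeline`` executes any subset of the stages (spr, csp, pre, bound,
morph) under a single configuration and seed, writes per-stage outputs
into an output directory, and returns a combined :class:`RunReport`.
Without input paths each stage runs on synthetic data drawn from the
package's built-in demonstration ground truth, so a one-call demo
exercises every analysis against known generative parameters.

One global seed fans out into per-stage seeds by stable hashing, so a
stage-subset run reproduces the corresponding stages of a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import binding, csp, io, morphometry, relaxation, spr
from .sequences import AB42

__version__ = "0.1.0"

__all__ = ["RunConfig", "RunReport", "run_pipeline", "derive_seed", "DEMO_TRUTH"]

STAGES = ("spr", "csp", "pre", "bound", "morph")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _demo_truth() -> dict:
    """The built-in demonstration world for all-synthetic runs."""
    from .synthetic import GroundTruth  # local import to avoid cycle

    kinetics = spr.TwoPhaseKineticParams(
        k_on1=1.0e5, k_on2=1.0e3, k_off1=1.0e-2, k_off2=1.29e-3,
        B_max1=100.0, B_max2=80.0, a=0.4, t_0=300.0,
    )
    r1_apo_undoped = {i: 0.30 for i in range(1, 43)}
    apo_pre_sites = {9: 0.3, 16: 0.3, 26: 0.3, 27: 0.3, 28: 0.3, 29: 0.3, 42: 0.3}
    holo_pre_sites = dict(apo_pre_sites)
    for res in (26, 27, 28, 29):  # buried by the bound chaperone
        holo_pre_sites[res] = 0.05
    holo_pre_sites[42] = 0.6      # C-terminus released, more exposed
    r1_map = {
        "apo_undoped": r1_apo_undoped,
        "apo_doped": {i: r1_apo_undoped[i] + apo_pre_sites.get(i, 0.0) for i in r1_apo_undoped},
        "holo_undoped": dict(r1_apo_undoped),
        "holo_doped": {i: r1_apo_undoped[i] + holo_pre_sites.get(i, 0.0) for i in r1_apo_undoped},
    }
    return {
        "truth": GroundTruth(
            kinetic_params=kinetics,
            r1_map=r1_map,
            perturbed_residues={27, 28, 30, 31, 32, 40, 41, 42},
            bound_fraction=0.10,
            diameter_populations=[(13.8, 2.9, 100), (8.4, 1.5, 100)],
        ),
        "concentrations_M": [50e-6 / 2**k for k in range(9)],  # 0.195 - 50 uM
        "partner_residues": [115, 130, 132, 139, 140, 141, 142, 143, 145, 156, 157, 158],
        "soluble_fraction": 0.95,
    }


DEMO_TRUTH = _demo_truth()


@dataclass
class RunConfig:
    """Configuration for a pipeline run.

    All analysis constants (pairing, thresholds, k_sigma, n_sim, test
    variant) are surfaced here; nothing numeric is hard-coded in the
    stage runners.
    """

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    out_dir: str = "fibrilbind_out"
    rng_seed: int = 0
    fail_fast: bool = False
    spr_opts: dict = field(default_factory=lambda: {
        "input": None, "exclude_lowest": 2, "pairing": "crossed",
        "n_starts": 4, "noise_sd": 0.85,
    })
    csp_opts: dict = field(default_factory=lambda: {
        "reference": None, "query": None, "rule": "mean_sd", "rule_value": 1.0,
        "include_ambiguous": True, "n_subunits": 3,
    })
    pre_opts: dict = field(default_factory=lambda: {
        "input": None, "n_sim": 500, "k_sigma": 2.0, "noise_sd": 0.02,
    })
    bound_opts: dict = field(default_factory=lambda: {
        "input": None, "n_peaks": 50, "snr": 30.0, "tolerance": 0.06,
    })
    morph_opts: dict = field(default_factory=lambda: {
        "input_a": None, "input_b": None, "variant": "student", "boundary_nm": 11.0,
    })

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        merged = {}
        for f in dataclasses.fields(cls):
            if f.name in d and f.name.endswith("_opts"):
                opts = dict(getattr(base, f.name))
                extra = set(d[f.name]) - set(opts)
                if extra:
                    raise ValueError(f"unknown keys in {f.name}: {sorted(extra)}")
                opts.update(d[f.name])
                merged[f.name] = opts
            elif f.name in d:
                merged[f.name] = d[f.name]
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunReport:
    stages: dict[str, dict]
    version: str
    config: dict
    status: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stage runners


def _stage_spr(cfg: RunConfig, out: Path, seed: int) -> dict:
    from .synthetic import SyntheticConfig, gen_sensorgram_series

    opts = cfg.spr_opts
    if opts["input"]:
        series = io.read_sensorgrams_csv(opts["input"])
    else:
        truth = DEMO_TRUTH["truth"].kinetic_params
        t_grid = np.arange(0.0, 900.0, 1.0)
        series = gen_sensorgram_series(
            truth, DEMO_TRUTH["concentrations_M"], t_grid,
            SyntheticConfig(rng_seed=seed, noise_sd_sensorgram=opts["noise_sd"]),
            duplicates=2, pairing=opts["pairing"],
        )
        io.write_sensorgrams_csv(series, out / "sensorgrams.csv")
    fit = spr.global_fit(
        series, exclude_lowest=opts["exclude_lowest"], pairing=opts["pairing"],
        n_starts=opts["n_starts"], seed=seed,
    )
    report = {
        "kd_strong_M": fit.kd_strong,
        "kd_weak_M": fit.kd_weak,
        "converged": fit.converged,
        "residual_rms": fit.residual_rms,
        "excluded_concentrations_M": fit.excluded_concentrations,
        "params": {
            k: getattr(fit.params, k)
            for k in ("k_on1", "k_on2", "k_off1", "k_off2", "B_max1", "B_max2", "a")
        },
        "param_errors": fit.param_errors,
        "pairing": fit.pairing,
    }
    (out / "spr_fit.json").write_text(json.dumps(report, indent=2))
    return report


def _stage_csp(cfg: RunConfig, out: Path, seed: int) -> dict:
    from .synthetic import SyntheticConfig, gen_peak_tables

    opts = cfg.csp_opts
    if opts["reference"] and opts["query"]:
        reference = io.read_sparky_list(opts["reference"])
        query = io.read_sparky_list(opts["query"])
    else:
        reference, query = gen_peak_tables(
            sequence=AB42,
            perturbed_residues=DEMO_TRUTH["truth"].perturbed_residues,
            doubling=True,
            attenuation=0.0,
            cfg=SyntheticConfig(
                rng_seed=seed, noise_sd_shift_H=0.002, noise_sd_shift_C=0.01
            ),
        )
        io.write_sparky_list(reference, out / "reference.list")
        io.write_sparky_list(query, out / "query.list")
    records = csp.match_peaks(reference, query)
    rule = csp.ThresholdRule(kind=opts["rule"], value=opts["rule_value"])
    flags = csp.classify_significant(records, rule)
    active = csp.select_interacting_residues(records, rule, opts["include_ambiguous"])
    partner = csp.ActiveResidueSet(
        residues=DEMO_TRUTH["partner_residues"], threshold_ppm=0.0,
        rule="predicted client-contact residues",
    )
    restraints = csp.export_restraints(active, partner, n_subunits=opts["n_subunits"])
    io.write_csp_table(records, flags, out / "csp_table.tsv")
    io.write_restraints_tsv(restraints, out / "restraints.tsv")
    return {
        "interacting_residues": active.residues,
        "threshold_ppm": active.threshold_ppm,
        "rule": active.rule,
        "n_doubled": sum(1 for r in records if r.category == "doubled"),
        "n_restraint_rows": len(restraints),
    }


def _stage_pre(cfg: RunConfig, out: Path, seed: int) -> dict:
    from .synthetic import SyntheticConfig, gen_inversion_recovery

    opts = cfg.pre_opts
    if opts["input"]:
        all_series = io.read_relaxation_csv(opts["input"])
        by_cond: dict[str, list] = {}
        for s in all_series:
            by_cond.setdefault(s.condition, []).append(s)
    else:
        r1_map = DEMO_TRUTH["truth"].r1_map
        delays = {
            "apo": np.array([0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0]),
            "holo": np.array([0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 10.0, 15.0, 20.0]),
        }
        by_cond = {}
        rows = []
        for k, cond in enumerate(sorted(r1_map)):
            state = cond.split("_")[0]
            series = gen_inversion_recovery(
                r1_map[cond], delays[state],
                SyntheticConfig(rng_seed=seed + k, noise_sd_relaxation=opts["noise_sd"]),
                condition=cond,
            )
            by_cond[cond] = series
            rows.extend(series)
        io.write_relaxation_csv(rows, out / "relaxation.csv")

    profiles = {}
    r1_rows = []
    for state in ("apo", "holo"):
        fits = {}
        for kind in ("doped", "undoped"):
            cond = f"{state}_{kind}"
            fits[kind] = []
            for s in by_cond.get(cond, []):
                fit = relaxation.fit_inversion_recovery(s)
                if fit.converged and s.noise_sd > 0:
                    fit.r1_err = relaxation.mc_error(
                        s, fit, n_sim=opts["n_sim"],
                        seed=derive_seed(seed, f"{cond}:{s.residue_index}"),
                    )
                r1_rows.append(fit)
                fits[kind].append(fit)
        profiles[state] = relaxation.compute_pre(
            fits["doped"], fits["undoped"], condition=state
        )
    report_obj = relaxation.delta_pre(
        profiles["apo"], profiles["holo"], k_sigma=opts["k_sigma"]
    )

    import pandas as pd

    pd.DataFrame(
        [
            {"residue": f.residue_index, "condition": f.condition, "r1": f.r1,
             "r1_err": f.r1_err, "converged": f.converged}
            for f in r1_rows
        ]
    ).to_csv(out / "r1_fits.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"residue": res, "condition": state, "pre": v[0], "pre_err": v[1]}
            for state, prof in profiles.items()
            for res, v in sorted(prof.values.items())
        ]
    ).to_csv(out / "pre_profiles.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"residue": res, "delta_pre": d[0], "err": d[1],
             "flag": report_obj.flags.get(res, "")}
            for res, d in sorted(report_obj.diffs.items())
        ]
    ).to_csv(out / "delta_pre.tsv", sep="\t", index=False)
    return {
        "segments": [list(s) for s in report_obj.segments],
        "n_flagged": len(report_obj.flags),
        "k_sigma": report_obj.k_sigma,
    }


def _stage_bound(cfg: RunConfig, out: Path, seed: int) -> dict:
    from .synthetic import SyntheticConfig, gen_intensity_pairs

    opts = cfg.bound_opts
    if opts["input"]:
        import pandas as pd

        df = pd.read_csv(opts["input"], sep="\t")
        pairs = [
            binding.IntensityPair(
                str(r.peak_id), float(r.intensity_free), float(r.intensity_mixed),
                float(r.snr_free), float(r.snr_mixed),
            )
            for r in df.itertuples()
        ]
    else:
        raw = gen_intensity_pairs(
            opts["n_peaks"], DEMO_TRUTH["truth"].bound_fraction, opts["snr"],
            SyntheticConfig(rng_seed=seed),
        )
        pairs = [binding.IntensityPair(*r) for r in raw]
    ratios = binding.intensity_ratios(pairs)
    result = binding.bound_fraction(ratios)
    consistency = binding.supernatant_consistency(
        result.bound_fraction, DEMO_TRUTH["soluble_fraction"], opts["tolerance"]
    )
    report = {
        "bound_fraction": result.bound_fraction,
        "mean_ratio": result.mean_ratio,
        "ratio_err": result.ratio_err,
        "ratio_sd": result.ratio_sd,
        "uniformity_stat": result.uniformity_stat,
        "n_peaks": result.n_peaks,
        "supernatant_consistency": dataclasses.asdict(consistency),
    }
    (out / "bound_fraction.json").write_text(json.dumps(report, indent=2))
    return report


def _stage_morph(cfg: RunConfig, out: Path, seed: int) -> dict:
    from .synthetic import SyntheticConfig, gen_diameters

    opts = cfg.morph_opts
    if opts["input_a"] and opts["input_b"]:
        a = io.read_diameters_csv(opts["input_a"], "group_a")
        b = io.read_diameters_csv(opts["input_b"], "group_b")
    else:
        a, b = gen_diameters(
            DEMO_TRUTH["truth"].diameter_populations,
            SyntheticConfig(rng_seed=seed),
            labels=["fibrils_alone", "chaperone_coincubated"],
        )
        io.write_diameters_csv(a, out / "diameters_a.csv")
        io.write_diameters_csv(b, out / "diameters_b.csv")
    sa, sb = morphometry.summarize(a), morphometry.summarize(b)
    tests = {
        v: dataclasses.asdict(morphometry.ttest_from_summary(sa, sb, v))
        for v in ("student", "welch")
    }
    report = {
        "group_a": {"condition": a.condition, **dataclasses.asdict(sa)},
        "group_b": {"condition": b.condition, **dataclasses.asdict(sb)},
        "tests": tests,
        "class_a": morphometry.cross_section_class(sa.mean, opts["boundary_nm"]),
        "class_b": morphometry.cross_section_class(sb.mean, opts["boundary_nm"]),
    }
    (out / "morphometry.json").write_text(json.dumps(report, indent=2))
    return report


_RUNNERS = {
    "spr": _stage_spr,
    "csp": _stage_csp,
    "pre": _stage_pre,
    "bound": _stage_bound,
    "morph": _stage_morph,
}


def run_pipeline(config: RunConfig | dict) -> RunReport:
    """Execute the selected stages in canonical order and write a report.

    Each stage's failure is recorded in ``status`` and halts only that
    stage unless ``fail_fast`` is set.  Identical (config, seed) pairs
    produce identical reports.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    status: dict[str, str] = {}
    for name in STAGES:
        if name not in cfg.stages:
            continue
        seed = derive_seed(cfg.rng_seed, name)
        try:
            stages[name] = _RUNNERS[name](cfg, out, seed)
            status[name] = "ok"
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            status[name] = f"error: {exc}"
            if cfg.fail_fast:
                raise
    report = RunReport(
        stages=stages,
        version=__version__,
        config=dataclasses.asdict(cfg),
        status=status,
    )
    report.to_json(out / "run_report.json")
    return report
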