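"""Two-phase SPR binding kinetics.

Surface plasmon resonance sensorgrams of a chaperone domain binding to
immobilized amyloid fibrils are described by a two-phase association /
two-phase dissociation model.  During the injection (``t < t_0``) the
response is a sum of two saturating exponentials,

    R_asso(t) = kon1*c*Bmax1/(kon1*c + koffX) * (1 - exp(-kobs1*t))
              + kon2*c*Bmax2/(kon2*c + koffY) * (1 - exp(-kobs2*t))

with observed rates ``kobs_i = c*kon_i + koff``.  After the injection stops
the response decays biexponentially,

    R_diss(t) = R0 * (a*exp(-koff1*(t-t0)) + (1-a)*exp(-koff2*(t-t0))).

The published form of the observed rates pairs kon1 with koff2 and kon2
with koff1 ("crossed" pairing).  Because that pairing is unusual and may be
typographical, both conventions are implemented; ``pairing="crossed"`` is
the default and ``pairing="paired"`` gives the textbook
``kobs_i = c*kon_i + koff_i``.

A concentration series is fitted globally: one shared set of rate
constants, amplitudes and mixing weight across all retained curves, with a
per-curve dissociation amplitude R0.  Apparent dissociation constants are
the off/on-rate ratios under the selected pairing; the smaller one is the
"strong" (specific) site, the larger the "weak" (unspecific) one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

__all__ = [
    "Sensorgram",
    "TwoPhaseKineticParams",
    "KineticFitResult",
    "eval_association",
    "eval_dissociation",
    "subtract_reference",
    "global_fit",
    "compute_kd",
]

_PAIRINGS = ("crossed", "paired")


@dataclass
class Sensorgram:
    """One injection's response-vs-time trace.

    Parameters
    ----------
    concentration : float
        Analyte (chaperone) concentration in molar.
    times : array-like
        Strictly increasing time points in seconds.
    responses : array-like
        Response units, same length as ``times``.
    t_0 : float
        Injection stop time (s); association for ``t < t_0``, dissociation
        after.  Must lie inside the sampled time span.
    reference_subtracted : bool
        Whether the blank-surface response has been subtracted.
    """

    concentration: float
    times: np.ndarray
    responses: np.ndarray
    t_0: float
    reference_subtracted: bool = False
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.responses.shape:
            raise ValueError("times and responses must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if not (self.times[0] <= self.t_0 <= self.times[-1]):
            raise ValueError("t_0 must lie within the sampled time span")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass
class TwoPhaseKineticParams:
    """Full parameter set of the two-phase model.

    Rates are in 1/(M s) (on-rates) and 1/s (off-rates); amplitudes in
    response units; ``a`` in [0, 1] weights the two dissociation phases.
    ``R_0`` may be None (derive from continuity at ``t_0``), a scalar, or a
    per-curve array; ``t_0`` is the injection stop used when evaluating the
    dissociation phase.
    """

    k_on1: float
    k_on2: float
    k_off1: float
    k_off2: float
    B_max1: float
    B_max2: float
    a: float = 1.0
    R_0: float | np.ndarray | None = None
    t_0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_on1", "k_on2", "k_off1", "k_off2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.B_max1 < 0 or self.B_max2 < 0:
            raise ValueError("B_max amplitudes must be >= 0")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("a must lie in [0, 1]")

    def replace(self, **kw) -> "TwoPhaseKineticParams":
        return dataclasses.replace(self, **kw)


@dataclass
class KineticFitResult:
    params: TwoPhaseKineticParams
    kd_strong: float
    kd_weak: float
    param_errors: dict[str, float]
    residual_rms: float
    excluded_concentrations: list[float]
    converged: bool
    pairing: str = "crossed"
    r0_per_curve: dict[str, float] = field(default_factory=dict)
    cost: float = float("nan")


def _kobs(params: TwoPhaseKineticParams, c: float, pairing: str):
    if pairing not in _PAIRINGS:
        raise ValueError(f"pairing must be one of {_PAIRINGS}")
    if pairing == "crossed":
        return c * params.k_on1 + params.k_off2, c * params.k_on2 + params.k_off1
    return c * params.k_on1 + params.k_off1, c * params.k_on2 + params.k_off2


def eval_association(
    params: TwoPhaseKineticParams,
    c: float,
    t: np.ndarray | float,
    pairing: str = "crossed",
) -> np.ndarray | float:
    """Evaluate the two-phase association response at time(s) ``t``.

    ``t`` is measured from the injection start; negative times are
    rejected.  Returns 0 at t = 0 and approaches the weighted sum of the
    two plateau amplitudes at large t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("association time must be >= 0")
    if c <= 0:
        raise ValueError("concentration must be positive")
    kobs1, kobs2 = _kobs(params, c, pairing)
    term1 = params.k_on1 * c * params.B_max1 / kobs1 * (1.0 - np.exp(-kobs1 * t))
    term2 = params.k_on2 * c * params.B_max2 / kobs2 * (1.0 - np.exp(-kobs2 * t))
    out = term1 + term2
    return out.item() if out.ndim == 0 else out


def eval_dissociation(
    params: TwoPhaseKineticParams,
    t: np.ndarray | float,
    r0: float | None = None,
    t0: float | None = None,
) -> np.ndarray | float:
    """Evaluate the biexponential dissociation response at time(s) ``t``.

    ``t`` is absolute time; must satisfy ``t >= t_0``.  Equals ``R_0`` at
    ``t = t_0``.
    """
    t = np.asarray(t, dtype=float)
    t0 = params.t_0 if t0 is None else t0
    if r0 is None:
        if params.R_0 is None:
            raise ValueError("R_0 is unset; pass r0 explicitly")
        r0 = float(np.asarray(params.R_0).ravel()[0])
    if np.any(t < t0):
        raise ValueError("dissociation time must be >= t_0")
    dt = t - t0
    out = r0 * (
        params.a * np.exp(-params.k_off1 * dt)
        + (1.0 - params.a) * np.exp(-params.k_off2 * dt)
    )
    return out.item() if out.ndim == 0 else out


def eval_sensorgram(
    params: TwoPhaseKineticParams,
    c: float,
    t: np.ndarray,
    t0: float,
    pairing: str = "crossed",
) -> np.ndarray:
    """Full noiseless trace: association for t < t0, dissociation after.

    R_0 is tied to the association value at t0 so the trace is continuous.
    """
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    asso = t < t0
    out[asso] = eval_association(params, c, t[asso], pairing)
    r0 = float(eval_association(params, c, t0, pairing))
    out[~asso] = eval_dissociation(params, t[~asso], r0=r0, t0=t0)
    return out


def subtract_reference(
    sample: Sensorgram, blank: Sensorgram, interpolate: bool = False
) -> Sensorgram:
    """Subtract a blank-surface trace from a sample trace pointwise.

    Time grids must match exactly unless ``interpolate`` is set, in which
    case the blank is linearly interpolated onto the sample grid.
    """
    if sample.times.shape == blank.times.shape and np.allclose(
        sample.times, blank.times
    ):
        blank_resp = blank.responses
    elif interpolate:
        blank_resp = np.interp(sample.times, blank.times, blank.responses)
    else:
        raise ValueError("time grids differ; pass interpolate=True")
    return Sensorgram(
        concentration=sample.concentration,
        times=sample.times.copy(),
        responses=sample.responses - blank_resp,
        t_0=sample.t_0,
        reference_subtracted=True,
        curve_id=sample.curve_id,
    )


def compute_kd(
    params: TwoPhaseKineticParams, pairing: str = "crossed"
) -> tuple[float, float]:
    """Apparent dissociation constants under the selected pairing.

    crossed: (k_off2/k_on1, k_off1/k_on2); paired: (k_off_i/k_on_i).
    Returns (kd_strong, kd_weak) with kd_strong = min of the two.
    """
    if pairing not in _PAIRINGS:
        raise ValueError(f"pairing must be one of {_PAIRINGS}")
    if pairing == "crossed":
        kds = (params.k_off2 / params.k_on1, params.k_off1 / params.k_on2)
    else:
        kds = (params.k_off1 / params.k_on1, params.k_off2 / params.k_on2)
    return min(kds), max(kds)


# ---------------------------------------------------------------------------
# Global fitting


def _split_curve(sg: Sensorgram):
    asso = sg.times < sg.t_0
    return asso, ~asso


def _design_residuals(theta, curves, pairing, return_full=False):
    """Variable-projection residuals.

    theta = (log10 kon1, log10 kon2, log10 koff1, log10 koff2, a).
    Shared amplitudes B_max1/B_max2 and per-curve R_0 are solved linearly.
    """
    kon1, kon2, koff1, koff2 = 10.0 ** np.asarray(theta[:4], dtype=float)
    a = float(theta[4])
    rows = []
    y_asso = []
    for sg, (asso, _diss) in curves:
        c = sg.concentration
        if pairing == "crossed":
            kobs1, kobs2 = c * kon1 + koff2, c * kon2 + koff1
        else:
            kobs1, kobs2 = c * kon1 + koff1, c * kon2 + koff2
        t = sg.times[asso]
        b1 = kon1 * c / kobs1 * (1.0 - np.exp(-kobs1 * t))
        b2 = kon2 * c / kobs2 * (1.0 - np.exp(-kobs2 * t))
        rows.append(np.column_stack([b1, b2]))
        y_asso.append(sg.responses[asso])
    A = np.vstack(rows)
    y = np.concatenate(y_asso)
    bmax, _ = nnls(A, y)
    res_asso = A @ bmax - y

    res_diss = []
    r0s = []
    for sg, (_asso, diss) in curves:
        dt = sg.times[diss] - sg.t_0
        g = a * np.exp(-koff1 * dt) + (1.0 - a) * np.exp(-koff2 * dt)
        yd = sg.responses[diss]
        denom = float(g @ g)
        r0 = max(float(g @ yd) / denom, 0.0) if denom > 0 else 0.0
        r0s.append(r0)
        res_diss.append(r0 * g - yd)
    res = np.concatenate([res_asso, *res_diss])
    if return_full:
        return res, bmax, np.asarray(r0s)
    return res


def _heuristic_start(curves, pairing):
    """Data-driven starting point for the rate constants.

    The fast observed rate is read off the highest-concentration association
    curve (time to half plateau); the two off-rates from the early and late
    log-slopes of its dissociation tail.
    """
    sg, (asso, diss) = max(curves, key=lambda cv: cv[0].concentration)
    c = sg.concentration
    ya = sg.responses[asso]
    ta = sg.times[asso]
    plateau = max(float(ya[-1]), 1e-12)
    half_idx = int(np.searchsorted(ya, 0.5 * plateau))
    t_half = ta[min(half_idx, len(ta) - 1)] or (ta[-1] / 10.0)
    kobs_fast = np.log(2.0) / max(t_half, 1e-6)

    td = sg.times[diss] - sg.t_0
    yd = np.clip(sg.responses[diss], 1e-12, None)
    n = len(td)
    # early vs late window log-slopes bracket the two off-rates
    def _slope(sel):
        if sel.sum() < 2:
            return 1e-3
        p = np.polyfit(td[sel], np.log(yd[sel]), 1)
        return max(-p[0], 1e-6)

    koff_fast = _slope(np.arange(n) < max(n // 4, 2))
    koff_slow = _slope(np.arange(n) >= 3 * n // 4)
    koff_slow = min(koff_slow, koff_fast)
    kon_fast = max((kobs_fast - koff_slow) / c, 1e-1)
    # the slow association phase: assume ~10x slower on-rate as a seed
    if pairing == "crossed":
        start = (kon_fast, kon_fast / 100.0, koff_fast, koff_slow)
    else:
        start = (kon_fast, kon_fast / 100.0, koff_slow, koff_fast)
    return np.array([*np.log10(start), 0.5])


def _full_model_jacobian(theta_full, curves, pairing, eps=1e-6):
    """Numeric Jacobian of the concatenated model in the full parameters.

    theta_full = (kon1, kon2, koff1, koff2, Bmax1, Bmax2, a, R0_1..R0_m),
    rates and amplitudes on their natural (linear) scale.
    """

    def model(v):
        p = TwoPhaseKineticParams(
            k_on1=v[0], k_on2=v[1], k_off1=v[2], k_off2=v[3],
            B_max1=v[4], B_max2=v[5], a=min(max(v[6], 0.0), 1.0),
        )
        out = []
        for j, (sg, (asso, diss)) in enumerate(curves):
            out.append(eval_association(p, sg.concentration, sg.times[asso], pairing))
            dt = sg.times[diss] - sg.t_0
            r0 = v[7 + j]
            out.append(
                r0 * (p.a * np.exp(-p.k_off1 * dt) + (1 - p.a) * np.exp(-p.k_off2 * dt))
            )
        return np.concatenate(out)

    f0 = model(theta_full)
    J = np.empty((f0.size, theta_full.size))
    for k in range(theta_full.size):
        v = theta_full.copy()
        h = eps * max(abs(v[k]), 1e-12)
        v[k] += h
        J[:, k] = (model(v) - f0) / h
    return J, f0


def global_fit(
    series: list[Sensorgram],
    init: TwoPhaseKineticParams | None = None,
    exclude_lowest: int = 2,
    pairing: str = "crossed",
    n_starts: int = 8,
    seed: int = 0,
    rate_bounds: dict[str, tuple[float, float]] | None = None,
) -> KineticFitResult:
    """Globally fit a sensorgram concentration series.

    All retained curves share (k_on1, k_on2, k_off1, k_off2, B_max1,
    B_max2, a); each curve keeps its own dissociation amplitude R_0.  The
    ``exclude_lowest`` smallest concentrations are dropped before fitting
    (duplicate injections at an excluded concentration are all dropped).
    Optimization is multistart least squares over log10 rates; the mixing
    weight and amplitudes are recovered by linear projection at every step.

    Parameters
    ----------
    init : TwoPhaseKineticParams, optional
        Additional starting point; otherwise a data-driven start plus
        ``n_starts`` seeded log-uniform draws over ``rate_bounds``.
    rate_bounds : dict, optional
        ``{"k_on": (lo, hi), "k_off": (lo, hi)}`` in 1/(M s) and 1/s;
        defaults (1e1, 1e8) and (1e-6, 1e1).
    """
    if pairing not in _PAIRINGS:
        raise ValueError(f"pairing must be one of {_PAIRINGS}")
    concs = sorted({sg.concentration for sg in series})
    excluded = concs[:exclude_lowest]
    retained = [sg for sg in series if sg.concentration not in excluded]
    if len({sg.concentration for sg in retained}) < 3:
        raise ValueError("need >= 3 retained concentrations for a global fit")
    curves = []
    for sg in retained:
        asso, diss = _split_curve(sg)
        if asso.sum() < 4 or diss.sum() < 4:
            raise ValueError(
                f"curve {sg.curve_id or sg.concentration} lacks one of the phases"
            )
        curves.append((sg, (asso, diss)))

    rb = {"k_on": (1e1, 1e8), "k_off": (1e-6, 1e1)}
    if rate_bounds:
        rb.update(rate_bounds)
    lo = np.array([np.log10(rb["k_on"][0])] * 2 + [np.log10(rb["k_off"][0])] * 2 + [0.0])
    hi = np.array([np.log10(rb["k_on"][1])] * 2 + [np.log10(rb["k_off"][1])] * 2 + [1.0])

    starts = [np.clip(_heuristic_start(curves, pairing), lo, hi)]
    if init is not None:
        starts.append(
            np.clip(
                np.array(
                    [
                        np.log10(init.k_on1), np.log10(init.k_on2),
                        np.log10(init.k_off1), np.log10(init.k_off2),
                        init.a,
                    ]
                ),
                lo, hi,
            )
        )
    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        draw = lo + rng.random(5) * (hi - lo)
        starts.append(draw)

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                _design_residuals, x0, bounds=(lo, hi),
                args=(curves, pairing), method="trf", x_scale="jac",
                max_nfev=400,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    converged = best is not None and best.status > 0 and np.all(np.isfinite(best.x))
    if best is None:
        raise RuntimeError("all multistart optimizations raised")

    # polish the winner
    sol = least_squares(
        _design_residuals, best.x, bounds=(lo, hi), args=(curves, pairing),
        method="trf", x_scale="jac",
    )
    if sol.cost <= best.cost:
        best = sol
    res, bmax, r0s = _design_residuals(best.x, curves, pairing, return_full=True)

    kon1, kon2, koff1, koff2 = 10.0 ** best.x[:4]
    a = float(best.x[4])
    # canonical phase order: phase 1 carries the smaller (strong) KD
    if pairing == "crossed":
        kd1, kd2 = koff2 / kon1, koff1 / kon2
    else:
        kd1, kd2 = koff1 / kon1, koff2 / kon2
    if kd1 > kd2:
        kon1, kon2 = kon2, kon1
        koff1, koff2 = koff2, koff1
        bmax = bmax[::-1].copy()
        a = 1.0 - a

    params = TwoPhaseKineticParams(
        k_on1=kon1, k_on2=kon2, k_off1=koff1, k_off2=koff2,
        B_max1=float(bmax[0]), B_max2=float(bmax[1]), a=a,
        R_0=r0s, t_0=curves[0][0].t_0,
    )
    kd_strong, kd_weak = compute_kd(params, pairing)

    # covariance-based errors in the full (rates, amplitudes, a, R0_j) space
    theta_full = np.concatenate(
        [[kon1, kon2, koff1, koff2, bmax[0], bmax[1], a], r0s]
    )
    n_pts = res.size
    dof = max(n_pts - theta_full.size, 1)
    sigma2 = float(res @ res) / dof
    names = ["k_on1", "k_on2", "k_off1", "k_off2", "B_max1", "B_max2", "a"]
    try:
        J, _ = _full_model_jacobian(theta_full, curves, pairing)
        cov = sigma2 * np.linalg.pinv(J.T @ J)
        errs = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        param_errors = dict(zip(names, errs[:7]))
    except Exception:
        param_errors = {k: float("nan") for k in names}

    return KineticFitResult(
        params=params,
        kd_strong=kd_strong,
        kd_weak=kd_weak,
        param_errors=param_errors,
        residual_rms=float(np.sqrt(np.mean(res**2))),
        excluded_concentrations=list(excluded),
        converged=bool(converged),
        pairing=pairing,
        r0_per_curve={
            (sg.curve_id or f"c={sg.concentration:g}"): float(r0)
            for (sg, _), r0 in zip(curves, r0s)
        },
        cost=float(best.cost),
    )
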