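"""Calibration and nonlinear fitting of scrambling-assay traces.

The workflow mirrors the experimental design: protein-free liposome traces
calibrate the dithionite reduction rate ``gamma``, the protected inner-leaflet
fraction ``li_pf`` and the slow leak rate; proteoliposome traces are then fit
to the closed-form assay model with ``f0``, ``alpha`` and ``beta`` free and
the calibrated values held fixed.  A batch-level quality-control rule discards
whole experiment batches whose side-by-side control fits deviate from the
historical control mean by more than three standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import optimize, stats

from .kinetics import (
    DegenerateModelError,
    FluorescenceTrace,
    ScramblingParams,
    closed_form_fluorescence,
    protein_free_fluorescence,
)

__all__ = [
    "InsufficientBaselineError",
    "CalibrationError",
    "FitError",
    "ProteinFreeCalibration",
    "ScramblingFit",
    "BatchQC",
    "normalize_trace",
    "calibrate_protein_free",
    "fit_scrambling",
    "qc_batch",
    "DEFAULT_MULTISTART",
]


class InsufficientBaselineError(ValueError):
    """Too few or degenerate pre-addition samples for normalisation."""


class CalibrationError(RuntimeError):
    """Protein-free calibration failed or is unidentifiable."""


class FitError(RuntimeError):
    """No multi-start attempt of the scrambling fit converged."""


# deterministic multi-start grid for the scrambling fit: the model is
# multi-modal when alpha/beta are poorly identified
DEFAULT_MULTISTART: tuple[tuple[float, float, float], ...] = tuple(
    (a, b, f0)
    for a in (1e-3, 1e-2, 1e-1)
    for b in (1e-3, 1e-2, 1e-1)
    for f0 in (0.1, 0.3, 0.5)
)


def normalize_trace(trace: FluorescenceTrace, min_baseline_samples: int = 10) -> FluorescenceTrace:
    """Divide a trace by its mean pre-addition fluorescence.

    Returns a new trace with the ``normalized`` flag set; the pre-addition
    mean of the output is exactly 1.

    Raises
    ------
    InsufficientBaselineError
        Fewer than ``min_baseline_samples`` pre-addition samples, or a
        baseline mean that is zero/non-positive (nothing to normalise by).
    """
    pre = trace.fluorescence[trace.pre_mask]
    if pre.size < min_baseline_samples:
        raise InsufficientBaselineError(
            f"need >= {min_baseline_samples} pre-addition samples, got {pre.size}"
        )
    baseline = float(np.mean(pre))
    if not np.isfinite(baseline) or baseline <= 0:
        raise InsufficientBaselineError(f"degenerate baseline mean {baseline}")
    return FluorescenceTrace(
        time=trace.time.copy(),
        fluorescence=trace.fluorescence / baseline,
        dithionite_time=trace.dithionite_time,
        normalized=True,
        meta=dict(trace.meta),
    )


@dataclass
class ProteinFreeCalibration:
    """Pooled protein-free calibration: li_pf, gamma and the leak rate.

    ``*_se`` are standard errors (across-trace scatter when several traces
    are pooled, per-fit curvature otherwise).  ``gamma_identifiable`` is
    False when the fitted protected fraction is so close to 1 that the fast
    bleaching phase carries no information on gamma.
    """

    li_pf: float
    gamma: float
    leak: float
    li_pf_se: float
    gamma_se: float
    leak_se: float
    n_traces: int
    gamma_identifiable: bool = True
    per_trace: list[dict] = field(default_factory=list)

    def leak_confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the leak rate at the given level."""
        dof = max(self.n_traces - 1, 1)
        tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
        return (self.leak - tcrit * self.leak_se, self.leak + tcrit * self.leak_se)


def _fit_single_protein_free(
    t: np.ndarray, f: np.ndarray, fast_window_frac: float, leak_window_frac: float
) -> dict:
    n = t.size
    if n < 20:
        raise CalibrationError("trace too short for protein-free calibration")

    # fast window: early samples dominated by outer-leaflet bleaching
    n_fast = max(int(round(n * fast_window_frac)), 10)
    tf, ff = t[:n_fast], f[:n_fast]

    def model(tt, li, g):
        return protein_free_fluorescence(li, g, 0.0, tt)

    try:
        popt, pcov = optimize.curve_fit(
            model,
            tf,
            ff,
            p0=(0.5, 0.05),
            bounds=([0.0, 0.0], [1.0, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise CalibrationError(f"protein-free fit did not converge: {exc}") from exc
    li_hat, g_hat = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))

    # gamma is unidentifiable when essentially no label is exposed
    identifiable = li_hat < 1.0 - 1e-3

    # leak: ordinary linear regression of fluorescence on time over the late
    # plateau; the fractional rate is -slope / plateau level.  The fitted
    # fast bleaching component is subtracted first so that its tail does not
    # masquerade as leak.
    n_leak = max(int(round(n * leak_window_frac)), 10)
    fast_tail = (1.0 - li_hat) * np.exp(-g_hat * t)
    tl, fl = t[-n_leak:], (f - fast_tail)[-n_leak:]
    if tl[-1] - tl[0] <= 0:
        raise CalibrationError("leak window too short")
    res = stats.linregress(tl, fl)
    plateau = float(np.mean(fl))
    if plateau <= 0:
        raise CalibrationError("non-positive plateau level in leak window")
    leak_hat = max(-res.slope / plateau, 0.0)
    leak_se = res.stderr / plateau

    return {
        "li_pf": float(li_hat),
        "gamma": float(g_hat),
        "leak": float(leak_hat),
        "li_pf_se": float(perr[0]),
        "gamma_se": float(perr[1]),
        "leak_se": float(leak_se),
        "gamma_identifiable": bool(identifiable),
    }


def calibrate_protein_free(
    traces: list[FluorescenceTrace],
    fast_window_frac: float = 0.5,
    leak_window_frac: float = 0.5,
) -> ProteinFreeCalibration:
    """Estimate (li_pf, gamma, leak) from protein-free liposome traces.

    Each normalised trace is fit in two stages: the protected fraction and
    the dithionite reduction rate by least squares over the early
    ``fast_window_frac`` of post-addition samples, and the leak rate by
    ordinary linear regression of fluorescence on time over the late
    ``leak_window_frac`` (the slope divided by the plateau level gives the
    fractional loss rate).  Estimates are pooled as the across-trace mean.
    """
    if not traces:
        raise CalibrationError("no protein-free traces supplied")
    fits = []
    for tr in traces:
        if not tr.normalized:
            tr = normalize_trace(tr)
        fits.append(
            _fit_single_protein_free(
                tr.post_time, tr.post_fluorescence, fast_window_frac, leak_window_frac
            )
        )

    def pool(key: str) -> tuple[float, float]:
        vals = np.array([f[key] for f in fits])
        if len(vals) > 1:
            return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))
        return float(vals[0]), float(fits[0][key + "_se"])

    li, li_se = pool("li_pf")
    g, g_se = pool("gamma")
    leak, leak_se = pool("leak")
    identifiable = all(f["gamma_identifiable"] for f in fits)
    if not identifiable:
        warnings.warn(
            "protected fraction ~1: gamma is unidentifiable from these traces",
            stacklevel=2,
        )
    return ProteinFreeCalibration(
        li_pf=li,
        gamma=g,
        leak=leak,
        li_pf_se=li_se,
        gamma_se=g_se,
        leak_se=leak_se,
        n_traces=len(fits),
        gamma_identifiable=identifiable,
        per_trace=fits,
    )


@dataclass
class ScramblingFit:
    """Result of fitting one proteoliposome trace to the assay model.

    ``estimates`` carries the fitted free parameters (f0, alpha, beta) along
    with the fixed calibration values (gamma, li_pf).  ``at_bounds`` lists
    free parameters pinned at a box constraint, where the curvature-based
    standard errors are unreliable.
    """

    estimates: ScramblingParams
    standard_errors: dict[str, float]
    residual_norm: float
    converged: bool
    n_points: int
    at_bounds: list[str] = field(default_factory=list)
    n_starts_converged: int = 0


def fit_scrambling(
    trace: FluorescenceTrace,
    li_pf: float,
    gamma: float,
    starts: tuple[tuple[float, float, float], ...] = DEFAULT_MULTISTART,
) -> ScramblingFit:
    """Least-squares fit of the closed-form assay model to one trace.

    Free parameters: ``f0`` in [0, 1] and ``alpha``, ``beta`` >= 0; ``li_pf``
    and ``gamma`` are fixed at their protein-free calibration values.  The
    objective is unweighted.  Because the model surface is multi-modal in
    poorly identified regimes the optimisation is restarted from a
    deterministic coarse grid of initial guesses; the converged start with
    the lowest residual sum of squares wins (ties: first found).
    """
    if not trace.normalized:
        trace = normalize_trace(trace)
    t = trace.post_time
    y = trace.post_fluorescence
    if t.size < 10:
        raise FitError("too few post-addition samples to fit")

    def residual(pars):
        p = ScramblingParams(
            alpha=pars["alpha"].value,
            beta=pars["beta"].value,
            gamma=gamma,
            f0=pars["f0"].value,
            li_pf=li_pf,
        )
        try:
            return closed_form_fluorescence(p, t) - y
        except DegenerateModelError:
            return np.full_like(y, 1e6)

    best = None
    n_ok = 0
    for a0, b0, f00 in starts:
        pars = lmfit.Parameters()
        pars.add("alpha", value=a0, min=0.0)
        pars.add("beta", value=b0, min=0.0)
        pars.add("f0", value=f00, min=0.0, max=1.0)
        try:
            res = lmfit.minimize(residual, pars, method="least_squares")
        except Exception:
            continue
        if not res.success or not np.isfinite(res.chisqr):
            continue
        n_ok += 1
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("no multi-start attempt converged")

    ses = {}
    at_bounds = []
    for name in ("alpha", "beta", "f0"):
        par = best.params[name]
        ses[name] = float(par.stderr) if par.stderr is not None else float("nan")
        lo, hi = par.min, par.max
        v = par.value
        if (np.isfinite(lo) and abs(v - lo) < 1e-9) or (
            np.isfinite(hi) and abs(v - hi) < 1e-9
        ):
            at_bounds.append(name)

    est = ScramblingParams(
        alpha=best.params["alpha"].value,
        beta=best.params["beta"].value,
        gamma=gamma,
        f0=best.params["f0"].value,
        li_pf=li_pf,
    )
    return ScramblingFit(
        estimates=est,
        standard_errors=ses,
        residual_norm=float(best.chisqr),
        converged=True,
        n_points=int(t.size),
        at_bounds=at_bounds,
        n_starts_converged=n_ok,
    )


@dataclass
class BatchQC:
    """Decision record of the control-based batch quality-control rule.

    A batch is discarded when any monitored control parameter deviates from
    the historical control mean by strictly more than three reference
    standard deviations; a deviation of exactly 3 SD is kept.
    """

    reference_mean: dict[str, float]
    reference_sd: dict[str, float]
    control_params: dict[str, dict[str, float]]
    decision: dict[str, str] = field(default_factory=dict)

    @property
    def kept_batches(self) -> list[str]:
        return sorted(b for b, d in self.decision.items() if d == "keep")

    @property
    def discarded_batches(self) -> list[str]:
        return sorted(b for b, d in self.decision.items() if d == "discard")


def qc_batch(
    control_params: dict[str, dict[str, float]],
    reference_mean: dict[str, float],
    reference_sd: dict[str, float],
    n_reference: int | None = None,
    threshold: float = 3.0,
) -> BatchQC:
    """Apply the 3-SD control rule to per-batch control fit parameters.

    Parameters
    ----------
    control_params:
        Mapping batch id -> {parameter name -> fitted control value}.
    reference_mean, reference_sd:
        Historical statistics of the control parameters; every parameter
        present in a batch's controls must have a reference entry.
    n_reference:
        Number of historical controls behind the reference statistics; at
        least 2 are required for the SD to be meaningful.
    threshold:
        Number of reference SDs beyond which a batch is discarded
        (strictly greater than; the boundary itself is kept).
    """
    if n_reference is not None and n_reference < 2:
        raise ValueError("reference statistics require >= 2 historical controls")
    decision = {}
    for batch_id, params in control_params.items():
        verdict = "keep"
        for name, value in params.items():
            if name not in reference_mean or name not in reference_sd:
                raise KeyError(f"missing reference statistics for parameter {name!r}")
            sd = reference_sd[name]
            if sd < 0:
                raise ValueError(f"negative reference SD for {name!r}")
            if abs(value - reference_mean[name]) > threshold * sd:
                verdict = "discard"
                break
        decision[batch_id] = verdict
    return BatchQC(
        reference_mean=dict(reference_mean),
        reference_sd=dict(reference_sd),
        control_params={b: dict(p) for b, p in control_params.items()},
        decision=decision,
    )
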