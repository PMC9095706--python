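"""Synthetic data generators for the scrambling assay and AFM mechanics.

Emulates the assay design used throughout: a ~100 s pre-dithionite baseline,
a dithionite step, 3 Hz sampling for a total of ~500 s, a scramblase-free
liposome subpopulation, a slow dithionite leak in protein-free vesicles, and
additive Gaussian measurement noise.  Noiseless outputs coincide exactly with
the corresponding model operations, so the generators double as round-trip
oracles for the fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import FluorescenceTrace, ScramblingParams, ode_fluorescence
from .mechanics import ForceCurve, young_modulus_force

__all__ = [
    "AssayDesign",
    "simulate_trace",
    "simulate_thickness_series",
    "simulate_force_curves",
]


@dataclass(frozen=True)
class AssayDesign:
    """Acquisition design of a dithionite scrambling assay.

    Defaults follow the standard protocol: dithionite added after a 100 s
    baseline, 3 Hz sampling, 500 s total recording, additive Gaussian noise
    with SD equal to 1% of the baseline signal.
    """

    baseline_duration: float = 100.0
    total_duration: float = 500.0
    sampling_rate: float = 3.0
    noise_sd: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not 0 < self.baseline_duration < self.total_duration:
            raise ValueError("need 0 < baseline_duration < total_duration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.total_duration, 1.0 / self.sampling_rate)


def simulate_trace(
    params: ScramblingParams,
    design: AssayDesign = AssayDesign(),
    seed: int | None = None,
    baseline_level: float = 1.0,
) -> FluorescenceTrace:
    """Simulate one assay trace: flat baseline, dithionite step, decay.

    Before dithionite addition the signal sits at ``baseline_level``; after
    addition it follows the numerical-ODE assay model, with the slow leak
    acting on the protected pool of the protein-free subpopulation.  I.i.d.
    additive Gaussian noise (SD ``design.noise_sd`` as a fraction of the
    baseline) is applied to every sample.  Bit-reproducible for a fixed seed.
    """
    t = design.time_grid
    f = np.full(t.shape, float(baseline_level))
    post = t >= design.baseline_duration
    f[post] = baseline_level * ode_fluorescence(params, t[post] - design.baseline_duration)
    rng = np.random.default_rng(seed if seed is not None else design.seed)
    if design.noise_sd > 0:
        f = f + rng.normal(0.0, design.noise_sd * baseline_level, size=f.shape)
    return FluorescenceTrace(
        time=t,
        fluorescence=f,
        dithionite_time=design.baseline_duration,
        normalized=False,
        meta={"true_params": params, "noise_sd": design.noise_sd},
    )


def simulate_thickness_series(
    alpha0: float,
    slope: float,
    thicknesses: np.ndarray,
    replicates: int = 3,
    design: AssayDesign = AssayDesign(),
    h_ref: float = 3.4,
    gamma: float = 0.02,
    f0: float = 0.3,
    li_pf: float = 0.5,
    beta_ratio: float = 1.0,
    seed: int | None = None,
) -> tuple[list[FluorescenceTrace], pd.DataFrame]:
    """Simulate traces whose scrambling rate decays exponentially with
    membrane thickness.

    Ground truth: alpha(h) = alpha0 * exp(-slope * (h - h_ref)), with the
    backward rate beta = beta_ratio * alpha (equal by default, as the forward
    and reverse constants track each other across compositions).  ``h_ref``
    defaults to 3.4 nm, the thickness of the C18 reference composition.

    Returns the trace list (each trace's ``meta`` carries its thickness and
    replicate index) and a truth table with one row per condition.
    """
    thicknesses = np.asarray(thicknesses, dtype=float)
    if np.any((thicknesses < 3.0) | (thicknesses > 4.2)):
        raise ValueError("thicknesses must lie in the 3.0-4.2 nm bilayer range")
    base_seed = seed if seed is not None else design.seed
    ss = np.random.SeedSequence(base_seed)
    child_seeds = iter(ss.generate_state(thicknesses.size * replicates))

    traces: list[FluorescenceTrace] = []
    rows = []
    for h in thicknesses:
        alpha = alpha0 * np.exp(-slope * (h - h_ref))
        beta = beta_ratio * alpha
        params = ScramblingParams(alpha=alpha, beta=beta, gamma=gamma, f0=f0, li_pf=li_pf)
        rows.append({"thickness_nm": h, "alpha": alpha, "beta": beta})
        for rep in range(replicates):
            tr = simulate_trace(params, design, seed=int(next(child_seeds)) % (2**31))
            tr.meta.update({"thickness_nm": float(h), "replicate": rep})
            traces.append(tr)
    return traces, pd.DataFrame(rows)


def simulate_force_curves(
    E_true: float,
    tip_half_angle: float,
    nu: float = 0.5,
    max_indentation: float = 20e-9,
    noise_sd: float = 0.0,
    n_curves: int = 1,
    n_points: int = 100,
    seed: int | None = None,
) -> list[ForceCurve]:
    """Simulate AFM force-indentation curves for a pyramidal tip.

    The force follows the quadratic contact model
    F = E/(1-nu^2) * (2 tan(alpha)/pi) * delta^2, with additive Gaussian
    noise of SD ``noise_sd`` (in newtons) on the force channel.
    """
    if E_true <= 0:
        raise ValueError("E_true must be > 0")
    if not 0.0 <= nu < 1.0:
        raise ValueError("nu must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    delta = np.linspace(0.0, max_indentation, n_points)
    curves = []
    for _ in range(n_curves):
        force = young_modulus_force(E_true, delta, tip_half_angle, nu)
        if noise_sd > 0:
            force = force + rng.normal(0.0, noise_sd, size=force.shape)
        curves.append(
            ForceCurve(indentation=delta.copy(), force=force, tip_half_angle=tip_half_angle, nu=nu)
        )
    return curves
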