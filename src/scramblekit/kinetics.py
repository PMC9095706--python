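"""Kinetics of the dithionite lipid-scrambling assay.

The assay tracks the fluorescence of NBD-labelled lipids in liposomes after
addition of sodium dithionite, a membrane-impermeant reductant that
irreversibly bleaches NBD groups exposed on the outer leaflet.  In vesicles
carrying an active scramblase, inner-leaflet lipids flip to the outer leaflet
(rate constant ``alpha``), can flip back (``beta``) and are bleached once
outside (``gamma``), so the fluorescence decays towards zero.  A fraction
``f0`` of the vesicle population carries no active scramblase; there only
the outer-leaflet label (fraction ``1 - Li_PF`` of the total) is bleached,
and the protected inner pool decays, at most, at a very slow ``leak`` rate
attributed to dithionite permeation or spontaneous flip-flop.

Two interchangeable forward models are provided:

* :func:`closed_form_fluorescence` — the biexponential eigen-expansion of the
  two-compartment scrambling/bleaching scheme, as used for fitting;
* :func:`ode_fluorescence` — direct numerical integration of the underlying
  rate equations, serving as an independent oracle and as the fallback for
  parameter sets where the closed form is degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "InvalidParameterError",
    "DegenerateModelError",
    "ScramblingParams",
    "Eigensystem",
    "FluorescenceTrace",
    "eigensystem",
    "closed_form_fluorescence",
    "ode_fluorescence",
    "protein_free_fluorescence",
]


class InvalidParameterError(ValueError):
    """A kinetic parameter violates its physical constraint."""


class DegenerateModelError(ValueError):
    """The closed-form expression is singular for these parameters."""


@dataclass(frozen=True)
class ScramblingParams:
    """Rate constants and population fractions of the scrambling assay model.

    Parameters
    ----------
    alpha, beta:
        Forward (inner→outer) and backward (outer→inner) scrambling rate
        constants, in s⁻¹.
    gamma:
        Rate constant of dithionite reduction of outer-leaflet NBD lipids,
        in s⁻¹.
    f0:
        Fraction of liposomes without an active scramblase (0–1).
    li_pf:
        Fraction of NBD label residing in the inner (protected) leaflet of
        protein-free liposomes (0–1); 0.5 for symmetric labelling.
    leak:
        Slow fluorescence-loss rate constant of the protected pool in
        protein-free vesicles, in s⁻¹.  Not part of the closed-form fit
        model, where it is treated as negligible.
    """

    alpha: float
    beta: float
    gamma: float
    f0: float = 0.0
    li_pf: float = 0.5
    leak: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "leak"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")
        for name in ("f0", "li_pf"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")

    def replace(self, **changes) -> "ScramblingParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class Eigensystem:
    """Eigenvalues of the scrambling/bleaching rate matrix and the
    denominator of the closed-form solution.

    ``lambda1`` is the slow (less negative) and ``lambda2`` the fast (more
    negative) eigenvalue; both are <= 0 for non-negative rates.
    """

    lambda1: float
    lambda2: float
    D: float


def eigensystem(params: ScramblingParams) -> Eigensystem:
    """Eigenvalues λ₁ ≥ λ₂ of the 2×2 rate matrix ``[[-α, β], [α, -(β+γ)]]``.

    The characteristic polynomial gives

        λ = -[(α+β+γ) ∓ √((α+β+γ)² − 4αγ)] / 2

    with the discriminant provably non-negative for non-negative rates,
    since (α+β+γ)² − 4αγ = (α−γ)² + β² + 2β(α+γ).  ``D`` is the
    normalisation denominator (λ₁+α)(λ₂+β+γ) − αβ of the closed-form
    fluorescence expression.
    """
    a, b, g = params.alpha, params.beta, params.gamma
    s = a + b + g
    disc = s * s - 4.0 * a * g
    # algebraically >= 0; clip tiny negative round-off
    root = math.sqrt(max(disc, 0.0))
    lam1 = -(s - root) / 2.0
    lam2 = -(s + root) / 2.0
    D = (lam1 + a) * (lam2 + b + g) - a * b
    return Eigensystem(lambda1=lam1, lambda2=lam2, D=D)


def protein_free_fluorescence(
    li_pf: float, gamma: float, leak: float, t: np.ndarray
) -> np.ndarray:
    """Fluorescence of protein-free liposomes after dithionite addition.

    The outer-leaflet pool ``1 - li_pf`` is bleached at rate ``gamma``; the
    protected inner pool decays at the slow ``leak`` rate:

        F(t) = li_pf · e^(−leak·t) + (1 − li_pf) · e^(−γ·t)

    With zero leak the trace plateaus at ``li_pf`` — the familiar ~50%
    fluorescence loss of symmetrically labelled protein-free vesicles.
    """
    if not 0.0 <= li_pf <= 1.0:
        raise InvalidParameterError(f"li_pf must lie in [0, 1], got {li_pf}")
    if gamma < 0 or leak < 0:
        raise InvalidParameterError("gamma and leak must be >= 0")
    t = np.asarray(t, dtype=float)
    return li_pf * np.exp(-leak * t) + (1.0 - li_pf) * np.exp(-gamma * t)


def closed_form_fluorescence(params: ScramblingParams, t: np.ndarray) -> np.ndarray:
    """Total fluorescence F_tot(t) of the assay, in closed form.

    Measured from the moment of dithionite addition (t = 0), with the trace
    normalised to the pre-addition level:

        F_tot(t) = f₀·(Liᴾᶠ + (1−Liᴾᶠ)·e^(−γt))
                 + (1−f₀)/(D·(α+β)) · { α(λ₂+γ)(λ₁+α+β)·e^(λ₁t)
                                        + λ₁β(λ₂+α+β+γ)·e^(λ₂t) }

    The scramblase-containing pool starts from the pre-addition scrambling
    steady state (inner fraction β/(α+β)); F_tot(0) = 1.  The slow leak of
    protein-free vesicles is negligible on the scrambling timescale and is
    not part of this expression.

    Raises
    ------
    DegenerateModelError
        When α+β = 0 or D = 0, where the printed form divides by zero.
        Use :func:`ode_fluorescence` for those limits.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be measured from dithionite addition (>= 0)")
    a, b, g = params.alpha, params.beta, params.gamma
    pf = params.li_pf + (1.0 - params.li_pf) * np.exp(-g * t)
    if params.f0 == 1.0:
        # the proteoliposome term carries zero weight; no need to evaluate
        # the (possibly singular) bracket
        return pf
    eig = eigensystem(params)
    lam1, lam2, D = eig.lambda1, eig.lambda2, eig.D
    ab = a + b
    if ab == 0.0 or D == 0.0:
        raise DegenerateModelError(
            "closed form is singular (alpha+beta=0 or D=0); use ode_fluorescence"
        )
    bracket = a * (lam2 + g) * (lam1 + ab) * np.exp(lam1 * t) + lam1 * b * (
        lam2 + ab + g
    ) * np.exp(lam2 * t)
    return params.f0 * pf + (1.0 - params.f0) * bracket / (D * ab)


def ode_fluorescence(
    params: ScramblingParams,
    t: np.ndarray,
    initial_distribution: tuple[float, float] | None = None,
    rtol: float = 1e-13,
    atol: float = 1e-14,
) -> np.ndarray:
    """F_tot(t) by numerical integration of the two-compartment scheme.

    Integrates, for the scramblase-containing pool,

        dLi/dt = −α·Li + β·Lo
        dLo/dt =  α·Li − (β+γ)·Lo

    from the pre-addition steady state Li(0) = β/(α+β), Lo(0) = α/(α+β)
    (symmetric 1/2–1/2 when α+β = 0, i.e. no scrambling), and adds the
    protein-free pool ``f0·(li_pf·e^(−leak·t) + (1−li_pf)·e^(−γt))``.
    Unlike the closed form this path handles every valid parameter set and
    includes the slow leak of protein-free vesicles.

    Parameters
    ----------
    initial_distribution:
        Optional (inner, outer) fractions for the scramblase pool,
        overriding the steady-state default.  Must sum to 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise InvalidParameterError("t must be finite and >= 0")
    a, b, g = params.alpha, params.beta, params.gamma

    if initial_distribution is None:
        if a + b > 0:
            y0 = (b / (a + b), a / (a + b))
        else:
            y0 = (0.5, 0.5)
    else:
        y0 = tuple(float(x) for x in initial_distribution)
        if not math.isclose(sum(y0), 1.0, rel_tol=0, abs_tol=1e-9):
            raise InvalidParameterError("initial_distribution must sum to 1")

    def rhs(_t, y):
        li, lo = y
        return [-a * li + b * lo, a * li - (b + g) * lo]

    t_end = float(t[-1]) if t.size else 0.0
    if t_end > 0:
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            y0,
            method="DOP853",
            t_eval=t,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        proteo = sol.y[0] + sol.y[1]
    else:
        proteo = np.full(t.shape, y0[0] + y0[1])

    pf = protein_free_fluorescence(params.li_pf, g, params.leak, t)
    return params.f0 * pf + (1.0 - params.f0) * proteo


@dataclass
class FluorescenceTrace:
    """A sampled fluorescence time course from a scrambling assay.

    Attributes
    ----------
    time:
        Strictly increasing sample times, in seconds.
    fluorescence:
        Signal, in arbitrary units, or as a fraction of the pre-addition
        baseline when ``normalized`` is True.
    dithionite_time:
        Time of dithionite addition, within the sampled range.
    normalized:
        Whether the trace has been divided by its pre-addition mean.
    meta:
        Free-form metadata (condition labels, batch id, ...).
    """

    time: np.ndarray
    fluorescence: np.ndarray
    dithionite_time: float
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must be 1-D arrays of equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.time.size and not (
            self.time[0] <= self.dithionite_time <= self.time[-1]
        ):
            raise ValueError("dithionite_time must lie within the sampled range")

    @property
    def pre_mask(self) -> np.ndarray:
        """Samples recorded before dithionite addition."""
        return self.time < self.dithionite_time

    @property
    def post_mask(self) -> np.ndarray:
        return ~self.pre_mask

    @property
    def post_time(self) -> np.ndarray:
        """Post-addition sample times, measured from dithionite addition."""
        return self.time[self.post_mask] - self.dithionite_time

    @property
    def post_fluorescence(self) -> np.ndarray:
        return self.fluorescence[self.post_mask]
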