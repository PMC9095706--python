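"""Electrostatic energy barrier for lipid scrambling and the
thickness-rate analysis.

A lipid headgroup crossing the hydrocarbon core of a bilayer can be modelled
as a charged sphere (charge q, radius r) transferred from water (dielectric
constant eps_w) into a low-dielectric slab (eps_m) of finite thickness L.
The Born self-energy of the sphere in the slab, corrected for the finite
slab thickness, gives the barrier

    dG = q^2 / (2 eps_m r)  -  (q^2 / (eps_m L)) * ln(2 eps_w / (eps_m + eps_w))

written in the Gaussian (CGS) convention, i.e. without a 4*pi*eps_0 factor.
With q in elementary charges, lengths in angstroms and dielectric constants
dimensionless the result is in units of e^2/angstrom;
:data:`E2_PER_ANGSTROM_IN_KCAL_MOL` converts to kcal/mol.

Because ln(2 eps_w/(eps_m+eps_w)) > 0 whenever eps_w > eps_m, the barrier
increases monotonically with slab thickness — thinning the membrane lowers
the cost of moving the headgroup across.  An Arrhenius mapping turns the
barrier into a rate, predicting an exponential decrease of the scrambling
rate with membrane thickness, which is what the regression helpers quantify
on measured (thickness, rate) tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "E2_PER_ANGSTROM_IN_KCAL_MOL",
    "BornBarrierParams",
    "ThicknessRatePoint",
    "ThicknessRegression",
    "born_barrier",
    "rate_from_barrier",
    "fit_log_rate_vs_thickness",
]

# e^2 / (4 pi eps0 * 1 angstrom) expressed in kcal/mol: the Coulomb energy of
# two elementary charges 1 A apart in vacuum
E2_PER_ANGSTROM_IN_KCAL_MOL = 332.0637


@dataclass(frozen=True)
class BornBarrierParams:
    """Parameters of the finite-slab Born barrier.

    q in elementary charges, r and L in angstroms, dielectric constants
    dimensionless.  The defaults (q=1, r=4.5 A, eps_m=2, eps_w=80) are
    conventional order-of-magnitude values for a charged phospholipid
    headgroup in a hydrocarbon slab, intended for illustrative curves.
    """

    q: float = 1.0
    r: float = 4.5
    eps_m: float = 2.0
    eps_w: float = 80.0
    L: float = 34.0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.L <= 0:
            raise ValueError("r and L must be > 0")
        if not self.eps_w >= self.eps_m > 0:
            raise ValueError("need eps_w >= eps_m > 0")


def born_barrier(p: BornBarrierParams) -> float:
    """Scrambling energy barrier of a charged headgroup in a finite slab.

    Returns q^2/(2 eps_m r) - (q^2/(eps_m L)) * ln(2 eps_w/(eps_m + eps_w)),
    in e^2/angstrom for the documented unit convention (multiply by
    :data:`E2_PER_ANGSTROM_IN_KCAL_MOL` for kcal/mol).  The first term is the
    bulk Born self-energy difference; the finite-thickness correction
    vanishes as L -> inf and for dielectric-matched media (eps_m = eps_w).
    """
    q2 = p.q * p.q
    return q2 / (2.0 * p.eps_m * p.r) - (q2 / (p.eps_m * p.L)) * np.log(
        2.0 * p.eps_w / (p.eps_m + p.eps_w)
    )


def rate_from_barrier(barrier: float, prefactor: float, kT: float) -> float:
    """Arrhenius rate: prefactor * exp(-barrier / kT).

    ``barrier`` and ``kT`` must share units (e.g. both kcal/mol)."""
    if kT <= 0:
        raise ValueError("kT must be > 0")
    return prefactor * np.exp(-np.asarray(barrier, dtype=float) / kT)


@dataclass(frozen=True)
class ThicknessRatePoint:
    """One (composition, thickness, rates) measurement.

    ``calcium`` labels the condition (e.g. "0" or "saturating")."""

    composition: str
    thickness: float
    alpha: float
    beta: float
    calcium: str = "0"

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class ThicknessRegression:
    """OLS summary of ln(rate) against membrane thickness.

    ``slope`` is per nm (negative for rates that fall with thickness);
    ``fold_changes`` is the pairwise rate-ratio matrix between labelled
    conditions (row / column).
    """

    slope: float
    intercept: float
    slope_se: float
    slope_ci: tuple[float, float]
    r_squared: float
    n_points: int
    fold_changes: pd.DataFrame
    regressor: str = "thickness"


def fit_log_rate_vs_thickness(
    points: list[ThicknessRatePoint],
    rate: str = "alpha",
    regressor: str = "thickness",
    ci_level: float = 0.95,
) -> ThicknessRegression:
    """Ordinary linear regression of ln(rate) on membrane thickness.

    ``regressor='thickness'`` fits ln k = a + b*h (rate ~ e^(-c h), the
    default reading of an exponential inverse dependence on thickness);
    ``'inverse'`` fits ln k = a + b/h instead, the form suggested by the
    1/L term of the slab barrier.  Points with non-positive rates are
    excluded with a warning.  Pairwise fold changes (rate ratios) between
    the labelled compositions are computed from condition means.
    """
    if rate not in ("alpha", "beta"):
        raise ValueError("rate must be 'alpha' or 'beta'")
    if regressor not in ("thickness", "inverse"):
        raise ValueError("regressor must be 'thickness' or 'inverse'")
    rows = [(p.composition, p.thickness, getattr(p, rate)) for p in points]
    kept = [r for r in rows if r[2] > 0]
    if len(kept) < len(rows):
        import warnings

        warnings.warn(
            f"excluded {len(rows) - len(kept)} points with non-positive rates",
            stacklevel=2,
        )
    if len(kept) < 3:
        raise ValueError("need >= 3 points with positive rates")

    comp = np.array([r[0] for r in kept])
    h = np.array([r[1] for r in kept])
    k = np.array([r[2] for r in kept])
    x = h if regressor == "thickness" else 1.0 / h
    X = sm.add_constant(x)
    y = np.log(k)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=1.0 - ci_level)[1]
    # r^2 is indeterminate for a constant response (zero total variance)
    rsq = float(fit.rsquared) if np.var(y) > 0 else 1.0

    means = pd.Series(k).groupby(comp).mean()
    fold = pd.DataFrame(
        np.divide.outer(means.to_numpy(), means.to_numpy()),
        index=means.index,
        columns=means.index,
    )
    return ThicknessRegression(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        slope_ci=(float(ci[0]), float(ci[1])),
        r_squared=rsq,
        n_points=len(kept),
        fold_changes=fold,
        regressor=regressor,
    )
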