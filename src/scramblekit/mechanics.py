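"""AFM-derived membrane mechanics.

Young's modulus of a supported bilayer from force-indentation curves
acquired with a pyramidal tip, the elastic moduli derived from it, and the
mode/FWHH summary of AFM bilayer-height distributions.

The contact model for a pyramidal indenter of half angle alpha on a thin
elastic film of Poisson's ratio nu is quadratic in the indentation delta:

    F = E / (1 - nu^2) * (2 tan(alpha) / pi) * delta^2

which makes the fit for E linear in the slope of F versus delta^2.  The area
stretch modulus and bending stiffness follow from plate theory:

    k_A = E h / (1 - nu^2),      k_c = E h^3 / (24 (1 - nu^2))

so k_c / k_A = h^2 / 24 identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

__all__ = [
    "ForceCurve",
    "MembraneMechanics",
    "HeightDistribution",
    "MultimodalHeightsWarning",
    "young_modulus_force",
    "fit_young_modulus",
    "area_stretch_modulus",
    "bending_stiffness",
    "fwhh_thickness",
]

# poisson's ratio assumed for lipid bilayers (incompressible limit)
DEFAULT_POISSON_RATIO = 0.5


class MultimodalHeightsWarning(UserWarning):
    """The height distribution has more than one peak above half height."""


@dataclass
class ForceCurve:
    """An AFM force-indentation curve with tip geometry metadata.

    ``indentation`` in metres (non-negative, increasing), ``force`` in
    newtons, ``tip_half_angle`` the half cone / half face angle of the
    pyramidal tip in radians, ``nu`` the Poisson's ratio of the film.
    """

    indentation: np.ndarray
    force: np.ndarray
    tip_half_angle: float
    nu: float = DEFAULT_POISSON_RATIO

    def __post_init__(self) -> None:
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.indentation.shape != self.force.shape or self.indentation.ndim != 1:
            raise ValueError("indentation and force must be 1-D arrays of equal length")
        if np.any(self.indentation < 0) or np.any(np.diff(self.indentation) < 0):
            raise ValueError("indentation must be non-negative and non-decreasing")
        if not 0.0 < self.tip_half_angle < np.pi / 2:
            raise ValueError("tip_half_angle must lie in (0, pi/2) radians")
        if not 0.0 <= self.nu < 1.0:
            raise ValueError("nu must lie in [0, 1)")


@dataclass
class MembraneMechanics:
    """Elastic summary of one membrane: E [Pa], h [m], k_A [N/m], k_c [J]."""

    E: float
    h: float
    kA: float
    kc: float

    @classmethod
    def from_modulus(cls, E: float, h: float, nu: float = DEFAULT_POISSON_RATIO) -> "MembraneMechanics":
        return cls(
            E=E,
            h=h,
            kA=area_stretch_modulus(E, h, nu),
            kc=bending_stiffness(E, h, nu),
        )


def young_modulus_force(
    E: float, indentation: np.ndarray, tip_half_angle: float, nu: float
) -> np.ndarray:
    """Forward contact model: force for a given Young's modulus."""
    delta = np.asarray(indentation, dtype=float)
    return E / (1.0 - nu**2) * (2.0 * np.tan(tip_half_angle) / np.pi) * delta**2


def fit_young_modulus(curve: ForceCurve) -> tuple[float, float]:
    """Young's modulus (and standard error) from one force curve.

    The model is linear in E, so the fit reduces to the through-origin
    regression of force on indentation squared; no iterative optimisation is
    involved.  Returns ``(E, E_se)`` in pascals.
    """
    pos = curve.indentation > 0
    if np.count_nonzero(pos) < 10:
        raise ValueError("need >= 10 points with positive indentation")
    x = curve.indentation[pos] ** 2
    y = curve.force[pos]
    if np.max(np.abs(y)) == 0.0:
        raise ValueError("all-zero force curve")
    sxx = float(np.dot(x, x))
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    slope_se = np.sqrt(float(np.dot(resid, resid)) / dof / sxx)
    geom = (1.0 - curve.nu**2) * np.pi / (2.0 * np.tan(curve.tip_half_angle))
    return slope * geom, slope_se * geom


def _check_elastic_inputs(E: float, h: float, nu: float) -> None:
    if E <= 0 or h <= 0:
        raise ValueError("E and h must be > 0")
    if not 0.0 <= nu < 1.0:
        raise ValueError("nu must lie in [0, 1)")


def area_stretch_modulus(E: float, h: float, nu: float = DEFAULT_POISSON_RATIO) -> float:
    """Area stretch modulus k_A = E h / (1 - nu^2), in N/m for SI inputs."""
    _check_elastic_inputs(E, h, nu)
    return E * h / (1.0 - nu**2)


def bending_stiffness(E: float, h: float, nu: float = DEFAULT_POISSON_RATIO) -> float:
    """Bending stiffness k_c = E h^3 / (24 (1 - nu^2)), in J for SI inputs."""
    _check_elastic_inputs(E, h, nu)
    return E * h**3 / (24.0 * (1.0 - nu**2))


@dataclass
class HeightDistribution:
    """Mode and full width at half height of a bilayer-height sample."""

    heights: np.ndarray
    mode: float
    fwhh: float
    grid: np.ndarray = field(repr=False, default=None)
    density: np.ndarray = field(repr=False, default=None)


def fwhh_thickness(heights: np.ndarray, n_grid: int = 2048) -> HeightDistribution:
    """Peak position and FWHH of a height distribution.

    A Gaussian kernel-density estimate (Silverman bandwidth) is evaluated on
    a fine grid; the mode is the grid maximum and the FWHH is the width of
    the half-maximum crossing interval, with linear interpolation between
    grid points.  For a Gaussian sample the FWHH converges to
    2*sqrt(2 ln 2)*sigma.  Emits :class:`MultimodalHeightsWarning` when a
    secondary peak also rises above half height (e.g. a mica-background
    population next to the membrane peak); the reported mode is then the
    dominant peak.
    """
    heights = np.asarray(heights, dtype=float)
    if heights.size < 100:
        raise ValueError("need >= 100 height samples")
    spread = heights.std(ddof=1)
    if spread <= 1e-9 * max(abs(float(heights.mean())), 1.0):
        raise ValueError("degenerate height sample: all values identical")

    kde = stats.gaussian_kde(heights, bw_method="silverman")
    pad = 4.0 * spread
    grid = np.linspace(heights.min() - pad, heights.max() + pad, n_grid)
    dens = kde(grid)

    imax = int(np.argmax(dens))
    mode = float(grid[imax])
    half = dens[imax] / 2.0

    peaks, _ = signal.find_peaks(dens, height=half)
    if peaks.size > 1:
        warnings.warn(
            f"{peaks.size} density peaks exceed half height; reporting the dominant one",
            MultimodalHeightsWarning,
            stacklevel=2,
        )

    def cross(i_from: int, step: int) -> float:
        i = i_from
        while 0 < i < n_grid - 1 and dens[i] > half:
            i += step
        # interpolate between grid[i] and the previous point
        j = i - step
        if dens[j] == dens[i]:
            return float(grid[i])
        frac = (dens[j] - half) / (dens[j] - dens[i])
        return float(grid[j] + frac * (grid[i] - grid[j]))

    left = cross(imax, -1)
    right = cross(imax, +1)
    return HeightDistribution(
        heights=heights, mode=mode, fwhh=right - left, grid=grid, density=dens
    )
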