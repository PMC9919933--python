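"""UV calibration and phase-solubility analysis for host-guest complexation.

A Beer-Lambert standard curve (absorbance A versus guest concentration C,
both from a dilution series of the pure guest) converts measured absorbances
of guest-saturated host solutions into guest solubilities. Plotting guest
solubility against host concentration gives the phase-solubility isotherm;
a linear isotherm with slope K < 1 (Higuchi-Connors A_L type) indicates 1:1
host-guest complexation, and the 1:1 stability constant follows as

    Ks = K / (S0 * (1 - K))        [M^-1]

with K the dimensionless isotherm slope (both axes molar) and S0 the
intrinsic guest solubility taken from the fitted intercept.

Concentrations are carried in mM throughout and converted to M only inside
:func:`stability_constant`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ClassificationError, DomainError, InvalidInputError

__all__ = [
    "AbsorbanceSeries",
    "CalibrationCurve",
    "PhaseSolubilityIsotherm",
    "fit_calibration",
    "absorbance_to_concentration",
    "build_isotherm",
    "stability_constant",
    "rank_by_ks",
]

MM_TO_M = 1e-3

# r² at or above which a phase-solubility fit is accepted as linear (A_L)
AL_LINEARITY_R2 = 0.95


@dataclass(frozen=True)
class AbsorbanceSeries:
    """A dilution series: concentrations (mM) and absorbances (AU)."""

    concentrations: np.ndarray
    absorbances: np.ndarray
    wavelength: float | None = None  # nm, metadata only
    dilution_factor: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if c.shape != a.shape or c.ndim != 1 or len(c) < 2:
            raise InvalidInputError("need equal-length 1-D arrays with >= 2 points")
        if not np.all(np.diff(c) > 0):
            raise InvalidInputError("concentrations must be strictly increasing")
        if np.any(a < 0):
            raise InvalidInputError("absorbances must be non-negative")
        if self.dilution_factor < 1:
            raise InvalidInputError("dilution_factor must be >= 1")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "absorbances", a)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted Beer-Lambert line A = slope * C + intercept (C in mM)."""

    slope: float  # AU per mM
    intercept: float  # AU
    r_squared: float
    n_points: int

    def __post_init__(self):
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise InvalidInputError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class PhaseSolubilityIsotherm:
    """Guest solubility versus host concentration, with the A_L-model fit."""

    host_concentrations: np.ndarray  # mM
    guest_solubilities: np.ndarray  # mM
    slope_K: float  # dimensionless
    intercept_S0: float  # mM
    r_squared: float
    isotherm_class: str  # "AL" or "nonlinear"

    @property
    def Ks(self) -> float:
        """Stability constant in M^-1 (S0 converted from mM)."""
        return stability_constant(self.slope_K, self.intercept_S0 * MM_TO_M)


def _ols(x: np.ndarray, y: np.ndarray):
    if len(x) < 2 or np.ptp(x) == 0:
        raise InvalidInputError("need >= 2 distinct x values for a line fit")
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2


def fit_calibration(series: AbsorbanceSeries) -> CalibrationCurve:
    """Ordinary-least-squares Beer-Lambert line through a dilution series.

    r_squared is the squared Pearson correlation of the fitted line.
    """
    slope, intercept, r2 = _ols(series.concentrations, series.absorbances)
    return CalibrationCurve(slope=slope, intercept=intercept, r_squared=r2,
                            n_points=len(series.concentrations))


def absorbance_to_concentration(
    curve: CalibrationCurve, absorbance, dilution_factor: float = 1.0
):
    """Invert the calibration: C = d * (A - intercept) / slope, in mM.

    May return negative values for A below the intercept; callers decide
    whether to clip (fits here deliberately retain them).
    """
    if curve.slope <= 0:
        raise DomainError("calibration slope must be positive to invert")
    return dilution_factor * (np.asarray(absorbance, dtype=float) - curve.intercept) / curve.slope


def build_isotherm(
    host_concentrations,
    absorbances,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
) -> PhaseSolubilityIsotherm:
    """Construct and fit a phase-solubility isotherm from raw absorbances.

    Absorbances are converted to guest solubilities through ``curve``; the
    solubility-versus-host line is then fitted by unweighted OLS with both
    axes in mM, so the slope is dimensionless. S0 is the fitted intercept,
    not the measured zero-host point (which stays in the fit). The isotherm
    is classed ``AL`` when the fit is adequately linear (r² >= 0.95) and
    0 < K < 1; a slope outside (0, 1) is not an A_L isotherm and raises.
    """
    host = np.asarray(host_concentrations, dtype=float)
    absorb = np.asarray(absorbances, dtype=float)
    if host.shape != absorb.shape or host.ndim != 1:
        raise InvalidInputError("host concentrations and absorbances must match in length")
    if len(host) < 3:
        raise InvalidInputError("need >= 3 points for a phase-solubility fit")
    if not np.any(host == 0):
        raise InvalidInputError("isotherm must include a zero-host (intrinsic solubility) point")
    solubility = absorbance_to_concentration(curve, absorb, dilution_factor)
    if np.any(solubility < 0):
        warnings.warn(
            "negative computed solubilities retained (not clipped) to keep the fit unbiased",
            stacklevel=2,
        )
    slope, intercept, r2 = _ols(host, solubility)
    if slope <= 0 or slope >= 1:
        raise ClassificationError(
            f"isotherm slope K={slope:.4g} outside (0, 1): not an AL-type isotherm"
        )
    cls = "AL" if r2 >= AL_LINEARITY_R2 else "nonlinear"
    return PhaseSolubilityIsotherm(
        host_concentrations=host,
        guest_solubilities=solubility,
        slope_K=slope,
        intercept_S0=intercept,
        r_squared=r2,
        isotherm_class=cls,
    )


def stability_constant(slope_K: float, intercept_S0: float) -> float:
    """1:1 stability constant Ks = K / (S0 * (1 - K)) in M^-1.

    ``intercept_S0`` must be in mol/L for the returned unit to be M^-1.
    """
    if not 0 < slope_K < 1:
        raise DomainError(f"slope K must lie in (0, 1), got {slope_K}")
    if intercept_S0 <= 0:
        raise DomainError(f"intrinsic solubility S0 must be positive, got {intercept_S0}")
    return slope_K / (intercept_S0 * (1.0 - slope_K))


def rank_by_ks(isotherms: Sequence[tuple[str, PhaseSolubilityIsotherm]]) -> list[str]:
    """Names sorted by descending stability constant; ties keep input order."""
    if not isotherms:
        raise InvalidInputError("need at least one isotherm to rank")
    order = sorted(range(len(isotherms)), key=lambda i: -isotherms[i][1].Ks)
    return [isotherms[i][0] for i in order]
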