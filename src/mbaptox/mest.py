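"""Mouse embryonic stem cell test (mEST) scoring and curve fitting.

The mEST reads out developmental toxicity as inhibition of ES-D3 cell
differentiation into contracting cardiomyocytes: per concentration, 24
embryoid bodies (EBs) are scored beating / not beating.  An assay is
valid only when more than 21 of 24 solvent-control EBs beat.  Cytotoxicity
is read with the WST-1 assay as background-corrected absorbance
(A440 - A620) relative to the solvent control.

Concentration-response curves are fitted with the three-parameter
log-inhibition model (Hill slope fixed at 1):

    R(c) = bottom + (top - bottom) / (1 + c / IC50)

which in log10-concentration reads bottom + (top-bottom)/(1 + 10^(log c -
log IC50)).  A four-parameter variant with a free slope is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, DomainError, NoTransitionError, ParameterValidationError

__all__ = [
    "DifferentiationPlate",
    "ViabilityPlate",
    "InhibitionFit",
    "check_validity",
    "viability_percent",
    "differentiation_percent",
    "fit_inhibition",
    "read_differentiation_table",
]

#: validity threshold: strictly more than 21 of 24 control EBs must beat
_VALIDITY_FRACTION = 21.0 / 24.0


@dataclass
class DifferentiationPlate:
    """Beating-EB counts per concentration plus controls."""

    concentration: np.ndarray  # µM
    beating: np.ndarray  # counts
    total: np.ndarray  # EBs plated (24 per concentration in the assay)
    solvent_control: tuple[int, int]  # (beating, total)
    positive_control: tuple[int, int] | None = None  # 0.5 µM 5-FU

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.beating = np.asarray(self.beating, dtype=int)
        self.total = np.asarray(self.total, dtype=int)
        if not (len(self.concentration) == len(self.beating) == len(self.total)):
            raise DomainError("plate columns must have equal length")
        if (self.total <= 0).any():
            raise DomainError("total EB counts must be > 0")
        if ((self.beating < 0) | (self.beating > self.total)).any():
            raise DomainError("beating counts must be within [0, total]")


@dataclass
class ViabilityPlate:
    """WST-1 absorbances (triplicate wells) per concentration."""

    concentration: np.ndarray  # µM
    A440: np.ndarray  # (n_conc, n_wells)
    A620: np.ndarray
    control_A440: np.ndarray  # solvent-control wells
    control_A620: np.ndarray
    exposure_days: int = 5

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.A440 = np.atleast_2d(np.asarray(self.A440, dtype=float))
        self.A620 = np.atleast_2d(np.asarray(self.A620, dtype=float))
        self.control_A440 = np.asarray(self.control_A440, dtype=float)
        self.control_A620 = np.asarray(self.control_A620, dtype=float)
        if (self.A440 < 0).any() or (self.A620 < 0).any():
            raise DomainError("absorbances must be >= 0")
        if self.exposure_days not in (1, 5):
            raise DomainError("exposure_days must be 1 or 5")


@dataclass(frozen=True)
class InhibitionFit:
    top: float  # response at zero concentration
    bottom: float  # response floor
    IC50: float  # µM (in the units of the fitted concentrations)
    slope: float  # Hill slope (1.0 unless the free-slope variant is used)
    rss: float
    converged: bool
    se_log10_IC50: float = float("nan")  # asymptotic standard error

    def response(self, c):
        c = np.asarray(c, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (c / self.IC50) ** self.slope
        )


def check_validity(plate: DifferentiationPlate) -> tuple[bool, str]:
    """Assay validity from the solvent control.

    Valid iff strictly more than 21 of 24 control EBs beat; for other
    totals the 21/24 fraction is applied proportionally (strict).
    """
    if plate.solvent_control is None:
        raise ParameterValidationError("solvent control missing from plate")
    beating, total = plate.solvent_control
    if total <= 0:
        raise ParameterValidationError("solvent control total must be > 0")
    frac = beating / total
    if frac > _VALIDITY_FRACTION:
        return True, (f"valid: {beating}/{total} solvent-control EBs beating "
                      f"(> {_VALIDITY_FRACTION:.1%})")
    return False, (f"invalid: {beating}/{total} solvent-control EBs beating "
                   f"(needs > {_VALIDITY_FRACTION:.1%})")


def viability_percent(A440, A620, control_A440, control_A620) -> float:
    """WST-1 viability as % of solvent control.

    ``100 * mean(A440 - A620) / mean(A440c - A620c)`` on background-
    corrected absorbances.
    """
    corrected = np.asarray(A440, float) - np.asarray(A620, float)
    control = np.asarray(control_A440, float) - np.asarray(control_A620, float)
    denom = control.mean()
    if denom <= 0:
        raise DegenerateFitError(
            "solvent-control corrected absorbance must be > 0"
        )
    return float(100.0 * corrected.mean() / denom)


def differentiation_percent(plate: DifferentiationPlate) -> np.ndarray:
    """Beating fraction per concentration as % of the solvent control."""
    cb, ct = plate.solvent_control
    if cb <= 0:
        raise DegenerateFitError("solvent control has no beating EBs")
    control_frac = cb / ct
    return 100.0 * (plate.beating / plate.total) / control_frac


def fit_inhibition(concentration, response, free_slope: bool = False,
                   min_span: float = 5.0) -> InhibitionFit:
    """Fit the three-parameter log-inhibition model to %-response data.

    ``concentration`` in µM (zeros allowed: the model evaluates to ``top``
    there), ``response`` typically in percent of control.  The IC50 is
    reported in the concentration units supplied.  Raises
    :class:`NoTransitionError` when the response span is below ``min_span``
    (default 5 response units).
    """
    c = np.asarray(concentration, dtype=float)
    r = np.asarray(response, dtype=float)
    if c.shape != r.shape:
        raise DomainError("concentration and response must have equal length")
    if (c < 0).any():
        raise DomainError("concentrations must be >= 0")
    if np.unique(c).size < 4:
        raise DegenerateFitError("need >= 4 distinct concentrations")
    if r.max() - r.min() < min_span:
        raise NoTransitionError(
            f"response span {r.max() - r.min():.2f} below {min_span}; "
            "no transition to fit"
        )

    top0, bottom0 = float(r.max()), float(r.min())
    mid = (top0 + bottom0) / 2.0
    pos = c > 0
    ic0 = float(c[pos][np.argmin(np.abs(r[pos] - mid))])

    def model3(cc, top, bottom, log_ic50):
        return bottom + (top - bottom) / (1.0 + cc / 10.0 ** log_ic50)

    def model4(cc, top, bottom, log_ic50, slope):
        with np.errstate(divide="ignore"):
            ratio = np.where(cc > 0, cc / 10.0 ** log_ic50, 0.0)
            return bottom + (top - bottom) / (1.0 + ratio ** slope)

    se = float("nan")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if free_slope:
                popt, pcov = curve_fit(
                    model4, c, r, p0=(top0, bottom0, np.log10(ic0), 1.0),
                    maxfev=20000,
                )
                top, bottom, log_ic50, slope = popt
                pred = model4(c, *popt)
            else:
                popt, pcov = curve_fit(
                    model3, c, r, p0=(top0, bottom0, np.log10(ic0)),
                    maxfev=20000,
                )
                top, bottom, log_ic50 = popt
                slope = 1.0
                pred = model3(c, *popt)
        se = float(np.sqrt(max(pcov[2, 2], 0.0)))
        converged = True
    except RuntimeError:
        top, bottom, log_ic50, slope = top0, bottom0, np.log10(ic0), 1.0
        pred = model3(c, top, bottom, log_ic50)
        converged = False
        warnings.warn("inhibition fit did not converge; returning start "
                      "values", stacklevel=2)
    if top < bottom:  # canonical orientation
        top, bottom = bottom, top
    rss = float(np.sum((r - pred) ** 2))
    return InhibitionFit(top=float(top), bottom=float(bottom),
                         IC50=float(10.0 ** log_ic50), slope=float(slope),
                         rss=rss, converged=converged, se_log10_IC50=se)


def read_differentiation_table(path: str | Path, sep: str = "\t") -> DifferentiationPlate:
    """Read a plate table with concentration_uM, beating, total columns.

    The row with concentration 0 is taken as the solvent control.
    """
    df = pd.read_csv(path, sep=sep)
    ctrl = df[df["concentration_uM"] == 0]
    if ctrl.empty:
        raise ParameterValidationError(
            "no concentration_uM == 0 row (solvent control) in plate table"
        )
    rest = df[df["concentration_uM"] > 0]
    return DifferentiationPlate(
        concentration=rest["concentration_uM"].to_numpy(float),
        beating=rest["beating"].to_numpy(int),
        total=rest["total"].to_numpy(int),
        solvent_control=(int(ctrl["beating"].iloc[0]), int(ctrl["total"].iloc[0])),
    )
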