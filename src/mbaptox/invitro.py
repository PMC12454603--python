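"""In vitro enzyme kinetics: velocities from incubations and MM fitting.

Velocities are computed from metabolite concentrations measured in rat
liver S9 (or microsomal) incubations and expressed in nmol/min/mg
protein; the substrate-velocity relationship is fitted with the
Michaelis-Menten equation v = Vmax*S/(Km + S) by unweighted nonlinear
least squares, initialized from a Hanes-Woolf linearization.  Initial-rate
conditions are assumed (no substrate-depletion correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, DomainError

__all__ = [
    "VelocityDataset",
    "MMFit",
    "velocity_from_metabolite",
    "fit_michaelis_menten",
    "read_velocity_table",
    "write_mm_report",
]


@dataclass
class VelocityDataset:
    """Substrate-velocity pairs from one incubation series."""

    substrate_conc: np.ndarray  # µM
    velocity: np.ndarray  # nmol/min/mg protein
    protein_conc: float = 0.1  # mg/mL
    incubation_time: float = 20.0  # min
    replicate: int = 0

    def __post_init__(self):
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.substrate_conc.shape != self.velocity.shape:
            raise DomainError("substrate_conc and velocity must have equal length")
        if (self.substrate_conc < 0).any():
            raise DomainError("substrate concentrations must be >= 0")
        if (self.velocity < 0).any():
            raise DomainError("velocities must be >= 0")


@dataclass(frozen=True)
class MMFit:
    Vmax: float  # nmol/min/mg
    Km: float  # µM
    rss: float
    converged: bool


def velocity_from_metabolite(metabolite_conc: float, time: float,
                             protein: float) -> float:
    """Enzymatic velocity from the metabolite formed in an incubation.

    ``metabolite_conc`` in µM (= nmol/mL), ``time`` in min, ``protein`` in
    mg/mL; the result is nmol/min/mg protein.
    """
    if time <= 0:
        raise DomainError("incubation time must be > 0")
    if protein <= 0:
        raise DomainError("protein concentration must be > 0")
    if metabolite_conc < 0:
        raise DomainError("metabolite concentration must be >= 0")
    return metabolite_conc / (time * protein)


def _mm(S, Vmax, Km):
    return Vmax * S / (Km + S)


def fit_michaelis_menten(data: VelocityDataset) -> MMFit:
    """Fit v = Vmax*S/(Km+S) by unweighted nonlinear least squares.

    The start values come from a Hanes-Woolf (S/v vs S) linear pre-fit on
    the points with v > 0.  Requires at least 4 distinct substrate
    concentrations.  Non-convergence is flagged rather than raised.
    """
    S, v = data.substrate_conc, data.velocity
    pos = S > 0
    if np.unique(S[pos]).size < 4:
        raise DegenerateFitError(
            "need >= 4 distinct non-zero substrate concentrations"
        )
    if not (v > 0).any():
        raise DegenerateFitError("all velocities are zero; nothing to fit")

    ok = pos & (v > 0)
    # Hanes-Woolf: S/v = S/Vmax + Km/Vmax
    slope, intercept = np.polyfit(S[ok], S[ok] / v[ok], 1)
    vmax0 = 1.0 / slope if slope > 0 else float(v.max())
    km0 = intercept * vmax0 if intercept * vmax0 > 0 else float(np.median(S[pos]))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _mm, S, v, p0=(vmax0, km0),
                bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=10000,
            )
        converged = True
    except RuntimeError:
        popt, converged = (vmax0, km0), False
        warnings.warn("Michaelis-Menten fit did not converge; returning "
                      "Hanes-Woolf start values", stacklevel=2)
    rss = float(np.sum((v - _mm(S, *popt)) ** 2))
    return MMFit(Vmax=float(popt[0]), Km=float(popt[1]), rss=rss,
                 converged=converged)


def read_velocity_table(path: str | Path, sep: str = "\t") -> VelocityDataset:
    """Read a delimiter-separated table of substrate_uM / velocity columns.

    Accepts either ``velocity_nmol_min_mg`` directly or ``metabolite_uM``
    together with ``time_min`` and ``protein_mg_ml`` columns from which the
    velocity is computed.
    """
    df = pd.read_csv(path, sep=sep)
    if "velocity_nmol_min_mg" in df.columns:
        vel = df["velocity_nmol_min_mg"].to_numpy(float)
    elif {"metabolite_uM", "time_min", "protein_mg_ml"} <= set(df.columns):
        vel = np.array([
            velocity_from_metabolite(c, t, p)
            for c, t, p in zip(df["metabolite_uM"], df["time_min"],
                               df["protein_mg_ml"])
        ])
    else:
        raise DomainError(
            "table must contain velocity_nmol_min_mg or "
            "metabolite_uM/time_min/protein_mg_ml columns"
        )
    return VelocityDataset(df["substrate_uM"].to_numpy(float), vel)


def write_mm_report(fit: MMFit, path: str | Path) -> None:
    Path(path).write_text(
        "michaelis_menten_fit\n"
        f"Vmax_nmol_min_mg\t{fit.Vmax:.6g}\n"
        f"Km_uM\t{fit.Km:.6g}\n"
        f"rss\t{fit.rss:.6g}\n"
        f"converged\t{fit.converged}\n"
    )
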