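"""Synthetic-data generators emulating the study's wet-lab readouts.

Three generators mirror the statistical structure of the experimental
inputs so that every pipeline stage can be exercised without laboratory
data:

* Michaelis-Menten incubation velocities with multiplicative Gaussian
  noise (S9 substrate-velocity curves, 0-100 µM substrate);
* mEST differentiation plates with binomial beating counts over 24
  embryoid bodies per concentration on a slope-1 log-inhibition curve;
* blood concentration-time tables on the in vivo sampling schedule
  (1 min - 72 h, n = 3 animals) with lognormal measurement noise, the
  truth being a PBK simulation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .invitro import VelocityDataset
from .mest import DifferentiationPlate
from .parameters import ParameterBundle
from .pbk import ExposureEvent, build_model, simulate

__all__ = [
    "BLOOD_SAMPLING_SCHEDULE_H",
    "gen_mm_velocities",
    "gen_mest_plate",
    "gen_blood_timecourse",
]

#: In vivo blood-sampling schedule (hours): 1 min, then 0.5-72 h.
BLOOD_SAMPLING_SCHEDULE_H = (
    1.0 / 60.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 32.0, 48.0, 72.0,
)

#: beating probability for the 5-FU positive control (strong inhibition)
_POSITIVE_CONTROL_P = 0.05


def gen_mm_velocities(
    Vmax: float,
    Km: float,
    substrate_grid,
    cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[VelocityDataset]:
    """Noisy Michaelis-Menten velocity datasets.

    ``v = Vmax*S/(Km+S) * (1 + cv*eps)`` with standard-normal ``eps``,
    truncated at zero.  One dataset per replicate; ``cv = 0`` gives the
    exact curve.
    """
    S = np.asarray(substrate_grid, dtype=float)
    if (S < 0).any() or S.max() > 100.0:
        raise DomainError("substrate grid must lie within 0-100 µM")
    if cv < 0:
        raise DomainError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    truth = Vmax * S / (Km + S)
    out = []
    for rep in range(n_replicates):
        noise = 1.0 + cv * rng.standard_normal(S.size)
        v = np.maximum(truth * noise, 0.0)
        out.append(VelocityDataset(substrate_conc=S.copy(), velocity=v,
                                   replicate=rep))
    return out


def gen_mest_plate(
    IC50: float,
    top_fraction: float,
    concentrations,
    n_EB: int = 24,
    seed: int = 0,
) -> DifferentiationPlate:
    """Binomial differentiation plate on a slope-1 log-inhibition curve.

    The beating probability is ``p(c) = top_fraction / (1 + c/IC50)``;
    each concentration scores ``n_EB`` embryoid bodies.  The solvent
    control is drawn at ``p = top_fraction`` and the 5-FU positive
    control at a strongly inhibited probability.
    """
    if not 0 < top_fraction <= 1:
        raise DomainError("top_fraction must be in (0, 1]")
    if IC50 <= 0:
        raise DomainError("IC50 must be > 0")
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    p = top_fraction / (1.0 + c / IC50)
    beating = rng.binomial(n_EB, p)
    solvent = int(rng.binomial(n_EB, top_fraction))
    positive = int(rng.binomial(n_EB, _POSITIVE_CONTROL_P))
    return DifferentiationPlate(
        concentration=c,
        beating=beating,
        total=np.full(c.size, n_EB, dtype=int),
        solvent_control=(solvent, n_EB),
        positive_control=(positive, n_EB),
    )


def gen_blood_timecourse(
    bundle: ParameterBundle,
    exposure: ExposureEvent,
    times=BLOOD_SAMPLING_SCHEDULE_H,
    sdlog: float = 0.3,
    n_animals: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated blood sampling with lognormal measurement noise.

    Columns: time_h, animal, species, concentration_uM.  The truth is the
    PBK-predicted venous blood concentration; each animal's observation
    is ``truth * exp(sdlog * eps)``.  ``sdlog = 0`` returns the model
    predictions exactly.
    """
    if sdlog < 0:
        raise DomainError("sdlog must be >= 0")
    t = np.asarray(times, dtype=float)
    model = build_model(bundle)
    res = simulate(model, exposure, t_end=float(t.max()))
    rng = np.random.default_rng(seed)
    rows = []
    for species in ("parent", "metabolite"):
        idx = res._tissue_index(species, "blood")
        if res.sol is None:  # zero dose
            truth = np.zeros(t.size)
        else:
            truth = res.sol(t)[idx] / model.volumes["venous_blood"]
            truth = np.maximum(truth, 0.0)
        for animal in range(n_animals):
            eps = rng.standard_normal(t.size)
            obs = truth * np.exp(sdlog * eps)
            rows.append(pd.DataFrame({
                "time_h": t,
                "animal": animal,
                "species": species,
                "concentration_uM": obs,
            }))
    return pd.concat(rows, ignore_index=True)
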