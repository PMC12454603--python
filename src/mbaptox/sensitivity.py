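"""Normalized local sensitivity analysis of the PBK model.

For each scalar parameter P the coefficient

    SC = ((C' - C) / (P' - P)) * (P / C)

is computed by a one-sided forward perturbation (default +10%), where C
is the model-predicted blood Cmax of the 3-OH metabolite.  When a
fractional blood flow is perturbed, the remaining flows among
{liver, rapidly perfused, slowly perfused} are rescaled proportionally so
the fractions (including fat) keep summing to 1.

Perturbing the fractional liver volume also rescales the whole-liver
mass (and with it the metabolic capacities), so the perturbation carries
the capacity pathway through which liver size dominates metabolite
kinetics; the packaged fixed 9.1 g default agrees with VLc*BW to 0.4%.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, LookupKeyError
from .parameters import REACTION_INDEX, ParameterBundle
from .pbk import ExposureEvent, build_model, simulate

__all__ = [
    "SensitivityResult",
    "parameter_names",
    "perturb_bundle",
    "sensitivity_coefficient",
    "sensitivity_screen",
    "screen_to_frame",
]

_FLOW_TRIO = ("QLc", "QRc", "QSc")


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    SC: float
    route: str
    dose: float  # mg/kg bw
    delta: float  # relative perturbation


def _scale_field(obj, name: str, factor: float):
    return dataclasses.replace(obj, **{name: getattr(obj, name) * factor})


def _perturb_flow(bundle: ParameterBundle, name: str, factor: float):
    p = bundle.physiology
    new = {name: getattr(p, name) * factor}
    others = [q for q in _FLOW_TRIO if q != name]
    qf = new.get("QFc", p.QFc)
    fixed = qf + new.get(name, 0.0) if name != "QFc" else qf
    rest = 1.0 - fixed
    cur = sum(getattr(p, q) for q in others)
    for q in others:
        new[q] = getattr(p, q) * rest / cur
    return dataclasses.replace(bundle, physiology=dataclasses.replace(p, **new))


def _registry(bundle: ParameterBundle) -> dict:
    """parameter name -> function(bundle, factor) -> perturbed bundle."""
    reg: dict = {}

    def phys(field):
        return lambda b, f: dataclasses.replace(
            b, physiology=_scale_field(b.physiology, field, f)
        )

    def absorb(field):
        return lambda b, f: dataclasses.replace(
            b, absorption=_scale_field(b.absorption, field, f)
        )

    def compound(which, field):
        return lambda b, f: dataclasses.replace(
            b, **{which: _scale_field(getattr(b, which), field, f)}
        )

    def scaling(field):
        return lambda b, f: dataclasses.replace(
            b, scaling=_scale_field(b.scaling, field, f)
        )

    def vlc(b, f):
        # liver volume fraction carries the liver mass (metabolic capacity)
        b = dataclasses.replace(b, physiology=_scale_field(b.physiology, "VLc", f))
        return dataclasses.replace(b, scaling=_scale_field(b.scaling, "liver_mass", f))

    def reaction_field(key, field):
        def apply(b, f):
            rx = tuple(
                _scale_field(r, field, f) if r.key == key else r
                for r in b.reactions
            )
            return dataclasses.replace(b, reactions=rx)
        return apply

    reg["BW"] = phys("BW")
    reg["QCc"] = phys("QCc")
    for v in ("VFc", "VLuc", "VABc", "VVBc", "VRc", "VSc"):
        reg[v] = phys(v)
    reg["VLc"] = vlc
    for q in ("QFc", "QLc", "QRc", "QSc"):
        reg[q] = lambda b, f, _q=q: _perturb_flow(b, _q, f)
    for a in ("Kd", "Kt", "Ka", "kabin", "kin", "Kb"):
        reg[a] = absorb(a)

    for which, tag in (("parent", "8MBaP"), ("metabolite", "3OH8MBaP")):
        reg[f"MW{tag}"] = compound(which, "MW")
        reg[f"fub{tag}"] = compound(which, "fub_in_vivo")
        for pc in ("PF", "PL", "PLu", "PR", "PS"):
            reg[f"{pc}{tag}"] = compound(which, pc)

    for r in bundle.reactions:
        idx = REACTION_INDEX.get(r.key)
        reg[f"Vmax{idx}c"] = reaction_field(r.key, "Vmax_in_vitro")
        reg[f"Km{idx}"] = reaction_field(r.key, "Km")
    reg["MPL"] = scaling("MPL")
    reg["MSL"] = scaling("MSL")
    return reg


def parameter_names(bundle: ParameterBundle) -> list[str]:
    """Every scalar parameter addressable in the sensitivity screen."""
    return list(_registry(bundle))


def perturb_bundle(bundle: ParameterBundle, parameter: str,
                   factor: float) -> ParameterBundle:
    """Return a bundle with one parameter multiplied by ``factor``."""
    reg = _registry(bundle)
    if parameter not in reg:
        raise LookupKeyError(f"unknown parameter {parameter!r}")
    out = reg[parameter](bundle, factor)
    out.validate()
    return out


def _metabolite_cmax(bundle: ParameterBundle, route: str, dose: float,
                     t_end: float, rtol: float) -> float:
    r = simulate(build_model(bundle), ExposureEvent(route, dose),
                 t_end=t_end, rtol=rtol, atol=rtol * 1e-3)
    return r.summary("metabolite", "blood")[0]


def sensitivity_coefficient(
    bundle: ParameterBundle,
    parameter: str,
    route: str = "oral",
    dose: float = 10.0,
    delta: float = 0.10,
    baseline: float | None = None,
    t_end: float = 24.0,
    rtol: float = 1e-7,
) -> SensitivityResult:
    """One-sided normalized sensitivity of metabolite blood Cmax."""
    if delta <= 0:
        raise DomainError("delta must be > 0")
    if baseline is None:
        baseline = _metabolite_cmax(bundle, route, dose, t_end, rtol)
    if baseline == 0.0:
        raise DomainError("baseline Cmax is zero (zero dose?); SC undefined")
    perturbed = perturb_bundle(bundle, parameter, 1.0 + delta)
    c_prime = _metabolite_cmax(perturbed, route, dose, t_end, rtol)
    sc = (c_prime / baseline - 1.0) / delta
    return SensitivityResult(parameter=parameter, SC=float(sc),
                             route=str(route), dose=dose, delta=delta)


def sensitivity_screen(
    bundle: ParameterBundle,
    route: str = "oral",
    dose: float = 10.0,
    delta: float = 0.10,
    report_threshold: float = 0.0,
    t_end: float = 24.0,
    rtol: float = 1e-7,
) -> list[SensitivityResult]:
    """Perturb every scalar parameter independently; sort by |SC|.

    Returns results with |SC| >= ``report_threshold`` in descending
    |SC| order.  Coefficients with |SC| > 0.5 mark the most influential
    parameters.
    """
    baseline = _metabolite_cmax(bundle, route, dose, t_end, rtol)
    if baseline == 0.0:
        raise DomainError("baseline Cmax is zero (zero dose?); SC undefined")
    results = [
        sensitivity_coefficient(bundle, name, route, dose, delta,
                                baseline=baseline, t_end=t_end, rtol=rtol)
        for name in parameter_names(bundle)
    ]
    results = [r for r in results if abs(r.SC) >= report_threshold]
    return sorted(results, key=lambda r: abs(r.SC), reverse=True)


def screen_to_frame(results: list[SensitivityResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.parameter, r.SC, r.route, r.dose, r.delta) for r in results],
        columns=["parameter", "SC", "route", "dose_mg_per_kg", "delta"],
    )
    df["influential"] = df["SC"].abs() > 0.5
    return df
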