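"""Typed parameter bundles for the rat PBK model of 8-MBaP.

The model describes a flow-limited physiologically based kinetic (PBK)
model for 8-methyl-benzo[a]pyrene (8-MBaP) in rats with a sub-model for
its aromatic-ring oxidation metabolite 3-OH-8-MBaP.  All parameters enter
through a single structured-text (TOML) configuration; the packaged
default ``rat_8mbap.toml`` reproduces the published rat parameterization:
physiology and tissue:blood partition coefficients, absorption and
excretion rate constants, and the four hepatic Michaelis-Menten reactions
(P450 hydroxylation of the parent to the 3-OH metabolite, P450 oxidation
to the sum of other metabolites, and S9-based glucuronidation and
sulfation of the metabolite).

Units
-----
* body weight ``kg``; tissue volumes and blood flows as fractions
* cardiac output ``QC = QCc * BW^0.74`` in L/h
* in vitro Vmax in nmol/min/mg protein, Km in µM
* whole-liver Vmax in µmol/h via ``Vmax * protein content * 60/1000 *
  liver mass`` with 45 mg microsomal and 125 mg S9 protein per g liver
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import ConfigurationError, DomainError, ParameterValidationError

__all__ = [
    "PhysiologyParams",
    "CompoundParams",
    "AbsorptionExcretionParams",
    "MetabolicReaction",
    "ScalingConstants",
    "ParameterBundle",
    "load_parameters",
    "default_bundle",
    "save_parameters",
    "scale_vmax",
    "derive_kabin",
    "dose_to_amount",
]

#: Expected unit string for every quantity in the configuration.  Units are
#: not converted -- they are contracts checked at load time.
_EXPECTED_UNITS = {
    ("physiology", "BW"): "kg",
    ("physiology", "QCc"): "L/h/kg^0.74",
    ("absorption", "Kd"): "1/h",
    ("absorption", "Kt"): "1/h",
    ("absorption", "Ka"): "1/h",
    ("absorption", "Papp"): "dm/h",
    ("absorption", "SAin"): "dm^2",
    ("absorption", "kin"): "1/h",
    ("absorption", "V_lumen"): "L",
    ("absorption", "Kb"): "1/h",
    ("absorption", "kabin"): "L/h",
    ("metabolism", "MPL"): "mg/g",
    ("metabolism", "MSL"): "mg/g",
    ("metabolism", "liver_mass"): "g",
    ("metabolism", "allometric_exponent"): "1",
    ("compound", "MW"): "g/mol",
    ("compound", "logP"): "log10",
    ("compound", "fub_in_vivo"): "fraction",
    ("reaction", "Vmax"): "nmol/min/mg",
    ("reaction", "Km"): "uM",
}

_VOLUME_KEYS = ("VFc", "VLc", "VLuc", "VABc", "VVBc", "VRc", "VSc")
_FLOW_KEYS = ("QFc", "QLc", "QRc", "QSc")
_PARTITION_KEYS = ("PF", "PL", "PLu", "PR", "PS")

#: Conventional 1-based reaction indices used in sensitivity reporting
#: (Vmax1c..Vmax4c / Km1..Km4).
REACTION_INDEX = {
    "hydroxylation": 1,
    "other_oxidation": 2,
    "sulfation": 3,
    "glucuronidation": 4,
}


@dataclass(frozen=True)
class PhysiologyParams:
    """Rat physiology: body weight, fractional volumes and blood flows."""

    BW: float
    VFc: float
    VLc: float
    VLuc: float
    VABc: float
    VVBc: float
    VRc: float
    VSc: float
    QCc: float
    QFc: float
    QLc: float
    QRc: float
    QSc: float
    QLuc: float = 1.0

    def validate(self) -> None:
        if self.BW <= 0:
            raise ParameterValidationError("body weight BW must be > 0")
        for key in _VOLUME_KEYS + _FLOW_KEYS:
            v = getattr(self, key)
            if not 0 < v <= 1:
                raise ParameterValidationError(
                    f"fraction {key}={v} outside (0, 1]"
                )
        if self.QCc <= 0:
            raise ParameterValidationError("QCc must be > 0")

    def check_fraction_sums(self, tol: float = 1e-12) -> None:
        """Enforce that volume and flow fractions each sum to 1.

        Applied when loading a configuration document; deliberately not
        applied to perturbed bundles used in sensitivity analysis.
        """
        vsum = sum(getattr(self, k) for k in _VOLUME_KEYS)
        if abs(vsum - 1.0) > tol:
            raise ParameterValidationError(
                f"fractional tissue volumes {_VOLUME_KEYS} sum to {vsum!r}, "
                "expected 1.0"
            )
        qsum = sum(getattr(self, k) for k in _FLOW_KEYS)
        if abs(qsum - 1.0) > tol:
            raise ParameterValidationError(
                f"fractional blood flows {_FLOW_KEYS} sum to {qsum!r}, "
                "expected 1.0"
            )

    @property
    def cardiac_output(self) -> float:
        """Total cardiac output QC in L/h (allometric in BW)."""
        return self.QCc * self.BW**0.74


@dataclass(frozen=True)
class CompoundParams:
    """Physicochemical properties and tissue:blood partition coefficients."""

    name: str
    MW: float
    logP: float
    fub_in_vivo: float
    PF: float
    PL: float
    PLu: float
    PR: float
    PS: float

    def validate(self) -> None:
        if self.MW <= 0:
            raise ParameterValidationError(f"{self.name}: MW must be > 0")
        if not 0 < self.fub_in_vivo <= 1:
            raise ParameterValidationError(
                f"{self.name}: fub_in_vivo={self.fub_in_vivo} outside (0, 1]"
            )
        for key in _PARTITION_KEYS:
            if getattr(self, key) <= 0:
                raise ParameterValidationError(
                    f"{self.name}: partition coefficient {key} must be > 0"
                )


@dataclass(frozen=True)
class AbsorptionExcretionParams:
    """Route-specific absorption and excretion constants.

    ``kabin`` is the per-segment intestinal absorption clearance in L/h,
    derived as ``Papp * SAin`` unless given explicitly.  ``kin`` is the
    lumen transfer rate to the next intestinal segment; it is a calibration
    choice (total small-intestinal residence ~1.5 h), not a measured value.
    """

    Kd: float
    Kt: float
    Ka: float
    Papp: float
    SAin: float
    kabin: float
    n_segments: int
    kin: float
    V_lumen: float
    Kb: float

    def validate(self) -> None:
        for key in ("Kd", "Kt", "Ka", "Papp", "SAin", "kabin", "kin", "Kb"):
            if getattr(self, key) < 0:
                raise ParameterValidationError(f"rate {key} must be >= 0")
        if self.n_segments < 1:
            raise ParameterValidationError("n_segments must be >= 1")
        if self.V_lumen <= 0:
            raise ParameterValidationError("V_lumen must be > 0")


@dataclass(frozen=True)
class MetabolicReaction:
    """One saturable hepatic reaction with in vitro kinetic constants."""

    key: str
    substrate: str
    product: str
    Vmax_in_vitro: float  # nmol/min/mg protein
    Km: float  # µM
    basis: str  # "microsomal" or "S9"

    def validate(self) -> None:
        if self.Vmax_in_vitro < 0:
            raise ParameterValidationError(
                f"reaction {self.key}: Vmax must be >= 0"
            )
        if self.Km <= 0:
            raise ParameterValidationError(f"reaction {self.key}: Km must be > 0")
        if self.basis not in ("microsomal", "S9"):
            raise ParameterValidationError(
                f"reaction {self.key}: basis must be 'microsomal' or 'S9'"
            )
        if self.substrate not in ("parent", "metabolite"):
            raise ParameterValidationError(
                f"reaction {self.key}: substrate must be 'parent' or 'metabolite'"
            )


@dataclass(frozen=True)
class ScalingConstants:
    """In vitro protein content to whole-liver scaling constants.

    ``allometric_exponent`` sets the in vivo maximal-rate convention used by
    the ODE model: ``Vmax_in_vivo = whole_liver_capacity * BW**a``.  The
    default a = 0.75 follows the allometric metabolic-scaling convention of
    the classic PBK template this model family descends from; a = 0 uses the
    whole-liver capacity (µmol/h) literally.
    """

    MPL: float = 45.0  # mg microsomal protein / g liver
    MSL: float = 125.0  # mg S9 protein / g liver
    liver_mass: float = 9.1  # g
    allometric_exponent: float = 0.75

    def validate(self) -> None:
        for key in ("MPL", "MSL", "liver_mass"):
            if getattr(self, key) <= 0:
                raise ParameterValidationError(f"{key} must be > 0")
        if self.allometric_exponent < 0:
            raise ParameterValidationError("allometric_exponent must be >= 0")


@dataclass(frozen=True)
class ParameterBundle:
    """Complete validated parameter set for one model build."""

    physiology: PhysiologyParams
    parent: CompoundParams
    metabolite: CompoundParams
    absorption: AbsorptionExcretionParams
    reactions: tuple[MetabolicReaction, ...]
    scaling: ScalingConstants

    def validate(self) -> None:
        self.physiology.validate()
        self.parent.validate()
        self.metabolite.validate()
        self.absorption.validate()
        for r in self.reactions:
            r.validate()
        self.scaling.validate()

    def reaction(self, key: str) -> MetabolicReaction:
        for r in self.reactions:
            if r.key == key:
                return r
        raise ConfigurationError(f"no reaction named {key!r} in the bundle")

    def protein_content(self, basis: str) -> float:
        """mg protein per g liver for the given in vitro basis."""
        if basis == "microsomal":
            return self.scaling.MPL
        if basis == "S9":
            return self.scaling.MSL
        raise ConfigurationError(f"unknown protein basis {basis!r}")

    def whole_liver_vmax(self, reaction: MetabolicReaction) -> float:
        """Maximum reaction rate scaled to the whole liver, in µmol/h."""
        _, whole = scale_vmax(
            reaction.Vmax_in_vitro,
            self.protein_content(reaction.basis),
            self.scaling.liver_mass,
        )
        return whole


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def scale_vmax(
    vmax_in_vitro: float, protein_content: float, liver_mass: float
) -> tuple[float, float]:
    """Scale an in vitro Vmax to the whole liver.

    Parameters
    ----------
    vmax_in_vitro : nmol/min/mg protein
    protein_content : mg protein per g liver (45 microsomal, 125 S9)
    liver_mass : g

    Returns
    -------
    (per_gram, whole_liver) : (µmol/h/g liver, µmol/h)
        ``per_gram = vmax * protein_content * 60 / 1000`` (minutes to hours,
        nmol to µmol); ``whole_liver = per_gram * liver_mass``.
    """
    if vmax_in_vitro < 0 or protein_content < 0 or liver_mass < 0:
        raise DomainError("scale_vmax arguments must be >= 0")
    per_gram = vmax_in_vitro * protein_content * 60.0 / 1000.0
    return per_gram, per_gram * liver_mass


def derive_kabin(Papp: float, SAin: float) -> float:
    """Per-segment intestinal absorption clearance ``Papp * SAin`` in L/h."""
    if Papp < 0 or SAin < 0:
        raise DomainError("Papp and SAin must be >= 0")
    return Papp * SAin  # dm/h * dm^2 = dm^3/h = L/h


def dose_to_amount(dose: float, BW: float, MW: float) -> float:
    """Convert a dose in mg/kg bw to a molar amount in µmol."""
    if MW <= 0:
        raise DomainError("MW must be > 0")
    if BW <= 0:
        raise DomainError("BW must be > 0")
    if dose < 0:
        raise DomainError("dose must be >= 0")
    return dose * BW / MW * 1000.0


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def _quantity(section: dict, section_name: str, key: str, unit_key: str | None = None) -> float:
    """Extract ``{value, unit}`` and validate the unit string."""
    try:
        entry = section[key]
    except KeyError as exc:
        raise ConfigurationError(
            f"missing key {key!r} in section [{section_name}]"
        ) from exc
    if not isinstance(entry, dict) or "value" not in entry or "unit" not in entry:
        raise ConfigurationError(
            f"[{section_name}] {key} must be a table with 'value' and 'unit'"
        )
    lookup = unit_key if unit_key is not None else section_name
    expected = _EXPECTED_UNITS.get((lookup, key))
    if expected is not None and entry["unit"] != expected:
        raise ConfigurationError(
            f"[{section_name}] {key}: unit {entry['unit']!r}, expected {expected!r}"
        )
    return float(entry["value"])


def _fraction(section: dict, section_name: str, key: str) -> float:
    entry = section.get(key)
    if entry is None:
        raise ConfigurationError(f"missing key {key!r} in section [{section_name}]")
    if not isinstance(entry, dict) or entry.get("unit") != "fraction":
        raise ConfigurationError(
            f"[{section_name}] {key} must carry unit 'fraction'"
        )
    return float(entry["value"])


def _load_compound(doc: dict, which: str) -> CompoundParams:
    try:
        sec = doc["compounds"][which]
    except KeyError as exc:
        raise ConfigurationError(f"missing section [compounds.{which}]") from exc
    return CompoundParams(
        name=str(sec.get("name", which)),
        MW=_quantity(sec, f"compounds.{which}", "MW", unit_key="compound"),
        logP=_quantity(sec, f"compounds.{which}", "logP", unit_key="compound"),
        fub_in_vivo=_quantity(
            sec, f"compounds.{which}", "fub_in_vivo", unit_key="compound"
        ),
        **{
            k: float(sec[k]["value"]) if isinstance(sec.get(k), dict) else _missing(sec, which, k)
            for k in _PARTITION_KEYS
        },
    )


def _missing(sec: dict, which: str, key: str):
    raise ConfigurationError(f"missing key {key!r} in section [compounds.{which}]")


def load_parameters(path: str | Path | None = None) -> ParameterBundle:
    """Load and validate a parameter bundle from a TOML document.

    With ``path=None`` the packaged rat 8-MBaP defaults are loaded.  The
    default document additionally has its fraction sums and the
    liver-mass/VLc consistency checked; user documents get the same
    treatment (perturbed bundles constructed programmatically do not).
    """
    if path is None:
        text = (
            resources.files("mbaptox.data").joinpath("rat_8mbap.toml").read_text()
        )
        doc = tomllib.loads(text)
    else:
        doc = tomllib.loads(Path(path).read_text())

    for required in ("physiology", "compounds", "absorption", "metabolism"):
        if required not in doc:
            raise ConfigurationError(f"missing section [{required}]")

    phys_sec = doc["physiology"]
    physiology = PhysiologyParams(
        BW=_quantity(phys_sec, "physiology", "BW"),
        QCc=_quantity(phys_sec, "physiology", "QCc"),
        **{k: _fraction(phys_sec, "physiology", k) for k in _VOLUME_KEYS},
        **{k: _fraction(phys_sec, "physiology", k) for k in _FLOW_KEYS},
        QLuc=_fraction(phys_sec, "physiology", "QLuc"),
    )

    parent = _load_compound(doc, "parent")
    metabolite = _load_compound(doc, "metabolite")

    ab = doc["absorption"]
    Papp = _quantity(ab, "absorption", "Papp")
    SAin = _quantity(ab, "absorption", "SAin")
    kabin = (
        _quantity(ab, "absorption", "kabin")
        if "kabin" in ab
        else derive_kabin(Papp, SAin)
    )
    absorption = AbsorptionExcretionParams(
        Kd=_quantity(ab, "absorption", "Kd"),
        Kt=_quantity(ab, "absorption", "Kt"),
        Ka=_quantity(ab, "absorption", "Ka"),
        Papp=Papp,
        SAin=SAin,
        kabin=kabin,
        n_segments=int(ab.get("n_segments", 7)),
        kin=_quantity(ab, "absorption", "kin"),
        V_lumen=_quantity(ab, "absorption", "V_lumen"),
        Kb=_quantity(ab, "absorption", "Kb"),
    )

    met = doc["metabolism"]
    scaling = ScalingConstants(
        MPL=_quantity(met, "metabolism", "MPL"),
        MSL=_quantity(met, "metabolism", "MSL"),
        liver_mass=_quantity(met, "metabolism", "liver_mass"),
        allometric_exponent=(
            _quantity(met, "metabolism", "allometric_exponent")
            if "allometric_exponent" in met else 0.75
        ),
    )
    reactions = []
    for rsec in met.get("reactions", []):
        reactions.append(
            MetabolicReaction(
                key=str(rsec["key"]),
                substrate=str(rsec["substrate"]),
                product=str(rsec["product"]),
                Vmax_in_vitro=_quantity(rsec, f"reaction {rsec.get('key')}", "Vmax", unit_key="reaction"),
                Km=_quantity(rsec, f"reaction {rsec.get('key')}", "Km", unit_key="reaction"),
                basis=str(rsec["basis"]),
            )
        )
    if not reactions:
        raise ConfigurationError("no [[metabolism.reactions]] entries found")

    bundle = ParameterBundle(
        physiology=physiology,
        parent=parent,
        metabolite=metabolite,
        absorption=absorption,
        reactions=tuple(reactions),
        scaling=scaling,
    )
    bundle.validate()
    physiology.check_fraction_sums()
    # the fixed whole-liver mass must agree with VLc * BW to within 1%
    implied = physiology.VLc * physiology.BW * 1000.0
    if abs(scaling.liver_mass - implied) / implied > 0.01:
        raise ParameterValidationError(
            f"liver_mass={scaling.liver_mass} g inconsistent with "
            f"VLc*BW={implied:.3f} g (>1%)"
        )
    return bundle


def default_bundle() -> ParameterBundle:
    """The packaged rat 8-MBaP parameterization."""
    return load_parameters(None)


def _fmt(value: float) -> str:
    return repr(float(value))


def save_parameters(bundle: ParameterBundle, path: str | Path) -> None:
    """Serialize a bundle back to the TOML layout read by ``load_parameters``.

    Values are written with ``repr`` so a save/load round trip reproduces
    them bit-exactly.
    """
    p = bundle.physiology
    lines: list[str] = ['schema = "mbaptox-parameters-v1"', "", "[physiology]"]
    lines.append(f'BW = {{ value = {_fmt(p.BW)}, unit = "kg" }}')
    for k in _VOLUME_KEYS:
        lines.append(f'{k} = {{ value = {_fmt(getattr(p, k))}, unit = "fraction" }}')
    lines.append(f'QCc = {{ value = {_fmt(p.QCc)}, unit = "L/h/kg^0.74" }}')
    for k in _FLOW_KEYS + ("QLuc",):
        lines.append(f'{k} = {{ value = {_fmt(getattr(p, k))}, unit = "fraction" }}')

    for which, c in (("parent", bundle.parent), ("metabolite", bundle.metabolite)):
        lines += ["", f"[compounds.{which}]", f'name = "{c.name}"']
        lines.append(f'MW = {{ value = {_fmt(c.MW)}, unit = "g/mol" }}')
        lines.append(f'logP = {{ value = {_fmt(c.logP)}, unit = "log10" }}')
        lines.append(
            f'fub_in_vivo = {{ value = {_fmt(c.fub_in_vivo)}, unit = "fraction" }}'
        )
        for k in _PARTITION_KEYS:
            lines.append(f'{k} = {{ value = {_fmt(getattr(c, k))}, unit = "ratio" }}')

    a = bundle.absorption
    lines += ["", "[absorption]"]
    for k, unit in (
        ("Kd", "1/h"), ("Kt", "1/h"), ("Ka", "1/h"),
        ("Papp", "dm/h"), ("SAin", "dm^2"), ("kabin", "L/h"),
        ("kin", "1/h"), ("V_lumen", "L"), ("Kb", "1/h"),
    ):
        lines.append(f'{k} = {{ value = {_fmt(getattr(a, k))}, unit = "{unit}" }}')
    lines.append(f"n_segments = {a.n_segments}")

    s = bundle.scaling
    lines += ["", "[metabolism]"]
    lines.append(f'MPL = {{ value = {_fmt(s.MPL)}, unit = "mg/g" }}')
    lines.append(f'MSL = {{ value = {_fmt(s.MSL)}, unit = "mg/g" }}')
    lines.append(f'liver_mass = {{ value = {_fmt(s.liver_mass)}, unit = "g" }}')
    lines.append(
        f'allometric_exponent = {{ value = {_fmt(s.allometric_exponent)}, unit = "1" }}'
    )
    for r in bundle.reactions:
        lines += [
            "",
            "[[metabolism.reactions]]",
            f'key = "{r.key}"',
            f'substrate = "{r.substrate}"',
            f'product = "{r.product}"',
            f'basis = "{r.basis}"',
            f'Vmax = {{ value = {_fmt(r.Vmax_in_vitro)}, unit = "nmol/min/mg" }}',
            f'Km = {{ value = {_fmt(r.Km)}, unit = "uM" }}',
        ]
    Path(path).write_text("\n".join(lines) + "\n")
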