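"""Reference substance library and unit conversions.

Houses the chemical characterisation of the candidate Fe-binding humic
materials — bacterial, phytoplankton and in-situ exopolymeric substances
(EPS), poly- and monosaccharide carbohydrates, and the Suwannee River fulvic
(FA) and humic (HA) acid standards — as a packaged constant table, together
with the small unit algebra the equivalence arithmetic needs.

Per-substance fields:

``carb_content``
    hydrolysable-carbohydrate content, mg C-Carb per mg substance
    (glucose equivalents).
``ehs_content``
    electroactive-humic signature, mg eHS per mg substance (Suwannee River
    fulvic acid equivalents).  Not measured for HA; see
    :func:`effective_ehs_content`.
``fel_content``
    maximal Fe-binding capacity, nmol Fe per mg substance.
``logK``
    conditional stability constant log10(K_Fe'L), K in L/mol with respect
    to inorganic Fe'.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import DomainError, ParseError, UnitError

__all__ = [
    "SubstanceProfile",
    "Quantity",
    "SUBSTANCE_NAMES",
    "load_substance_table",
    "effective_ehs_content",
    "convert",
]


@dataclass(frozen=True)
class SubstanceProfile:
    """Constants for one candidate ligand substance.

    ``spread`` carries the reported half-ranges / standard deviations and
    ``n_obs`` the per-field observation counts; both are metadata only —
    no error propagation is performed downstream.
    """

    name: str
    carb_content: float
    ehs_content: float | None
    fel_content: float
    logK: float
    n_obs: Mapping[str, int] = field(default_factory=dict)
    spread: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr in ("carb_content", "fel_content"):
            v = getattr(self, attr)
            if not (v > 0):
                raise DomainError(f"{self.name}: {attr} must be > 0, got {v}")
        if self.ehs_content is not None and not (self.ehs_content > 0):
            raise DomainError(
                f"{self.name}: ehs_content must be > 0 or absent, got {self.ehs_content}"
            )
        if not (8.0 <= self.logK <= 14.0):
            raise DomainError(f"{self.name}: logK {self.logK} outside [8, 14]")


#: Packaged per-substance constants (mass fractions, binding capacities,
#: conditional stability constants).  Spread values are SD for n >= 3,
#: half data-gap for n == 2.
_SUBSTANCE_TABLE: tuple[SubstanceProfile, ...] = (
    SubstanceProfile(
        "EPS_bacteria", 0.189, 0.011, 4.724, 11.38,
        n_obs={"carb_content": 3, "ehs_content": 2, "fel_content": 4, "logK": 4},
        spread={"carb_content": 0.034, "ehs_content": 0.008,
                "fel_content": 2.374, "logK": 0.25},
    ),
    SubstanceProfile(
        "EPS_phytoplankton", 0.141, 0.104, 62.63, 11.65,
        n_obs={"carb_content": 3, "ehs_content": 2, "fel_content": 2, "logK": 2},
        spread={"carb_content": 0.040, "ehs_content": 0.025,
                "fel_content": 31.22, "logK": 0.27},
    ),
    SubstanceProfile(
        "EPS_insitu", 0.109, 0.164, 68.07, 10.91,
        n_obs={"carb_content": 2, "ehs_content": 1, "fel_content": 1, "logK": 1},
        spread={"carb_content": 0.011},
    ),
    SubstanceProfile(
        "Carb_PS", 0.101, 0.034, 0.376, 10.90,
        n_obs={"carb_content": 1, "ehs_content": 1, "fel_content": 1, "logK": 1},
    ),
    SubstanceProfile(
        "Carb_MS", 1.010, 0.075, 1.231, 9.855,
        n_obs={"carb_content": 1, "ehs_content": 1, "fel_content": 1, "logK": 2},
        spread={"logK": 1.06},
    ),
    SubstanceProfile(
        "FA", 0.077, 1.02, 16.70, 10.60,
        n_obs={"carb_content": 1, "ehs_content": 1, "fel_content": 1, "logK": 1},
    ),
    SubstanceProfile(
        "HA", 0.060, None, 31.90, 11.10,
        n_obs={"carb_content": 1, "fel_content": 1, "logK": 1},
    ),
)

SUBSTANCE_NAMES: tuple[str, ...] = tuple(p.name for p in _SUBSTANCE_TABLE)

_OVERRIDE_COLUMNS = ("name", "carb_content", "ehs_content", "fel_content", "logK")


def load_substance_table(source: str | Path | None = None) -> dict[str, SubstanceProfile]:
    """Return the substance library, keyed by substance name.

    With no ``source`` the packaged reference table is returned.  An
    override file is comma-separated UTF-8 with a header row containing
    ``name, carb_content, ehs_content, fel_content, logK``; an empty cell
    means the value is absent (only allowed for ``ehs_content``).
    """
    if source is None:
        return {p.name: p for p in _SUBSTANCE_TABLE}

    profiles: dict[str, SubstanceProfile] = {}
    with open(source, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _OVERRIDE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ParseError(f"override table missing columns: {', '.join(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            values: dict[str, float | None] = {}
            for col in _OVERRIDE_COLUMNS[1:]:
                cell = (row.get(col) or "").strip()
                if cell == "":
                    if col != "ehs_content":
                        raise ParseError(f"row {i}, column '{col}': value required")
                    values[col] = None
                    continue
                try:
                    values[col] = float(cell)
                except ValueError as exc:
                    raise ParseError(
                        f"row {i}, column '{col}': cannot parse {cell!r}"
                    ) from exc
            name = (row.get("name") or "").strip()
            if not name:
                raise ParseError(f"row {i}, column 'name': empty")
            try:
                profiles[name] = SubstanceProfile(
                    name,
                    values["carb_content"],  # type: ignore[arg-type]
                    values["ehs_content"],
                    values["fel_content"],  # type: ignore[arg-type]
                    values["logK"],  # type: ignore[arg-type]
                )
            except DomainError as exc:
                raise ParseError(f"row {i}: {exc}") from exc
    return profiles


def effective_ehs_content(profile: SubstanceProfile, ha_ehs_default: float = 1.0) -> float:
    """eHS content to use in the equivalence pipeline.

    HA has no measured eHS content; by convention it is treated as pure
    eHS mass (1.0 mg eHS per mg), consistent with the SRFA-equivalent mass
    scale on which eHS is reported (FA measures 1.02 ≈ 1).  The default is
    overridable so both conventions discussed in the field are available.
    """
    if profile.ehs_content is not None:
        return profile.ehs_content
    if not (ha_ehs_default > 0):
        raise DomainError(f"ha_ehs_default must be > 0, got {ha_ehs_default}")
    return ha_ehs_default


# --- unit algebra ----------------------------------------------------------

@dataclass(frozen=True)
class Quantity:
    value: float
    unit: str


# unit -> (dimension, factor to the dimension's base unit)
_UNITS: dict[str, tuple[str, float]] = {
    # mass concentration, base g/L
    "ug/L": ("mass_conc", 1e-6),
    "mg/L": ("mass_conc", 1e-3),
    "g/L": ("mass_conc", 1.0),
    # molar concentration, base mol/L
    "nmol/L": ("molar_conc", 1e-9),
    "umol/L": ("molar_conc", 1e-6),
    "mol/L": ("molar_conc", 1.0),
    # specific binding capacity, base nmol/mg
    "nmol/mg": ("capacity", 1.0),
    "nmol/ug": ("capacity", 1e3),
    # mass fraction, base mg/mg
    "mg/mg": ("fraction", 1.0),
    "ug/mg": ("fraction", 1e-3),
    # areal flux, base ug/m2/d
    "ug/m2/d": ("flux", 1.0),
    "mg/m2/d": ("flux", 1e3),
}

# aliases matching column-name spellings
_ALIASES = {
    "µg/L": "ug/L", "ugL": "ug/L", "nM": "nmol/L", "M": "mol/L",
    "µg/m2/d": "ug/m2/d", "nmol-per-mg": "nmol/mg", "nmol-per-ug": "nmol/ug",
    "nmol-per-µg": "nmol/ug", "mg-per-mg": "mg/mg",
    "mg-per-m2-per-day": "mg/m2/d", "µg-per-m2-per-day": "ug/m2/d",
    "ug-per-m2-per-day": "ug/m2/d",
}


def _resolve(unit: str) -> tuple[str, float]:
    u = _ALIASES.get(unit, unit)
    try:
        return _UNITS[u]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}") from None


def convert(q: Quantity, target: str, molar_mass: float | None = None) -> Quantity:
    """Convert ``q`` to ``target`` units by exact scale-factor arithmetic.

    Crossing between mass and molar concentration requires ``molar_mass``
    in g/mol; all other conversions are within one dimension.
    """
    dim_from, f_from = _resolve(q.unit)
    dim_to, f_to = _resolve(target)
    if dim_from == dim_to:
        return Quantity(q.value * f_from / f_to, target)
    if {dim_from, dim_to} == {"mass_conc", "molar_conc"}:
        if molar_mass is None:
            raise UnitError(
                f"conversion {q.unit!r} -> {target!r} requires molar_mass (g/mol)"
            )
        if not (molar_mass > 0 and math.isfinite(molar_mass)):
            raise DomainError(f"molar_mass must be positive, got {molar_mass}")
        grams_per_litre = q.value * f_from if dim_from == "mass_conc" else None
        if grams_per_litre is not None:
            return Quantity(grams_per_litre / molar_mass / f_to, target)
        mol_per_litre = q.value * f_from
        return Quantity(mol_per_litre * molar_mass / f_to, target)
    raise UnitError(f"cannot convert {q.unit!r} ({dim_from}) to {target!r} ({dim_to})")
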