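"""Humic-equivalence arithmetic: from eHS to ligand equivalents.

Converts a measured electroactive-humic concentration (eHS, µg/L SRFA
equivalent) into the iron-binding-ligand pool a candidate substance would
supply if all of the eHS signal were that substance:

1. equivalent substance concentration (mg/L) = eHS (mg/L) / eHS content,
2. ligand equivalent L_X (nmol/L) = equivalent concentration × Fe-L content,
3. contribution (%) = 100 × L_X / in-situ Fe-L.

Alongside: the complexing-capacity criterion (excess ligand eL = Fe-L − DFe
times the conditional constant K; a substance can plausibly control in-situ
Fe chemistry only when its capacity matches or exceeds the in-situ one),
DFe:eHS saturation diagnostics, the Fe saturation a substance would need to
account for the in-situ ligand pool, and the dust-flux / mixed-layer
inventory bookkeeping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError
from .stats import box_summary
from .substances import SubstanceProfile, effective_ehs_content, load_substance_table

logger = logging.getLogger(__name__)

__all__ = [
    "StationRecord",
    "EquivalenceResult",
    "equivalent_substance_concentration",
    "ligand_equivalent",
    "percent_contribution",
    "excess_ligand",
    "complexing_capacity",
    "dfe_ehs_ratio",
    "fe_capacity_per_mg_ehs",
    "required_fe_saturation",
    "dust_ehs_flux",
    "mld_inventory_comparison",
    "run_equivalence_pipeline",
]


@dataclass(frozen=True)
class StationRecord:
    """One depth sample of the speciation/organic-matter profile."""

    station: str
    depth: float                 # m, positive down
    dfe: float | None = None     # nmol/L
    fel: float | None = None     # nmol/L
    logK: float | None = None
    ehs: float | None = None     # µg/L SRFA equivalent
    carb: float | None = None    # µg/L glucose equivalent
    latitude: float | None = None
    longitude: float | None = None
    bacteria: float | None = None  # cells/mL
    fvfm: float | None = None      # photosystem-II efficiency, 0–1
    chla: float | None = None      # µg/L

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise DomainError(f"depth must be >= 0, got {self.depth}")
        for name in ("dfe", "fel", "ehs", "carb", "bacteria", "chla"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be >= 0, got {v}")
        if self.fvfm is not None and not (0.0 <= self.fvfm <= 1.0):
            raise DomainError(f"fvfm must be in [0, 1], got {self.fvfm}")


@dataclass(frozen=True)
class EquivalenceResult:
    """Ligand equivalents for one (record, substance) pair."""

    substance: str
    eq_substance_conc: float      # mg/L
    ligand_equivalent: float      # nmol/L (L_X)
    contribution_pct: float       # % of in-situ Fe-L; may exceed 100
    complexing_capacity_log: float       # substance eL×K, log10, eL in mol/L
    insitu_capacity_log: float = math.nan
    flags: tuple[str, ...] = ()


def equivalent_substance_concentration(
    ehs: float, substance: SubstanceProfile, ha_ehs_default: float = 1.0
) -> float:
    """Substance concentration (mg/L) equivalent to ``ehs`` µg/L."""
    if ehs < 0:
        raise DomainError(f"ehs must be >= 0, got {ehs}")
    content = effective_ehs_content(substance, ha_ehs_default)
    if content == 0:
        raise DomainError(f"{substance.name}: zero eHS content")
    return (ehs / 1000.0) / content


def ligand_equivalent(eq_conc: float, substance: SubstanceProfile) -> float:
    """L_X (nmol/L) supplied by ``eq_conc`` mg/L of the substance.

    Equivalently, the dissolved-Fe concentration at which the substance
    would be Fe-saturated — the saturation line of DFe-vs-eHS diagnostics.
    """
    if eq_conc < 0:
        raise DomainError(f"eq_conc must be >= 0, got {eq_conc}")
    return eq_conc * substance.fel_content


def percent_contribution(ligand_equiv: float, fel_insitu: float) -> float:
    """Potential contribution of L_X to the in-situ ligand pool, percent."""
    if fel_insitu <= 0:
        raise DomainError(f"fel_insitu must be > 0, got {fel_insitu}")
    if ligand_equiv < 0:
        raise DomainError(f"ligand_equiv must be >= 0, got {ligand_equiv}")
    return 100.0 * ligand_equiv / fel_insitu


def excess_ligand(fel: float, dfe: float) -> tuple[float, bool]:
    """eL = Fe-L − DFe (nmol/L); flag True when ligands are Fe-saturated."""
    if fel < 0 or dfe < 0:
        raise DomainError("fel and dfe must be >= 0")
    el = fel - dfe
    return el, el < 0


def complexing_capacity(eL: float, logK: float) -> float:
    """log10 of eL × K, with eL converted to mol/L.

    Undefined (NaN) when eL <= 0 — saturated ligands have no free binding
    capacity; callers exclude such values from aggregates.
    """
    if eL <= 0:
        return math.nan
    return math.log10(eL * 1e-9) + logK


def dfe_ehs_ratio(dfe: float, ehs: float) -> float:
    """Fe saturation proxy: nmol dissolved Fe per mg eHS."""
    if ehs <= 0:
        raise DomainError(f"ehs must be > 0, got {ehs}")
    if dfe < 0:
        raise DomainError(f"dfe must be >= 0, got {dfe}")
    return dfe / (ehs / 1000.0)


def fe_capacity_per_mg_ehs(substance: SubstanceProfile) -> float:
    """Fe-binding capacity normalised to eHS mass, nmol Fe per mg eHS."""
    if substance.ehs_content is None:
        raise DomainError(f"{substance.name} has no measured eHS content")
    return substance.fel_content / substance.ehs_content


def required_fe_saturation(ligand_equiv: float, fel_insitu: float) -> float:
    """Fe saturation (%) at which L_X alone accounts for the in-situ Fe-L."""
    if ligand_equiv <= 0:
        raise DomainError(f"ligand_equiv must be > 0, got {ligand_equiv}")
    if fel_insitu < 0:
        raise DomainError(f"fel_insitu must be >= 0, got {fel_insitu}")
    return 100.0 * fel_insitu / ligand_equiv


def dust_ehs_flux(
    content_lo_hi: tuple[float, float], deposition_lo_hi: tuple[float, float]
) -> tuple[float, float]:
    """Aeolian eHS flux range, µg eHS m⁻² d⁻¹.

    ``content_lo_hi`` in mg eHS per g dust, ``deposition_lo_hi`` in mg dust
    m⁻² d⁻¹; mg/g × mg/m²/d = µg/m²/d.
    """
    (clo, chi), (dlo, dhi) = content_lo_hi, deposition_lo_hi
    if clo > chi or dlo > dhi:
        raise DomainError("range bounds must satisfy lo <= hi")
    if min(clo, dlo) < 0:
        raise DomainError("ranges must be >= 0")
    return clo * dlo, chi * dhi


def mld_inventory_comparison(flux: float, ehs_conc: float, mld: float) -> float:
    """Daily aeolian input as a fraction of the mixed-layer eHS inventory.

    ``flux`` µg m⁻² d⁻¹, ``ehs_conc`` µg/L, ``mld`` m; the 1000 converts the
    m³ column under 1 m² to litres.
    """
    if flux < 0:
        raise DomainError(f"flux must be >= 0, got {flux}")
    if ehs_conc <= 0 or mld <= 0:
        raise DomainError("ehs_conc and mld must be > 0")
    return flux / (ehs_conc * mld * 1000.0)


_REQUIRED = ("ehs", "fel", "dfe", "logK")


def _as_records(records) -> list[StationRecord]:
    if isinstance(records, pd.DataFrame):
        from .io import records_from_frame
        return records_from_frame(records)
    return list(records)


def run_equivalence_pipeline(
    records: Iterable[StationRecord] | pd.DataFrame,
    substances: Sequence[str] | Mapping[str, SubstanceProfile] | None = None,
    ha_ehs_default: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the equivalence chain per record × substance.

    Returns ``(results, summaries)``: one result row per record/substance
    with ligand equivalent, contribution, required Fe saturation and both
    complexing capacities (substance constant vs in-situ constant, each with
    the record's excess ligand); and per-substance box summaries (mean, SD,
    5th/95th percentiles, n) of contribution and capacity.  Records missing
    any of ehs/fel/dfe/logK are skipped with a logged count; undefined
    capacities (eL <= 0) are flagged and excluded from aggregates.
    """
    library = load_substance_table()
    if substances is None:
        profiles = list(library.values())
    elif isinstance(substances, Mapping):
        profiles = list(substances.values())
    else:
        profiles = [library[name] for name in substances]

    rows = []
    n_skipped = 0
    for rec in _as_records(records):
        if any(getattr(rec, f) is None for f in _REQUIRED):
            n_skipped += 1
            continue
        el, saturated = excess_ligand(rec.fel, rec.dfe)
        cap_insitu = complexing_capacity(el, rec.logK) if not saturated else math.nan
        for prof in profiles:
            eq_conc = equivalent_substance_concentration(rec.ehs, prof, ha_ehs_default)
            lx = ligand_equivalent(eq_conc, prof)
            contrib = percent_contribution(lx, rec.fel) if rec.fel > 0 else math.nan
            req_sat = required_fe_saturation(lx, rec.fel) if lx > 0 else math.nan
            cap_sub = complexing_capacity(el, prof.logK) if not saturated else math.nan
            flags = []
            if saturated:
                flags.append("negative excess ligand")
            rows.append({
                "station": rec.station, "depth_m": rec.depth,
                "substance": prof.name,
                "eq_substance_conc_mgL": eq_conc,
                "ligand_equivalent_nM": lx,
                "contribution_pct": contrib,
                "required_fe_saturation_pct": req_sat,
                "excess_ligand_nM": el,
                "capacity_substance_log": cap_sub,
                "capacity_insitu_log": cap_insitu,
                "flags": ";".join(flags),
            })
    if n_skipped:
        logger.warning("equivalence pipeline skipped %d record(s) missing %s",
                       n_skipped, "/".join(_REQUIRED))

    columns = ["station", "depth_m", "substance", "eq_substance_conc_mgL",
               "ligand_equivalent_nM", "contribution_pct",
               "required_fe_saturation_pct", "excess_ligand_nM",
               "capacity_substance_log", "capacity_insitu_log", "flags"]
    results = pd.DataFrame(rows, columns=columns)
    results.attrs["n_skipped"] = n_skipped

    summary_rows = []
    for name, grp in results.groupby("substance", sort=False):
        for quantity, col in (
            ("contribution_pct", "contribution_pct"),
            ("ligand_equivalent_nM", "ligand_equivalent_nM"),
            ("capacity_substance_log", "capacity_substance_log"),
        ):
            s = box_summary(grp[col].dropna().to_numpy())
            summary_rows.append({
                "substance": name, "quantity": quantity,
                "mean": s.mean, "sd": s.sd, "p5": s.p5, "p95": s.p95, "n": s.n,
                "n_undefined": int(grp[col].isna().sum()),
            })
    summaries = pd.DataFrame(
        summary_rows,
        columns=["substance", "quantity", "mean", "sd", "p5", "p95",
                 "n", "n_undefined"],
    )
    return results, summaries
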