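"""Delimited-text readers and writers.

One fixed dialect everywhere: comma separator, UTF-8, mandatory header
row, "." decimal, empty cell = missing.  Units are encoded in column
names (``dfe_nM``, ``ehs_ugL``) so files are self-describing.  Result
files carry a provenance header of ``#``-prefixed comment lines, skipped
on read; headers never include timestamps so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .equivalence import StationRecord
from .errors import SchemaError
from .speciation import TitrationCurve

logger = logging.getLogger(__name__)

__all__ = [
    "STATION_COLUMNS",
    "read_station_table",
    "write_station_table",
    "read_titration",
    "write_titration",
    "records_from_frame",
    "frame_from_records",
]

STATION_COLUMNS = (
    "station", "latitude", "longitude", "depth_m", "dfe_nM", "fel_nM",
    "logK", "ehs_ugL", "carb_ugL", "bacteria_per_mL", "fvfm", "chla_ugL",
)
_MANDATORY = ("depth_m",)
_ANY_OF = ("dfe_nM", "fel_nM", "ehs_ugL")

_COLUMN_TO_FIELD = {
    "station": "station", "latitude": "latitude", "longitude": "longitude",
    "depth_m": "depth", "dfe_nM": "dfe", "fel_nM": "fel", "logK": "logK",
    "ehs_ugL": "ehs", "carb_ugL": "carb", "bacteria_per_mL": "bacteria",
    "fvfm": "fvfm", "chla_ugL": "chla",
}


def _provenance_header(meta: dict | None = None) -> str:
    from . import __version__
    lines = [f"# felig v{__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k} = {v}")
    return "\n".join(lines) + "\n"


def read_station_table(path: str | Path, strict: bool = False) -> pd.DataFrame:
    """Read a station CSV into a validated DataFrame.

    Requires ``depth_m`` plus at least one of ``dfe_nM``/``fel_nM``/
    ``ehs_ugL``.  Rows violating record invariants (negative depth or
    concentrations, fvfm outside [0,1]) are dropped and counted in
    ``df.attrs["n_rejected"]``.  Unknown columns are accepted with a
    warning in lenient mode and rejected in strict mode.
    """
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing or not any(c in df.columns for c in _ANY_OF):
        raise SchemaError(
            f"{path}: needs columns {_MANDATORY} and one of {_ANY_OF}; "
            f"found {list(df.columns)}")
    unknown = [c for c in df.columns if c not in STATION_COLUMNS]
    if unknown:
        if strict:
            raise SchemaError(f"{path}: unknown columns {unknown} (strict mode)")
        logger.warning("%s: ignoring unknown columns %s", path, unknown)

    ok = df["depth_m"].notna() & (df["depth_m"] >= 0)
    for col in ("dfe_nM", "fel_nM", "ehs_ugL", "carb_ugL",
                "bacteria_per_mL", "chla_ugL"):
        if col in df.columns:
            ok &= df[col].isna() | (df[col] >= 0)
    if "fvfm" in df.columns:
        ok &= df["fvfm"].isna() | df["fvfm"].between(0, 1)
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d invalid row(s)", path, n_rejected)
    out = df[ok].reset_index(drop=True)
    out.attrs["n_rejected"] = n_rejected
    return out


def write_station_table(df: pd.DataFrame, path: str | Path,
                        meta: dict | None = None) -> None:
    """Write a station CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_header(meta))
        df.to_csv(fh, index=False)


def records_from_frame(df: pd.DataFrame) -> list[StationRecord]:
    """Typed records from a station DataFrame (NaN -> absent)."""
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, fname in _COLUMN_TO_FIELD.items():
            if col not in df.columns:
                continue
            v = row[col]
            if isinstance(v, float) and np.isnan(v):
                v = None
            kwargs[fname] = v
        kwargs.setdefault("station", "NA")
        records.append(StationRecord(**kwargs))
    return records


def frame_from_records(records: list[StationRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({col: getattr(rec, fname)
                     for col, fname in _COLUMN_TO_FIELD.items()})
    return pd.DataFrame(rows, columns=list(STATION_COLUMNS))


def write_titration(curve: TitrationCurve, path: str | Path) -> None:
    """Write one titration: ``#`` metadata header block then the series."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "dfe0_nM": repr(curve.dfe0),
        "sa_conc_M": repr(curve.sa_conc),
        "alpha_sa": repr(curve.alpha_sa),
        "pH": repr(curve.ph),
        **{k: v for k, v in curve.meta.items()},
    }
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_header(meta))
        pd.DataFrame({
            "fe_added_nM": curve.fe_added,
            "peak_current": curve.peak_current,
        }).to_csv(fh, index=False)


def read_titration(path: str | Path) -> TitrationCurve:
    """Read a titration CSV written by :func:`write_titration`."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("#").split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    for col in ("fe_added_nM", "peak_current"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col}")
    if "dfe0_nM" not in meta:
        raise SchemaError(f"{path}: header block must provide dfe0_nM")

    def _f(key: str, default: float | None = None) -> float | None:
        if key in meta:
            try:
                return float(meta[key])
            except ValueError as exc:
                raise SchemaError(f"{path}: bad header value {key}={meta[key]!r}") from exc
        return default

    extra = {k: v for k, v in meta.items()
             if k not in ("dfe0_nM", "sa_conc_M", "alpha_sa", "pH")
             and not k.startswith("felig ")}
    from .speciation import DEFAULT_SA_CONC
    return TitrationCurve(
        fe_added=df["fe_added_nM"].to_numpy(),
        peak_current=df["peak_current"].to_numpy(),
        dfe0=_f("dfe0_nM"),
        sa_conc=_f("sa_conc_M", DEFAULT_SA_CONC),
        alpha_sa=_f("alpha_sa"),
        ph=_f("pH", 8.2),
        meta=extra,
    )
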