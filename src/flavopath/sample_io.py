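"""Sample-table data model, validation and CSV/TSV round-tripping.

The universal currency of the pipeline is a :class:`SampleTable`: one row per
provenance (collection site) carrying the 15 flavonoid contents in mg/g dried
peel, the CIELAB color triple of the peel, the 10 annual climate factors of
the site, and the geographic metadata (group, altitude, longitude, latitude).
Any subset of the optional blocks may be absent -- the bundled reference table
of measured flavonoid contents, for instance, carries neither climate nor
color columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTE_CODES",
    "ANALYTE_NAMES",
    "CLIMATE_CODES",
    "CLIMATE_UNITS",
    "COLOR_CODES",
    "AnalyteCatalog",
    "ClimateCatalog",
    "ColorTriple",
    "SampleRecord",
    "SampleTable",
    "SchemaError",
    "ValidationError",
    "ParseError",
    "read_sample_table",
    "write_sample_table",
    "load_table1_fixture",
    "validate_schema",
    "summarize_ranges",
]

#: Canonical analyte codes, in catalog order.
ANALYTE_CODES: tuple[str, ...] = (
    "Y_HY", "Y_LU", "Y_KP", "Y_QI", "Y_C", "Y_RU", "Y_CA", "Y_QU",
    "Y_HE", "Y_AP", "Y_PH", "Y_PG", "Y_CGC", "Y_CSA", "Y_CGT",
)

ANALYTE_NAMES: dict[str, str] = {
    "Y_HY": "hyperoside",
    "Y_LU": "luteolin",
    "Y_KP": "kaempferol",
    "Y_QI": "quercitrin",
    "Y_C": "catechin",
    "Y_RU": "rutin",
    "Y_CA": "chlorogenic acid",
    "Y_QU": "quercetin",
    "Y_HE": "hesperetin",
    "Y_AP": "apigenin",
    "Y_PH": "peonidin O-hexoside",
    "Y_PG": "peonidin 3-O-glucoside",
    "Y_CGC": "cyanidin 3-O-glucoside",
    "Y_CSA": "cyanidin O-syringic acid",
    "Y_CGT": "cyanidin 3-O-galactoside",
}

#: Canonical annual climate-factor codes.
CLIMATE_CODES: tuple[str, ...] = (
    "X_AMT", "X_AMAT", "X_AMIT", "X_RH", "X_AAP",
    "X_MW", "X_MAW", "X_EW", "X_ASD", "X_ASP",
)

CLIMATE_UNITS: dict[str, str] = {
    "X_AMT": "degC",   # annual mean temperature
    "X_AMAT": "degC",  # annual mean maximum temperature
    "X_AMIT": "degC",  # annual mean minimum temperature
    "X_RH": "%",       # annual relative humidity
    "X_AAP": "mm",     # annual average precipitation
    "X_MW": "m/s",     # mean wind speed
    "X_MAW": "m/s",    # maximum wind speed
    "X_EW": "m/s",     # extreme wind speed
    "X_ASD": "h",      # annual sunshine duration
    "X_ASP": "%",      # percentage of sunshine
}

#: CIELAB color axis codes (L = lightness, a = green-red, b = blue-yellow).
COLOR_CODES: tuple[str, ...] = ("L", "a", "b")

#: Geographic metadata columns (all optional except sample_id/group).
GEO_CODES: tuple[str, ...] = ("altitude", "longitude", "latitude")

#: Tokens treated as missing on input (case-insensitive).
MISSING_TOKENS = {"", "na", "nan"}


class SchemaError(ValueError):
    """A mandatory column is absent or the schema mapping is unusable."""


class ValidationError(ValueError):
    """Table contents violate an invariant (duplicate ids, negative content)."""


class ParseError(ValueError):
    """A cell could not be parsed as a number; names the offending cell."""


@dataclass(frozen=True)
class AnalyteCatalog:
    """The fixed, ordered set of quantified flavonoid analytes."""

    codes: tuple[str, ...] = ANALYTE_CODES
    names: Mapping[str, str] = field(default_factory=lambda: dict(ANALYTE_NAMES))

    def __post_init__(self) -> None:
        if len(self.codes) != 15 or len(set(self.codes)) != 15:
            raise ValidationError("analyte catalog must hold exactly 15 unique codes")


@dataclass(frozen=True)
class ClimateCatalog:
    """The fixed set of annual climate factors with their units."""

    codes: tuple[str, ...] = CLIMATE_CODES
    units: Mapping[str, str] = field(default_factory=lambda: dict(CLIMATE_UNITS))

    def __post_init__(self) -> None:
        if len(self.codes) != 10 or len(set(self.codes)) != 10:
            raise ValidationError("climate catalog must hold exactly 10 unique codes")


@dataclass(frozen=True)
class ColorTriple:
    """CIELAB color coordinates of a peel sample."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for axis in ("L", "a", "b"):
            if not math.isfinite(getattr(self, axis)):
                raise ValidationError(f"color axis {axis} is not finite")


@dataclass
class SampleRecord:
    """One provenance: contents, optional SDs, color, climate, geography."""

    sample_id: str
    group: str
    flavonoids: dict[str, float]
    flavonoid_sd: dict[str, float] = field(default_factory=dict)
    color: ColorTriple | None = None
    climate: dict[str, float] = field(default_factory=dict)
    altitude: float | None = None
    longitude: float | None = None
    latitude: float | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, value in self.flavonoids.items():
            if math.isfinite(value) and value < 0:
                raise ValidationError(
                    f"negative flavonoid content {value} for {code} in {self.sample_id}"
                )
        for code, value in self.flavonoid_sd.items():
            if math.isfinite(value) and value < 0:
                raise ValidationError(
                    f"negative SD {value} for {code} in {self.sample_id}"
                )


class SampleTable:
    """An ordered collection of :class:`SampleRecord` plus the two catalogs.

    Provides a pandas view (:meth:`to_frame`) used by every analysis stage;
    absent optional variables appear as NaN columns or are omitted entirely.
    """

    def __init__(
        self,
        records: Sequence[SampleRecord],
        analyte_catalog: AnalyteCatalog | None = None,
        climate_catalog: ClimateCatalog | None = None,
    ) -> None:
        self.records = list(records)
        self.analyte_catalog = analyte_catalog or AnalyteCatalog()
        self.climate_catalog = climate_catalog or ClimateCatalog()
        self._validate()

    def _validate(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        known = set(self.analyte_catalog.codes)
        for rec in self.records:
            unknown = set(rec.flavonoids) - known
            if unknown:
                raise ValidationError(
                    f"unknown analyte code(s) {sorted(unknown)} in {rec.sample_id}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def present_variables(self) -> list[str]:
        """Codes present (non-missing for at least one record)."""
        frame = self.to_frame()
        out = []
        for col in frame.columns:
            if col in ("group",) or col.endswith("_sd") or col.endswith("_letters"):
                continue
            if frame[col].notna().any():
                out.append(col)
        return out

    def to_frame(self, include_sd: bool = False) -> pd.DataFrame:
        """Return the table as a DataFrame indexed by sample_id."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {"sample_id": rec.sample_id, "group": rec.group}
            for geo in GEO_CODES:
                value = getattr(rec, geo)
                if value is not None:
                    row[geo] = value
            for code in self.analyte_catalog.codes:
                if code in rec.flavonoids:
                    row[code] = rec.flavonoids[code]
                if include_sd and code in rec.flavonoid_sd:
                    row[code + "_sd"] = rec.flavonoid_sd[code]
            if rec.color is not None:
                row["L"], row["a"], row["b"] = rec.color.L, rec.color.a, rec.color.b
            for code in self.climate_catalog.codes:
                if code in rec.climate:
                    row[code] = rec.climate[code]
            rows.append(row)
        frame = pd.DataFrame(rows)
        return frame.set_index("sample_id")

    def matrix(self, variables: Sequence[str]) -> pd.DataFrame:
        """Numeric sub-matrix for the requested variable codes."""
        frame = self.to_frame()
        missing = [v for v in variables if v not in frame.columns]
        if missing:
            raise KeyError(f"variable(s) not in table: {missing}")
        return frame[list(variables)].astype(float)


def _default_schema(columns: Iterable[str]) -> dict[str, str]:
    return {c: c for c in columns}


def _parse_cell(raw: object, row_label: str, column: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text.lower() in MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"non-numeric value {text!r} at row {row_label!r}, column {column!r}"
        ) from None


def read_sample_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    analyte_catalog: AnalyteCatalog | None = None,
    climate_catalog: ClimateCatalog | None = None,
) -> SampleTable:
    """Read a CSV/TSV sample table.

    Parameters
    ----------
    path:
        File with a header row; delimiter is taken from the extension
        (``.tsv``/``.txt`` -> tab, otherwise comma).
    schema:
        Optional mapping from source header names to canonical codes
        (``sample_id``, ``group``, analyte codes, ``L``/``a``/``b``,
        climate codes, ``altitude``/``longitude``/``latitude``). Unmapped
        canonical headers are used as-is; unrecognized columns are ignored
        except ``<code>_sd`` and ``<code>_letters`` companions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if schema:
        raw = raw.rename(columns=dict(schema))
    if "sample_id" not in raw.columns:
        raise SchemaError("missing mandatory column 'sample_id'")
    acat = analyte_catalog or AnalyteCatalog()
    ccat = climate_catalog or ClimateCatalog()
    analytes_present = [c for c in acat.codes if c in raw.columns]
    if not analytes_present:
        raise SchemaError("table holds no recognized analyte column")

    records = []
    for _, row in raw.iterrows():
        sid = str(row["sample_id"]).strip()
        group = str(row["group"]).strip() if "group" in raw.columns else sid[:1]
        flav: dict[str, float] = {}
        flav_sd: dict[str, float] = {}
        annotations: dict[str, str] = {}
        for code in analytes_present:
            value = _parse_cell(row[code], sid, code)
            if value is not None:
                flav[code] = value
            sd_col = code + "_sd"
            if sd_col in raw.columns:
                sd = _parse_cell(row[sd_col], sid, sd_col)
                if sd is not None:
                    flav_sd[code] = sd
            note_col = code + "_letters"
            if note_col in raw.columns and str(row[note_col]).strip():
                annotations[note_col] = str(row[note_col]).strip()
        climate: dict[str, float] = {}
        for code in ccat.codes:
            if code in raw.columns:
                value = _parse_cell(row[code], sid, code)
                if value is not None:
                    climate[code] = value
        color = None
        if all(axis in raw.columns for axis in COLOR_CODES):
            axes = [_parse_cell(row[axis], sid, axis) for axis in COLOR_CODES]
            if all(v is not None for v in axes):
                color = ColorTriple(*axes)  # type: ignore[arg-type]
        geo = {}
        for code in GEO_CODES:
            if code in raw.columns:
                geo[code] = _parse_cell(row[code], sid, code)
        records.append(
            SampleRecord(
                sample_id=sid,
                group=group,
                flavonoids=flav,
                flavonoid_sd=flav_sd,
                color=color,
                climate=climate,
                altitude=geo.get("altitude"),
                longitude=geo.get("longitude"),
                latitude=geo.get("latitude"),
                annotations=annotations,
            )
        )
    return SampleTable(records, acat, ccat)


def _fmt(x: float) -> str:
    # 12 significant digits guarantees lossless round-trip of printed values
    return format(float(x), ".12g")


def write_sample_table(table: SampleTable, path: str | Path) -> Path:
    """Write a sample table to CSV/TSV; optional blocks absent from every
    record are omitted from the header."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    recs = table.records
    have_sd = any(r.flavonoid_sd for r in recs)
    have_color = any(r.color is not None for r in recs)
    have_climate = any(r.climate for r in recs)
    have_geo = {g: any(getattr(r, g) is not None for r in recs) for g in GEO_CODES}
    have_notes = any(r.annotations for r in recs)

    header = ["sample_id", "group"]
    header += [g for g in GEO_CODES if have_geo[g]]
    for code in table.analyte_catalog.codes:
        header.append(code)
        if have_sd:
            header.append(code + "_sd")
        if have_notes:
            header.append(code + "_letters")
    if have_color:
        header += list(COLOR_CODES)
    if have_climate:
        header += [c for c in table.climate_catalog.codes
                   if any(c in r.climate for r in recs)]

    lines = [sep.join(header)]
    for rec in recs:
        cells = {"sample_id": rec.sample_id, "group": rec.group}
        for g in GEO_CODES:
            value = getattr(rec, g)
            cells[g] = _fmt(value) if value is not None else ""
        for code in table.analyte_catalog.codes:
            cells[code] = _fmt(rec.flavonoids[code]) if code in rec.flavonoids else ""
            if code in rec.flavonoid_sd:
                cells[code + "_sd"] = _fmt(rec.flavonoid_sd[code])
            cells[code + "_letters"] = rec.annotations.get(code + "_letters", "")
        if rec.color is not None:
            cells["L"], cells["a"], cells["b"] = (
                _fmt(rec.color.L), _fmt(rec.color.a), _fmt(rec.color.b))
        for code, value in rec.climate.items():
            cells[code] = _fmt(value)
        lines.append(sep.join(cells.get(col, "") for col in header))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def load_table1_fixture() -> SampleTable:
    """Load the bundled 26-provenance flavonoid content table.

    Means and SDs (mg/g, n = 3 analytical replicates) are exactly as printed
    in the source publication; the homogeneity letters of the multiple-
    comparison test ship as inert annotations.
    """
    with resources.as_file(
        resources.files("flavopath.data") / "table1_flavonoids.csv"
    ) as p:
        return read_sample_table(p)


def validate_schema(table: SampleTable, required: Sequence[str]) -> pd.DataFrame:
    """Report presence and per-variable missing-cell counts (report-only)."""
    frame = table.to_frame()
    n = len(table)
    rows = []
    for code in required:
        present = code in frame.columns
        missing = int(frame[code].isna().sum()) if present else n
        rows.append({"variable": code, "present": present, "n_missing": missing})
    return pd.DataFrame(rows).set_index("variable")


def summarize_ranges(
    table: SampleTable, variables: Sequence[str]
) -> pd.DataFrame:
    """Per-variable (min, max, mean) over record means, with the sample ids
    attaining the extremes (first occurrence on ties)."""
    frame = table.to_frame()
    unknown = [v for v in variables if v not in frame.columns]
    if unknown:
        raise KeyError(f"unknown variable code(s): {unknown}")
    rows = []
    for code in variables:
        col = frame[code].astype(float)
        valid = col.dropna()
        if valid.empty:
            raise KeyError(f"variable {code} has no observed values")
        imin = valid.idxmin()  # pandas idxmin: first occurrence on ties
        imax = valid.idxmax()
        rows.append({
            "variable": code,
            "min": float(valid.min()),
            "max": float(valid.max()),
            "mean": float(valid.mean()),
            "argmin": imin,
            "argmax": imax,
        })
    return pd.DataFrame(rows).set_index("variable")
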