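"""Read, write and validate the reference-dataset CSV layouts.

Nine table schemas cover the published file family: plant ingredients,
marine/freshwater/other-animal fresh organisms, marine/freshwater/other
processed ingredients, milk ingredients, and the per-species NPPU standard
deviations.  pandas does the CSV heavy lifting; this module adds

* header-name (order-insensitive) column mapping to safe internal
  identifiers — published headers contain "%" and "/";
* dialect sniffing on read (comma vs. semicolon delimiter, dot vs. comma
  decimals — the source files are French-origin) while the writer always
  emits canonical comma/dot/UTF-8;
* unit normalization: percent composition columns become g/kg internally
  (×10), transfer efficiency becomes a fraction (values above 1 are read
  as percent), both restored on write;
* semantic validation producing row-level findings rather than exceptions:
  g/kg vs. kg/kg NPPU consistency, TE in (0, 1], TL >= 1, composition
  percentages within [0, 100] summing to at most 101, non-negative SDs.

Absent values are empty cells on disk, never sentinel numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .composition import ProximateComposition
from .errors import SchemaError
from .trophic import TrophicParameters, SpeciesRecord

PathLike = Union[str, Path]

# column kinds and their unit handling:
#   text        verbatim strings
#   number      plain float (TL, SD, C_content, energies, factors, yields)
#   gkg_percent percent on disk, g/kg internally (x10 on read)
#   te          percent-or-fraction on disk, fraction internally
#   nppu_g      NPPU in g C/kg
#   nppu_kg     NPPU in kg C/kg; `pair` names the g/kg sibling column
_NUMERIC_KINDS = {"number", "gkg_percent", "te", "nppu_g", "nppu_kg"}


@dataclass(frozen=True)
class Column:
    header: str
    internal: str
    kind: str = "text"
    required: bool = False
    pair: Optional[str] = None  # internal name of the g/kg sibling (nppu_kg only)


@dataclass(frozen=True)
class TableSchema:
    schema_id: str
    columns: Tuple[Column, ...]

    def __post_init__(self) -> None:
        internals = [c.internal for c in self.columns]
        headers = [c.header for c in self.columns]
        if len(set(internals)) != len(internals) or len(set(headers)) != len(headers):
            raise SchemaError(f"duplicate column names in schema {self.schema_id}")

    @property
    def required(self) -> Tuple[Column, ...]:
        return tuple(c for c in self.columns if c.required)

    def by_internal(self, internal: str) -> Column:
        for c in self.columns:
            if c.internal == internal:
                return c
        raise KeyError(internal)


def _species_block() -> List[Column]:
    return [
        Column("Specie", "species", "text", required=True),
        Column("Common_name", "common_name"),
        Column("Common_name_FR", "common_name_fr"),
    ]


def _trophic_block() -> List[Column]:
    return [
        Column("Ecosystem", "ecosystem"),
        Column("Trophic_level", "trophic_level", "number", required=True),
        Column("Trophic_level_SD", "trophic_level_sd", "number"),
        Column("Transfer_efficiency", "transfer_efficiency", "te"),
        Column("Comment", "comment"),
    ]


def _composition_block(dry_matter: bool = False) -> List[Column]:
    cols = []
    if dry_matter:
        cols.append(Column("Dry_matter_%", "dry_matter", "gkg_percent"))
    cols += [
        Column("Moisture_%", "moisture", "gkg_percent"),
        Column("Protein_%", "protein", "gkg_percent"),
        Column("Fat_%", "lipid", "gkg_percent"),
        Column("Ash_%", "ash", "gkg_percent"),
        Column("Carbohydrates_%", "carbohydrate", "gkg_percent"),
    ]
    return cols


def _source_block() -> List[Column]:
    return [
        Column("Source_TL", "source_tl"),
        Column("Source_Body_Composition", "source_body_composition"),
        Column("Source_TE", "source_te"),
    ]


def _nppu_block() -> List[Column]:
    return [
        Column("C_content", "c_content", "number"),
        Column("NPPU_g/kg", "nppu_g", "nppu_g"),
        Column("NPPU_kg/kg", "nppu_kg", "nppu_kg", pair="nppu_g"),
    ]


def _fresh_schema(schema_id: str, dry_matter: bool) -> TableSchema:
    return TableSchema(
        schema_id,
        tuple(
            _species_block()
            + _trophic_block()
            + _composition_block(dry_matter)
            + _source_block()
            + _nppu_block()
        ),
    )


def _coproduct_block() -> List[Column]:
    return [
        Column("Yield_meal_generic", "yield_meal_generic", "number"),
        Column("Yield_oil_generic", "yield_oil_generic", "number"),
        Column("Yield_meal_specific", "yield_meal_specific", "number"),
        Column("Yield_oil_specific", "yield_oil_specific", "number"),
        Column("Energy_meal", "energy_meal", "number"),
        Column("Energy_oil", "energy_oil", "number"),
    ]


def _variant_block(tiers: Sequence[str]) -> List[Column]:
    cols: List[Column] = []
    for t in tiers:
        for y in ("1", "2"):  # 1 = generic yields, 2 = specific yields
            cols.append(
                Column(f"NPPU_mass_{t}{y}(kg/kg)", f"nppu_mass_{t.lower()}{y}", "nppu_kg")
            )
    for t in tiers:
        for y in ("1", "2"):
            cols.append(
                Column(
                    f"NPPU_meal_energy_{t}{y}(kg/kg)",
                    f"nppu_meal_energy_{t.lower()}{y}",
                    "nppu_kg",
                )
            )
            cols.append(
                Column(
                    f"NPPU_oil_energy_{t}{y}(kg/kg)",
                    f"nppu_oil_energy_{t.lower()}{y}",
                    "nppu_kg",
                )
            )
    return cols


def _ingredient_schema(schema_id: str, tiers: Sequence[str]) -> TableSchema:
    cols = _species_block()
    for t in tiers:
        cols.append(Column(f"NPPU_{t}(g/kg)", f"nppu_{t.lower()}_g", "nppu_g"))
        cols.append(
            Column(
                f"NPPU_{t}(kg/kg)", f"nppu_{t.lower()}_kg", "nppu_kg",
                pair=f"nppu_{t.lower()}_g",
            )
        )
    cols += _coproduct_block() + _variant_block(tiers)
    return TableSchema(schema_id, tuple(cols))


SCHEMAS: Dict[str, TableSchema] = {
    "plant": TableSchema(
        "plant",
        (
            Column("Feed_EN", "feed_en", "text", required=True),
            Column("Feed_FR", "feed_fr"),
            Column("Category", "category"),
            Column("Protein_%", "protein", "gkg_percent", required=True),
            Column("Fat_%", "lipid", "gkg_percent", required=True),
            Column("Ash_%", "ash", "gkg_percent", required=True),
            Column("Carbohydrates_%", "carbohydrate", "gkg_percent"),
            Column("C_content", "c_content", "number"),
            Column("NPPU_g/kg", "nppu_g", "nppu_g"),
            Column("NPPU_kg/kg", "nppu_kg", "nppu_kg", pair="nppu_g"),
            Column("Source", "source"),
        ),
    ),
    "marine_fresh": _fresh_schema("marine_fresh", dry_matter=False),
    "freshwater_fresh": _fresh_schema("freshwater_fresh", dry_matter=True),
    "other_animal_fresh": _fresh_schema("other_animal_fresh", dry_matter=True),
    "marine_ingredient": _ingredient_schema("marine_ingredient", ("T1", "T2", "T3")),
    "freshwater_ingredient": _ingredient_schema(
        "freshwater_ingredient", ("T1", "T2")
    ),
    "other_animal_ingredient": TableSchema(
        "other_animal_ingredient",
        (
            Column("Ingredient", "ingredient", "text", required=True),
            Column("Specie", "species"),
            Column("NPPU_T1(g/kg)", "nppu_t1_g", "nppu_g"),
            Column("NPPU_T1(kg/kg)", "nppu_t1_kg", "nppu_kg", pair="nppu_t1_g"),
            Column("Comment", "comment"),
        ),
    ),
    "milk": TableSchema(
        "milk",
        tuple(
            [
                Column("Ingredient", "species", "text", required=True),
                Column("Ingredient_FR", "common_name_fr"),
            ]
            + _trophic_block()[1:]  # no Ecosystem column in the milk layout
            + _composition_block()
            + _source_block()
            + _nppu_block()
        ),
    ),
    "nppu_sd": TableSchema(
        "nppu_sd",
        (
            Column("Specie", "species", "text", required=True),
            Column("Trophic_level", "trophic_level", "number"),
            Column("Trophic_level_SD", "trophic_level_sd", "number"),
            Column("Transfer_efficiency", "transfer_efficiency", "te"),
            Column("C_content", "c_content", "number"),
            Column("NPPU_g/kg", "nppu_g", "nppu_g"),
            Column("NPPU_kg/kg", "nppu_kg", "nppu_kg", pair="nppu_g"),
            Column("NPPU_SD_g/kg", "nppu_sd_g", "nppu_g"),
            Column("NPPU_SD_kg/kg", "nppu_sd_kg", "nppu_kg", pair="nppu_sd_g"),
        ),
    ),
}


@dataclass(frozen=True)
class Finding:
    """One validation finding; row is 0-based data-row index (None = table-level)."""

    rule: str
    severity: str  # {"error", "warning"}
    message: str
    row: Optional[int] = None
    column: Optional[str] = None


@dataclass
class ValidationReport:
    schema_id: str
    n_rows: int = 0
    findings: List[Finding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        """True iff no finding has severity 'error'."""
        return not any(f.severity == "error" for f in self.findings)

    @property
    def n_errors(self) -> int:
        return sum(f.severity == "error" for f in self.findings)

    @property
    def n_warnings(self) -> int:
        return sum(f.severity == "warning" for f in self.findings)

    def summary(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (
            f"{status} [{self.schema_id}]: {self.n_rows} rows, "
            f"{self.n_errors} errors, {self.n_warnings} warnings"
        )


def get_schema(schema_id: str) -> TableSchema:
    try:
        return SCHEMAS[schema_id]
    except KeyError:
        raise SchemaError(
            f"unknown schema {schema_id!r}; known: {sorted(SCHEMAS)}"
        ) from None


def _sniff_dialect(path: Path) -> Tuple[str, str]:
    """Return (delimiter, decimal) from the header line."""
    with open(path, "r", encoding="utf-8-sig") as fh:
        for line in fh:
            if line.strip():
                if line.count(";") > line.count(","):
                    return ";", ","
                return ",", "."
    return ",", "."


def _parse_cell(raw: str, decimal: str) -> float:
    s = raw.strip()
    if not s:
        return math.nan
    if decimal == ",":
        s = s.replace(",", ".")
    return float(s)


def _load(path: PathLike, schema: TableSchema) -> Tuple[pd.DataFrame, List[Finding]]:
    """Read a file into internal representation, collecting findings."""
    path = Path(path)
    findings: List[Finding] = []
    sep, decimal = _sniff_dialect(path)
    raw = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8-sig"
    )
    raw.columns = [c.strip() for c in raw.columns]

    for col in schema.required:
        if col.header not in raw.columns:
            findings.append(
                Finding(
                    "missing_required_column",
                    "error",
                    f"required column {col.header!r} absent",
                    column=col.header,
                )
            )

    n = len(raw)
    data: Dict[str, object] = {}
    for col in schema.columns:
        if col.header not in raw.columns:
            if col.kind in _NUMERIC_KINDS:
                data[col.internal] = np.full(n, np.nan)
            else:
                data[col.internal] = np.full(n, "", dtype=object)
            continue
        series = raw[col.header]
        if col.kind not in _NUMERIC_KINDS:
            data[col.internal] = series.to_numpy(dtype=object)
            continue
        values = np.full(n, np.nan)
        for i, cell in enumerate(series):
            try:
                values[i] = _parse_cell(cell, decimal)
            except ValueError:
                findings.append(
                    Finding(
                        "unparseable_cell",
                        "error",
                        f"cannot parse {cell!r} as a number",
                        row=i,
                        column=col.header,
                    )
                )
        if col.kind == "gkg_percent":
            values = values * 10.0  # percent -> g/kg
        elif col.kind == "te":
            values = np.where(values > 1.0, values / 100.0, values)
        data[col.internal] = values
    frame = pd.DataFrame(data, columns=[c.internal for c in schema.columns])
    return frame, findings


def read_table(path: PathLike, schema_id: str) -> pd.DataFrame:
    """Read a schema-conforming CSV into a normalized DataFrame.

    Columns are mapped by header name (order-insensitive) to internal
    identifiers; composition columns are in g/kg, TE is a fraction.

    Raises
    ------
    SchemaError
        On a missing required column or an unparseable numeric cell
        (the message names the column and row).
    """
    frame, findings = _load(path, get_schema(schema_id))
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        first = errors[0]
        where = f" (row {first.row})" if first.row is not None else ""
        raise SchemaError(
            f"{path}: {first.message} in column {first.column!r}{where}; "
            f"{len(errors)} error(s) total"
        )
    return frame


def write_table(frame: pd.DataFrame, path: PathLike, schema_id: str) -> None:
    """Write a normalized DataFrame as a canonical CSV (comma, dot, UTF-8).

    Internal units are converted back to the file dialect (g/kg -> percent,
    TE fraction -> percent) and every kg/kg NPPU column is re-derived from
    its g/kg sibling when present, so the emitted pair is exactly
    consistent.  Raises SchemaError before any bytes are written if a
    required column is absent or has missing values.
    """
    schema = get_schema(schema_id)
    for col in schema.required:
        if col.internal not in frame.columns:
            raise SchemaError(
                f"cannot write {schema_id}: required column {col.header!r} "
                f"({col.internal}) missing from input"
            )
        series = frame[col.internal]
        if col.kind in _NUMERIC_KINDS:
            bad = pd.isna(series)
        else:
            bad = pd.isna(series) | (series.astype(str).str.strip() == "")
        if bad.any():
            raise SchemaError(
                f"cannot write {schema_id}: required column {col.header!r} has "
                f"missing values (first at row {int(np.argmax(bad.to_numpy()))})"
            )

    out: Dict[str, object] = {}
    for col in schema.columns:
        if col.internal in frame.columns:
            series = pd.Series(frame[col.internal]).reset_index(drop=True)
        elif col.kind == "nppu_kg" and col.pair and col.pair in frame.columns:
            series = pd.Series(frame[col.pair]).reset_index(drop=True) / 1000.0
        else:
            series = pd.Series([np.nan] * len(frame))
        if col.kind == "nppu_kg" and col.pair and col.pair in frame.columns:
            g = pd.to_numeric(
                pd.Series(frame[col.pair]).reset_index(drop=True), errors="coerce"
            )
            series = series.where(g.isna(), g / 1000.0)
        if col.kind == "gkg_percent":
            series = pd.to_numeric(series, errors="coerce") / 10.0
        elif col.kind == "te":
            series = pd.to_numeric(series, errors="coerce") * 100.0
        out[col.header] = series
    pd.DataFrame(out).to_csv(path, index=False, encoding="utf-8", na_rep="")


_RULE_NPPU_PAIR_TOL_G = 0.5  # g/kg
_COMPOSITION_INTERNALS = ("moisture", "protein", "lipid", "ash", "carbohydrate")


def _validate_frame(frame: pd.DataFrame, schema: TableSchema) -> List[Finding]:
    findings: List[Finding] = []

    def col(name: str) -> Optional[pd.Series]:
        return frame[name] if name in frame.columns else None

    # NPPU g/kg vs kg/kg consistency, per declared pair
    for c in schema.columns:
        if c.kind == "nppu_kg" and c.pair and c.pair in frame.columns:
            g = frame[c.pair]
            kg = frame[c.internal]
            both = g.notna() & kg.notna()
            bad = both & ((g - 1000.0 * kg).abs() > _RULE_NPPU_PAIR_TOL_G)
            for i in np.flatnonzero(bad.to_numpy()):
                findings.append(
                    Finding(
                        "nppu_unit_consistency",
                        "error",
                        f"{c.header} != {schema.by_internal(c.pair).header}/1000 "
                        f"(difference beyond {_RULE_NPPU_PAIR_TOL_G} g/kg)",
                        row=int(i),
                        column=c.header,
                    )
                )

    te = col("transfer_efficiency")
    if te is not None:
        bad = te.notna() & ~((te > 0) & (te <= 1))
        for i in np.flatnonzero(bad.to_numpy()):
            findings.append(
                Finding(
                    "te_range", "error",
                    "transfer efficiency must lie in (0, 1] as a fraction",
                    row=int(i), column="Transfer_efficiency",
                )
            )

    tl = col("trophic_level")
    if tl is not None:
        bad = tl.notna() & (tl < 1)
        for i in np.flatnonzero(bad.to_numpy()):
            findings.append(
                Finding(
                    "tl_minimum", "error", "trophic level must be >= 1",
                    row=int(i), column="Trophic_level",
                )
            )

    comp_cols = [c for c in _COMPOSITION_INTERNALS if c in frame.columns]
    for name in comp_cols:
        series = frame[name]
        header = schema.by_internal(name).header
        bad = series.notna() & ~((series >= 0) & (series <= 1000.0))
        for i in np.flatnonzero(bad.to_numpy()):
            findings.append(
                Finding(
                    "composition_range", "error",
                    f"{header} must lie within [0, 100] percent",
                    row=int(i), column=header,
                )
            )
    if comp_cols:
        total = frame[comp_cols].sum(axis=1, min_count=1)
        bad = total.notna() & (total > 1010.0)  # 100 % + 1 % tolerance
        for i in np.flatnonzero(bad.to_numpy()):
            findings.append(
                Finding(
                    "composition_closure", "error",
                    "composition percentages sum above 100 + 1",
                    row=int(i), column=None,
                )
            )

    for name in ("trophic_level_sd", "nppu_sd_g", "nppu_sd_kg"):
        series = col(name)
        if series is None:
            continue
        header = schema.by_internal(name).header
        bad = series.notna() & (series < 0)
        for i in np.flatnonzero(bad.to_numpy()):
            findings.append(
                Finding(
                    "sd_nonnegative", "error",
                    f"{header} must be non-negative",
                    row=int(i), column=header,
                )
            )
    return findings


def validate_table(path: PathLike, schema_id: str) -> ValidationReport:
    """Validate a CSV against a schema's semantic rules.

    Never raises on content problems: structural and row-level issues are
    returned as findings.  A table passes iff no finding is an error.
    """
    schema = get_schema(schema_id)
    try:
        frame, findings = _load(path, schema)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        return ValidationReport(
            schema_id,
            findings=[Finding("unreadable_file", "error", str(exc))],
        )
    findings = list(findings) + _validate_frame(frame, schema)
    return ValidationReport(schema_id, n_rows=len(frame), findings=findings)


_FRESH_SCHEMAS = ("marine_fresh", "freshwater_fresh", "other_animal_fresh", "milk")


def frame_to_records(frame: pd.DataFrame, schema_id: str) -> List[SpeciesRecord]:
    """Convert a fresh-organism (or milk) frame to SpeciesRecord objects."""
    if schema_id not in _FRESH_SCHEMAS:
        raise SchemaError(
            f"records can be built from {_FRESH_SCHEMAS}, not {schema_id!r}"
        )
    records: List[SpeciesRecord] = []
    for _, row in frame.iterrows():
        def num(name: str) -> Optional[float]:
            v = row.get(name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return float(v)

        def text(name: str) -> str:
            v = row.get(name, "")
            return "" if v is None or (isinstance(v, float) and math.isnan(v)) else str(v)

        te = num("transfer_efficiency")
        tl = num("trophic_level")
        trophic = TrophicParameters(
            TL=tl if tl is not None else 1.0,
            TL_SD=num("trophic_level_sd") or 0.0,
            TE=te if te is not None else 0.10,
            ecosystem=text("ecosystem"),
        )
        comp_vals = {k: num(k) for k in _COMPOSITION_INTERNALS}
        if any(v is not None for v in comp_vals.values()):
            comp = ProximateComposition(
                protein=comp_vals["protein"] or 0.0,
                lipid=comp_vals["lipid"] or 0.0,
                ash=comp_vals["ash"] or 0.0,
                moisture=comp_vals["moisture"] or 0.0,
                carbohydrate=comp_vals["carbohydrate"] or 0.0,
                dry_matter=num("dry_matter"),
            )
        else:
            comp = None
        records.append(
            SpeciesRecord(
                species=text("species"),
                common_name=text("common_name"),
                common_name_fr=text("common_name_fr"),
                trophic=trophic,
                C_specific=num("c_content"),
                composition=comp,
                source_tl=text("source_tl"),
                source_body_composition=text("source_body_composition"),
                source_te=text("source_te"),
                comment=text("comment"),
            )
        )
    return records


def records_to_frame(
    records: Sequence[SpeciesRecord], schema_id: str
) -> pd.DataFrame:
    """Convert SpeciesRecord objects to a normalized frame for a fresh schema.

    NPPU columns are left empty; computation modules fill them.
    """
    schema = get_schema(schema_id)
    if schema_id not in _FRESH_SCHEMAS:
        raise SchemaError(
            f"records map onto {_FRESH_SCHEMAS}, not {schema_id!r}"
        )
    rows = []
    for r in records:
        comp = r.composition
        row = {
            "species": r.species,
            "common_name": r.common_name,
            "common_name_fr": r.common_name_fr,
            "ecosystem": r.trophic.ecosystem,
            "trophic_level": r.trophic.TL,
            "trophic_level_sd": r.trophic.TL_SD,
            "transfer_efficiency": r.trophic.TE,
            "comment": r.comment,
            "moisture": comp.moisture if comp else np.nan,
            "protein": comp.protein if comp else np.nan,
            "lipid": comp.lipid if comp else np.nan,
            "ash": comp.ash if comp else np.nan,
            "carbohydrate": comp.carbohydrate if comp else np.nan,
            "dry_matter": (
                comp.dry_matter
                if comp and comp.dry_matter is not None
                else (1000.0 - comp.moisture if comp else np.nan)
            ),
            "source_tl": r.source_tl,
            "source_body_composition": r.source_body_composition,
            "source_te": r.source_te,
            "c_content": r.C_specific if r.C_specific is not None else np.nan,
            "nppu_g": np.nan,
            "nppu_kg": np.nan,
        }
        rows.append(row)
    internals = [c.internal for c in schema.columns]
    if not rows:
        return pd.DataFrame(columns=internals)
    frame = pd.DataFrame(rows)
    return frame[[c for c in internals if c in frame.columns]]


def read_species_records(path: PathLike, schema_id: str) -> List[SpeciesRecord]:
    """Read a fresh-organism CSV directly into SpeciesRecord objects."""
    return frame_to_records(read_table(path, schema_id), schema_id)
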