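"""Reading and writing bioactivity tables and structure files.

Activity tables arrive either as ChEMBL-style CSV exports or as a simple
in-house CSV dialect.  All concentrations are normalised to molar units
internally; pIC50 = -log10(IC50 in molar) is the working potency scale.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable

from rdkit import Chem

ASSAY_TYPES = ("SP", "HEK", "CHO", "other")
RELATIONS = ("eq", "lt", "gt", "le", "ge")
UNIT_FACTORS = {"nM": 1e-9, "uM": 1e-6, "M": 1.0}

#: default mapping from assay annotations found in exports to assay types;
#: unknown tokens map to "other".
DEFAULT_ASSAY_MAP = {
    "SP": "SP",
    "SINGLE PROTEIN": "SP",
    "PATCH CLAMP": "SP",
    "HEK": "HEK",
    "HEK293": "HEK",
    "HEK-293": "HEK",
    "CHO": "CHO",
    "CHO-K1": "CHO",
}

_RELATION_TOKENS = {
    "=": "eq",
    "<": "lt",
    ">": "gt",
    "<=": "le",
    ">=": "ge",
    "eq": "eq",
    "lt": "lt",
    "gt": "gt",
    "le": "le",
    "ge": "ge",
}

_UNIT_ALIASES = {"nm": "nM", "um": "uM", "µm": "uM", "m": "M"}


class FormatError(ValueError):
    """A table cannot be read at all (missing columns, bad dialect)."""


def to_molar(value: float, units: str) -> float:
    """Convert a concentration to molar.

    Supported units: nM, uM, M.  Raises ValueError for non-positive values
    or unsupported unit tokens.
    """
    if not value > 0:
        raise ValueError(f"concentration must be positive, got {value!r}")
    try:
        return value * UNIT_FACTORS[units]
    except KeyError:
        raise ValueError(f"unsupported units {units!r}") from None


@dataclass(frozen=True)
class ActivityRecord:
    """One assay measurement of one compound."""

    compound_id: str
    smiles: str
    assay_type: str  # SP | HEK | CHO | other
    relation: str    # eq | lt | gt | le | ge
    value: float     # concentration in `units`
    units: str       # nM | uM | M
    pic50: float | None = None

    def __post_init__(self):
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"unknown assay type {self.assay_type!r}")
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if not self.value > 0:
            raise ValueError("value must be positive")
        if self.units not in UNIT_FACTORS:
            raise ValueError(f"unsupported units {self.units!r}")
        if self.pic50 is not None:
            expected = -math.log10(to_molar(self.value, self.units))
            if abs(self.pic50 - expected) > 1e-9:
                raise ValueError(
                    f"pic50 {self.pic50} inconsistent with value "
                    f"{self.value} {self.units} (expected {expected})"
                )

    @property
    def value_molar(self) -> float:
        return to_molar(self.value, self.units)

    def with_pic50(self) -> "ActivityRecord":
        return replace(self, pic50=-math.log10(self.value_molar))


@dataclass(frozen=True)
class Reject:
    """An unparseable input row kept for audit."""

    row_number: int
    reason: str
    raw: dict


@dataclass
class DatasetTable:
    """Ordered collection of activity records plus provenance."""

    records: list[ActivityRecord] = field(default_factory=list)
    provenance: str = ""
    rejects: list[Reject] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


_DIALECTS = {
    "chembl_csv": {
        "compound_id": "molecule_chembl_id",
        "smiles": "canonical_smiles",
        "assay_type": "assay_cell_type",
        "relation": "standard_relation",
        "value": "standard_value",
        "units": "standard_units",
    },
    "simple_csv": {
        "compound_id": "compound_id",
        "smiles": "smiles",
        "assay_type": "assay_type",
        "relation": "relation",
        "value": "value",
        "units": "units",
    },
}


def _parse_row(row: dict, cols: dict, assay_map: dict) -> ActivityRecord:
    smiles = (row.get(cols["smiles"]) or "").strip()
    if not smiles:
        raise ValueError("empty SMILES")
    rel_token = (row.get(cols["relation"]) or "=").strip() or "="
    relation = _RELATION_TOKENS.get(rel_token)
    if relation is None:
        raise ValueError(f"unknown relation token {rel_token!r}")
    raw_units = (row.get(cols["units"]) or "").strip()
    units = raw_units if raw_units in UNIT_FACTORS else _UNIT_ALIASES.get(raw_units.lower())
    if units is None:
        raise ValueError("unsupported units")
    try:
        value = float(row.get(cols["value"]) or "")
    except ValueError:
        raise ValueError(f"unparseable value {row.get(cols['value'])!r}") from None
    if not value > 0:
        raise ValueError("non-positive value")
    assay_token = (row.get(cols["assay_type"]) or "").strip().upper()
    assay = assay_map.get(assay_token, "other")
    pic50_raw = (row.get("pic50") or "").strip()
    pic50 = float(pic50_raw) if pic50_raw else None
    return ActivityRecord(
        compound_id=(row.get(cols["compound_id"]) or "").strip(),
        smiles=smiles,
        assay_type=assay,
        relation=relation,
        value=value,
        units=units,
        pic50=pic50,
    )


def read_activity_table(
    source: str | Path | IO[str],
    dialect: str = "simple_csv",
    assay_map: dict | None = None,
) -> DatasetTable:
    """Read a bioactivity CSV table.

    Unparseable rows are never silently dropped: each ends up in
    ``table.rejects`` with a reason.  A missing required column raises
    :class:`FormatError`.
    """
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    cols = _DIALECTS[dialect]
    amap = {k.upper(): v for k, v in (assay_map or DEFAULT_ASSAY_MAP).items()}

    if hasattr(source, "read"):
        handle, own = source, False
    else:
        handle, own = open(source, newline="", encoding="utf-8"), True
    try:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise FormatError("empty file: no header row")
        missing = [c for c in cols.values() if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"missing required columns for {dialect}: {missing}")
        table = DatasetTable(provenance=f"dialect={dialect}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                table.records.append(_parse_row(row, cols, amap))
            except ValueError as exc:
                table.rejects.append(Reject(row_number=i, reason=str(exc), raw=dict(row)))
        return table
    finally:
        if own:
            handle.close()


def write_dataset(table: DatasetTable, dest: str | Path, format: str = "csv") -> None:
    """Write a table as CSV, SMILES (.smi) or SDF.

    CSV and SDF round-trip every record field; .smi keeps smiles + id only.
    Every record must carry a SMILES string.
    """
    for rec in table.records:
        if not rec.smiles:
            raise ValueError("record with empty SMILES cannot be written")
    dest = Path(dest)
    if format == "csv":
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["compound_id", "smiles", "assay_type", "relation", "value", "units", "pic50"]
            )
            for r in table.records:
                writer.writerow(
                    [r.compound_id, r.smiles, r.assay_type, r.relation,
                     repr(r.value), r.units, "" if r.pic50 is None else repr(r.pic50)]
                )
    elif format == "smi":
        with open(dest, "w", encoding="utf-8") as fh:
            for r in table.records:
                fh.write(f"{r.smiles}\t{r.compound_id}\n")
    elif format == "sdf":
        writer = Chem.SDWriter(str(dest))
        try:
            for r in table.records:
                mol = Chem.MolFromSmiles(r.smiles)
                if mol is None:
                    raise ValueError(f"unwritable SMILES {r.smiles!r}")
                mol.SetProp("_Name", r.compound_id)
                mol.SetProp("compound_id", r.compound_id)
                mol.SetProp("smiles", r.smiles)
                mol.SetProp("assay_type", r.assay_type)
                mol.SetProp("relation", r.relation)
                mol.SetProp("value", repr(r.value))
                mol.SetProp("units", r.units)
                if r.pic50 is not None:
                    mol.SetProp("pic50", repr(r.pic50))
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise ValueError(f"unknown format {format!r}")


def read_sdf(source: str | Path) -> DatasetTable:
    """Read records back from an SDF written by :func:`write_dataset`."""
    table = DatasetTable(provenance="sdf")
    for mol in Chem.SDMolSupplier(str(source)):
        if mol is None:
            continue
        pic50 = float(mol.GetProp("pic50")) if mol.HasProp("pic50") else None
        table.records.append(
            ActivityRecord(
                compound_id=mol.GetProp("compound_id"),
                smiles=mol.GetProp("smiles"),
                assay_type=mol.GetProp("assay_type"),
                relation=mol.GetProp("relation"),
                value=float(mol.GetProp("value")),
                units=mol.GetProp("units"),
                pic50=pic50,
            )
        )
    return table


def records_from_rows(rows: Iterable[tuple]) -> DatasetTable:
    """Build a table from (id, smiles, assay, relation, value, units) tuples."""
    return DatasetTable(records=[ActivityRecord(*row) for row in rows])
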