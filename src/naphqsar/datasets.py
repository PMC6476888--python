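"""Activity table parsing and analytics for the anilide series.

The packaged dataset is the printed IC50 table of the 102-compound
1-hydroxynaphthalene-2-carboxanilide series: three cell lines
(HCT116 p53+/+, HCT116 p53-/-, NHDF), values in uM, with ">25" marking
activities beyond the tested range (right-censored) and empty cells marking
compounds never assayed on that line.  Compound structures are rebuilt from
the common scaffold plus the substituent codes of the table.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from rdkit import Chem

#: canonical cell-line labels, in table order
CELL_LINES = ("HCT116+/+", "HCT116-/-", "NHDF")

#: CSV column name for each cell line
_LINE_COLUMNS = {
    "HCT116+/+": "hct116_wt",
    "HCT116-/-": "hct116_null",
    "NHDF": "nhdf",
}

#: substituent group codes allowed on the anilide ring, and their SMILES
GROUP_SMILES = {
    "OCH3": "OC",
    "CH3": "C",
    "F": "F",
    "Cl": "Cl",
    "Br": "Br",
    "CF3": "C(F)(F)F",
    "NO2": "[N+](=O)[O-]",
    "H": "",
}

#: censoring threshold of the assay, uM
CENSOR_THRESHOLD_UM = 25.0

SCAFFOLD_SMILES = "Oc1c(ccc2ccccc12)C(=O)Nc1ccccc1"


class ParseError(ValueError):
    """Malformed cell or header in an activity table."""


class ValidationError(ValueError):
    """Table content violates a dataset invariant (e.g. duplicate id)."""


@dataclass(frozen=True)
class ActivityValue:
    """One assay outcome: a numeric IC50 [uM], a '>25' censor, or missing.

    Exactly one of the three states holds.  ``sd`` keeps the printed
    plus/minus uncertainty; it is stored but never propagated into models.
    """

    ic50: float | None = None
    censored: bool = False
    missing: bool = False
    sd: float | None = None

    def __post_init__(self) -> None:
        states = sum([self.ic50 is not None, self.censored, self.missing])
        if states != 1:
            raise ValidationError(
                f"ActivityValue must be exactly one of numeric/censored/missing, got {self!r}"
            )
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValidationError(f"IC50 must be positive, got {self.ic50}")

    @property
    def is_numeric(self) -> bool:
        return self.ic50 is not None


@dataclass(frozen=True)
class CompoundRecord:
    """One table row: id, substituent pattern, and per-line activities."""

    id: str
    series: int
    substituent_code: str
    substituents: tuple[tuple[int, str], ...]
    activities: dict[str, ActivityValue] = field(default_factory=dict)
    smiles: str | None = None

    def with_smiles(self) -> "CompoundRecord":
        return replace(self, smiles=build_smiles(self))


def parse_substituent_code(code: str) -> tuple[tuple[int, str], ...]:
    """Expand a code like ``2-Cl-3,5-CF3`` into ((2,'Cl'),(3,'CF3'),(5,'CF3')).

    Positions refer to the anilide ring (2-6); a position list shared by one
    group ("3,5-CF3") replicates the group.  The bare code "H" means the
    unsubstituted parent.
    """
    code = code.strip()
    if code == "H":
        return ()
    tokens = code.split("-")
    subs: list[tuple[int, str]] = []
    i = 0
    while i < len(tokens):
        if not re.fullmatch(r"\d(,\d)*", tokens[i]):
            raise ParseError(f"expected ring positions in {code!r} at {tokens[i]!r}")
        if i + 1 >= len(tokens):
            raise ParseError(f"positions without a group in {code!r}")
        group = tokens[i + 1]
        if group not in GROUP_SMILES or group == "H":
            allowed = sorted(g for g in GROUP_SMILES if g != "H")
            raise ParseError(f"unknown group {group!r} in {code!r}; allowed: {allowed}")
        for pos in tokens[i].split(","):
            p = int(pos)
            if not 2 <= p <= 6:
                raise ValidationError(f"ring position {p} outside 2-6 in {code!r}")
            subs.append((p, group))
        i += 2
    positions = [p for p, _ in subs]
    if len(positions) != len(set(positions)):
        raise ValidationError(f"duplicate ring position in {code!r}")
    return tuple(subs)


def _parse_cell(cell: str, row_id: str, column: str) -> tuple[float | None, bool, bool]:
    cell = cell.strip()
    if cell == "":
        return None, False, True
    if cell.startswith(">"):
        return None, True, False
    try:
        return float(cell), False, False
    except ValueError as exc:
        raise ParseError(f"malformed cell {cell!r} at row {row_id!r}, column {column!r}") from exc


def packaged_table_path() -> Path:
    """Path of the CSV shipped with the package."""
    return Path(resources.files("naphqsar").joinpath("data/activity_table.csv"))


def parse_activity_table(path: str | Path | None = None) -> list[CompoundRecord]:
    """Read an activity CSV into validated CompoundRecords.

    ``None`` loads the packaged table.  Columns ``{id, substituent_code,
    hct116_wt, hct116_null, nhdf}`` are required; ``*_sd`` columns carry the
    printed uncertainties and are optional.
    """
    path = packaged_table_path() if path is None else Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "substituent_code", *_LINE_COLUMNS.values()}
    if not required.issubset(df.columns):
        raise ParseError(f"missing columns: {sorted(required - set(df.columns))}")
    if df["id"].duplicated().any():
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise ValidationError(f"duplicate compound ids: {dupes}")
    records = []
    for _, row in df.iterrows():
        rid = row["id"]
        activities = {}
        for line, col in _LINE_COLUMNS.items():
            ic50, censored, missing = _parse_cell(row[col], rid, col)
            sd_col = f"{col}_sd"
            sd = None
            if sd_col in df.columns and row[sd_col].strip():
                sd = float(row[sd_col])
            activities[line] = ActivityValue(ic50=ic50, censored=censored, missing=missing, sd=sd)
        records.append(
            CompoundRecord(
                id=rid,
                series=int(rid[0]),
                substituent_code=row["substituent_code"],
                substituents=parse_substituent_code(row["substituent_code"]),
                activities=activities,
            )
        )
    return records


def write_activity_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Serialize records back to the CSV interface (round-trips with parse)."""
    rows = []
    for rec in records:
        row: dict[str, str] = {"id": rec.id, "substituent_code": rec.substituent_code}
        for line, col in _LINE_COLUMNS.items():
            val = rec.activities[line]
            if val.missing:
                row[col] = ""
            elif val.censored:
                row[col] = ">25"
            else:
                row[col] = repr(val.ic50)
            row[f"{col}_sd"] = "" if val.sd is None else repr(val.sd)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def build_smiles(record: CompoundRecord | str) -> str:
    """Canonical SMILES of the N-(substituted-phenyl) carboxamide.

    Accepts a record or a bare substituent code.  The anilide ring is written
    ipso-first so coded positions 2-6 map onto successive ring atoms.
    """
    subs = record.substituents if isinstance(record, CompoundRecord) else parse_substituent_code(record)
    by_pos = dict(subs)
    ring = ["c1"]
    for pos in (2, 3, 4, 5):
        g = GROUP_SMILES[by_pos.get(pos, "H")]
        ring.append(f"c({g})" if g else "c")
    g6 = GROUP_SMILES[by_pos.get(6, "H")]
    ring.append(f"c1{g6}")
    smiles = "O=C(N" + "".join(ring) + ")c1ccc2ccccc2c1O"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - construction is total over the code set
        raise ValidationError(f"internal error: generated SMILES does not parse: {smiles}")
    return Chem.MolToSmiles(mol)


class PActivity(NamedTuple):
    value: float
    censored: bool


def to_p_activity(value: ActivityValue, censor_policy: str = "clamp-at-25") -> PActivity | None:
    """Convert to pIC50 = -log10(IC50 in M).

    Censored ">25" entries are clamped to 25 uM (flag retained) or excluded;
    missing entries are always excluded (``None``).
    """
    if censor_policy not in ("clamp-at-25", "exclude"):
        raise ValueError(f"unknown censor policy {censor_policy!r}")
    if value.missing:
        return None
    if value.censored:
        if censor_policy == "exclude":
            return None
        return PActivity(-math.log10(CENSOR_THRESHOLD_UM * 1e-6), True)
    if value.ic50 <= 0:
        raise ValueError(f"non-positive IC50 {value.ic50}")
    return PActivity(-math.log10(value.ic50 * 1e-6), False)


def activity_vector(
    records: Iterable[CompoundRecord],
    line: str = "HCT116+/+",
    censor_policy: str = "clamp-at-25",
) -> pd.Series:
    """pIC50 series indexed by compound id (policy-excluded entries dropped)."""
    out = {}
    for rec in records:
        p = to_p_activity(rec.activities[line], censor_policy)
        if p is not None:
            out[rec.id] = p.value
    return pd.Series(out, name=f"pIC50[{line}]")


class Selectivity(NamedTuple):
    ratio: float
    lower_bound: bool


def selectivity_index(record: CompoundRecord, numerator: str, denominator: str) -> Selectivity:
    """IC50 ratio between two lines (e.g. NHDF / HCT116+/+ for compound 8c).

    A censored numerator yields a lower bound (">25 / x") with the flag set.
    """
    num, den = record.activities[numerator], record.activities[denominator]
    if num.missing or den.missing or den.censored:
        raise ValueError(
            f"selectivity undefined for {record.id}: {numerator}={num!r}, {denominator}={den!r}"
        )
    if num.censored:
        return Selectivity(CENSOR_THRESHOLD_UM / den.ic50, True)
    return Selectivity(num.ic50 / den.ic50, False)


def censoring_summary(records: list[CompoundRecord]) -> dict[str, float]:
    """Per-line percentage of non-numeric (censored + missing) entries."""
    if not records:
        raise ValueError("empty record list")
    out = {}
    for line in CELL_LINES:
        bad = sum(1 for r in records if not r.activities[line].is_numeric)
        out[line] = 100.0 * bad / len(records)
    return out


def count_active(records: Iterable[CompoundRecord], line: str, threshold_um: float) -> int:
    """Number of compounds with numeric IC50 strictly below ``threshold_um``."""
    if threshold_um <= 0:
        return 0
    return sum(
        1
        for r in records
        if r.activities[line].is_numeric and r.activities[line].ic50 < threshold_um
    )


def export_smi(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write an id<TAB>smiles .smi file (SMILES built on the fly if absent)."""
    with open(path, "w") as fh:
        for rec in records:
            smi = rec.smiles or build_smiles(rec)
            fh.write(f"{rec.id}\t{smi}\n")
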