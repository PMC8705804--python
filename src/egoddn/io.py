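"""Readers and writers for every table and network format the pipeline touches.

All tabular formats are plain text: TSV for data tables (summary statistics,
edge lists, genotype dosages, diagnoses), CSV for metadata tables (phenotype
info, ICD->PheCode map).  The delimiter is chosen from the file extension
alone, never sniffed.  Floats are serialized to 6 significant digits, switching
to scientific notation below 1e-4, so that outputs are byte-stable and
diffable.  Every reader validates its schema and raises :class:`SchemaError`
(missing/unknown structure) or :class:`RecordError` (row-level invariant
violation, with a line number).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A file does not have the expected columns or format."""


class RecordError(ValueError):
    """A row violates a field invariant; message carries the line number."""


# ---------------------------------------------------------------------------
# float formatting


def fmt_float(x: float) -> str:
    """Format a float with 6 significant digits.

    Scientific notation is used below 1e-4 in magnitude so that small
    p-values stay readable and round-trippable.
    """
    if x == 0:
        return "0"
    if abs(x) < 1e-4:
        return f"{x:.5e}"
    return f"{x:.6g}"


def _delimiter_for(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".txt"}:
        return "\t"
    if suffix == ".csv":
        return ","
    raise SchemaError(f"cannot infer delimiter from extension {suffix!r}; use .tsv or .csv")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, slots=True)
class SummaryStatRecord:
    """One phenotype-variant association from a PheWAS summary table."""

    phecode: str
    snp_id: str
    chrom: str
    pos: int
    pvalue: float
    maf: float
    n_cases: int

    def validate(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise RecordError(f"pvalue out of range (0,1]: {self.pvalue}")
        if not (0 < self.maf <= 0.5):
            raise RecordError(f"maf out of range (0,0.5]: {self.maf}")
        if self.pos < 1:
            raise RecordError(f"pos must be >= 1: {self.pos}")
        if self.n_cases < 0:
            raise RecordError(f"n_cases must be non-negative: {self.n_cases}")
        if not self.phecode or not self.snp_id:
            raise RecordError("phecode and snp_id must be non-empty")


SEX_SPECIFIC_VALUES = ("none", "male", "female")


@dataclass(frozen=True, slots=True)
class PhenotypeInfo:
    """Metadata for one PheCode phenotype."""

    phecode: str
    name: str
    category: str
    sex_specific: str = "none"

    def validate(self) -> None:
        if not self.phecode:
            raise RecordError("phecode must be non-empty")
        if not self.category:
            raise RecordError("category must be non-empty")
        if self.sex_specific not in SEX_SPECIFIC_VALUES:
            raise RecordError(
                f"sex_specific must be one of {SEX_SPECIFIC_VALUES}: {self.sex_specific!r}"
            )


CODE_SYSTEMS = ("ICD9", "ICD10", "PheCode")


@dataclass(frozen=True, slots=True)
class DiagnosisRecord:
    """One diagnosis event: a person received a code in some coding system."""

    person_id: str
    code: str
    code_system: str

    def validate(self) -> None:
        if not self.person_id:
            raise RecordError("person_id must be non-empty")
        if not self.code:
            raise RecordError("code must be non-empty")
        if self.code_system not in CODE_SYSTEMS:
            raise RecordError(
                f"code_system must be one of {CODE_SYSTEMS}: {self.code_system!r}"
            )


@dataclass(frozen=True, slots=True)
class IcdPhecodeMapEntry:
    """One row of an ICD -> PheCode mapping (one ICD code may map to many)."""

    icd_code: str
    icd_version: int
    phecode: str

    def validate(self) -> None:
        if not self.icd_code or not self.phecode:
            raise RecordError("icd_code and phecode must be non-empty")
        if self.icd_version not in (9, 10):
            raise RecordError(f"icd_version must be 9 or 10: {self.icd_version}")


@dataclass
class GenotypeMatrix:
    """Person x SNP dosage matrix with 0/1/2 entries (no missing values)."""

    person_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # shape (n_persons, n_snps), dtype integer

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.person_ids), len(self.snp_ids)):
            raise RecordError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.person_ids)} persons x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise RecordError(
                f"dosage out of range {{0,1,2}}: value {self.dosages[i, j]} "
                f"for person {self.person_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    def column(self, snp_id: str) -> np.ndarray:
        try:
            j = self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None
        return self.dosages[:, j]


# ---------------------------------------------------------------------------
# generic table plumbing


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    sep = _delimiter_for(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty (expected a header line)") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _parse(value: str, kind: type, column: str, line: int):
    try:
        if kind is float:
            return float(value)
        if kind is int:
            # reject floats masquerading as ints ("3.5" for pos)
            return int(value)
        return value
    except ValueError:
        raise RecordError(
            f"line {line}: cannot parse {column}={value!r} as {kind.__name__}"
        ) from None


def _validated(record, line: int):
    try:
        record.validate()
    except RecordError as exc:
        raise RecordError(f"line {line}: {exc}") from None
    return record


# ---------------------------------------------------------------------------
# summary statistics


SUMMARY_COLUMNS = ("phecode", "snp_id", "chrom", "pos", "pvalue", "maf", "n_cases")


def read_summary_stats(path: str | Path) -> list[SummaryStatRecord]:
    """Read a PheWAS-style summary association TSV.

    Row order is preserved; (phecode, snp_id) must be unique within the file.
    """
    df = _read_table(path, SUMMARY_COLUMNS)
    records: list[SummaryStatRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rec = SummaryStatRecord(
            phecode=row.phecode,
            snp_id=row.snp_id,
            chrom=row.chrom,
            pos=_parse(row.pos, int, "pos", line),
            pvalue=_parse(row.pvalue, float, "pvalue", line),
            maf=_parse(row.maf, float, "maf", line),
            n_cases=_parse(row.n_cases, int, "n_cases", line),
        )
        _validated(rec, line)
        key = (rec.phecode, rec.snp_id)
        if key in seen:
            raise RecordError(f"line {line}: duplicate (phecode, snp_id) pair {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(SUMMARY_COLUMNS) + "\n")
        for r in records:
            fh.write(
                sep.join(
                    (
                        r.phecode,
                        r.snp_id,
                        r.chrom,
                        str(r.pos),
                        fmt_float(r.pvalue),
                        fmt_float(r.maf),
                        str(r.n_cases),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# phenotype info


PHENOTYPE_COLUMNS = ("phecode", "name", "category", "sex_specific")


def read_phenotype_info(path: str | Path) -> list[PhenotypeInfo]:
    df = _read_table(path, PHENOTYPE_COLUMNS)
    out: list[PhenotypeInfo] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        rec = _validated(
            PhenotypeInfo(row.phecode, row.name, row.category, row.sex_specific), line
        )
        if rec.phecode in seen:
            raise RecordError(f"line {line}: duplicate phecode {rec.phecode!r}")
        seen.add(rec.phecode)
        out.append(rec)
    return out


def write_phenotype_info(phenos: Iterable[PhenotypeInfo], path: str | Path) -> None:
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(PHENOTYPE_COLUMNS) + "\n")
        for p in phenos:
            fh.write(sep.join((p.phecode, p.name, p.category, p.sex_specific)) + "\n")


# ---------------------------------------------------------------------------
# diagnoses


DIAGNOSIS_COLUMNS = ("person_id", "code", "code_system")


def read_diagnoses(path: str | Path) -> list[DiagnosisRecord]:
    df = _read_table(path, DIAGNOSIS_COLUMNS)
    return [
        _validated(DiagnosisRecord(row.person_id, row.code, row.code_system), i + 2)
        for i, row in enumerate(df.itertuples(index=False))
    ]


def write_diagnoses(records: Iterable[DiagnosisRecord], path: str | Path) -> None:
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(DIAGNOSIS_COLUMNS) + "\n")
        for r in records:
            fh.write(sep.join((r.person_id, r.code, r.code_system)) + "\n")


# ---------------------------------------------------------------------------
# ICD -> PheCode map


MAP_COLUMNS = ("icd_code", "icd_version", "phecode")


def read_phecode_map(path: str | Path) -> list[IcdPhecodeMapEntry]:
    df = _read_table(path, MAP_COLUMNS)
    return [
        _validated(
            IcdPhecodeMapEntry(
                row.icd_code, _parse(row.icd_version, int, "icd_version", i + 2), row.phecode
            ),
            i + 2,
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def write_phecode_map(entries: Iterable[IcdPhecodeMapEntry], path: str | Path) -> None:
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(MAP_COLUMNS) + "\n")
        for e in entries:
            fh.write(sep.join((e.icd_code, str(e.icd_version), e.phecode)) + "\n")


# ---------------------------------------------------------------------------
# genotype matrix (TSV: person_id index column, one column per SNP)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    sep = _delimiter_for(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.columns[0] != "person_id":
        raise SchemaError(f"{path}: first column must be 'person_id'")
    snp_ids = list(df.columns[1:])
    person_ids = df["person_id"].tolist()
    try:
        dosages = df.iloc[:, 1:].to_numpy(dtype=np.int64) if snp_ids else np.zeros(
            (len(person_ids), 0), dtype=np.int64
        )
    except ValueError as exc:
        raise RecordError(f"{path}: unparseable dosage value ({exc})") from None
    return GenotypeMatrix(person_ids, snp_ids, dosages)


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["person_id", *g.snp_ids]) + "\n")
        for pid, row in zip(g.person_ids, g.dosages):
            fh.write(pid + sep + sep.join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# disease-SNP matrix (sparse triplet TSV {phecode, snp_id})


def write_matrix_triplets(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write a binary disease-SNP matrix as sorted (phecode, snp_id) pairs."""
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path, "w") as fh:
        fh.write(sep.join(("phecode", "snp_id")) + "\n")
        for phecode, snp_id in sorted(set(pairs)):
            fh.write(phecode + sep + snp_id + "\n")


def read_matrix_triplets(path: str | Path) -> list[tuple[str, str]]:
    df = _read_table(path, ("phecode", "snp_id"))
    return [(row.phecode, row.snp_id) for row in df.itertuples(index=False)]
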