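"""Reading, validation and filtering of peptide identification tables and FASTA databases.

The canonical in-memory model is :class:`PeptideTable`: a list of
:class:`PeptideRecord` plus an ordered list of sample identifiers. Tables are
read from tab-separated peptide identification files in the MaxQuant
``peptides.txt`` dialect (configurable via :class:`TableDialect`) and written
back as TSV, so a round trip preserves sequences, flags and intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "CANONICAL_AA",
    "PeptideRecord",
    "PeptideTable",
    "ProteinDB",
    "TableDialect",
    "FilterReport",
    "PeptideTableFormatError",
    "read_peptide_table",
    "write_peptide_table",
    "read_fasta",
    "write_fasta",
    "filter_peptides",
]


class PeptideTableFormatError(ValueError):
    """Raised when an input table or FASTA file violates the expected format."""


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = set(seq) - CANONICAL_AA
    if bad:
        raise ValueError(
            f"non-canonical residue(s) {sorted(bad)} in sequence {seq!r}; "
            "only the 20 canonical amino-acid letters are supported"
        )


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide: sequence, protein accessions, per-sample intensity, flags."""

    sequence: str
    proteins: tuple[str, ...] = ()
    intensity: Mapping[str, float] = field(default_factory=dict)
    is_reverse: bool = False
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        for sample, value in self.intensity.items():
            if value < 0:
                raise ValueError(
                    f"negative intensity {value} for sample {sample!r} "
                    f"on peptide {self.sequence!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideTable:
    """A set of peptide records together with the ordered sample axis."""

    records: tuple[PeptideRecord, ...]
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        known = set(self.samples)
        for rec in self.records:
            extra = set(rec.intensity) - known
            if extra:
                raise ValueError(
                    f"record {rec.sequence!r} carries intensities for unknown "
                    f"sample(s) {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


@dataclass(frozen=True)
class ProteinDB:
    """Accession → amino-acid sequence map for the substrate protein database."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for acc, seq in self.entries.items():
            try:
                _validate_sequence(seq)
            except ValueError as exc:
                raise PeptideTableFormatError(f"entry {acc!r}: {exc}") from exc

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, accession: str) -> str:
        return self.entries[accession]


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for a peptide identification table.

    Defaults follow the MaxQuant ``peptides.txt`` convention: flag columns
    contain a marker character (``+``) when set, and per-sample intensity
    columns are named ``Intensity <sample>``.
    """

    sequence: str = "Sequence"
    proteins: str = "Proteins"
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"
    intensity_prefix: str = "Intensity "
    flag_marker: str = "+"
    protein_sep: str = ";"


@dataclass(frozen=True)
class FilterReport:
    """Per-reason removal counts produced by :func:`filter_peptides`."""

    n_input: int
    n_retained: int
    removed_reverse: int = 0
    removed_contaminant: int = 0
    removed_too_short: int = 0
    removed_too_long: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.removed_reverse
            + self.removed_contaminant
            + self.removed_too_short
            + self.removed_too_long
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def read_peptide_table(
    path: str | Path, dialect: TableDialect | None = None
) -> PeptideTable:
    """Parse a tab-separated peptide identification table into a :class:`PeptideTable`.

    Empty intensity cells are read as 0. A missing mapped column raises
    :class:`PeptideTableFormatError` naming the column; rows with non-canonical
    residues raise a row-level error listing the offending rows.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (dialect.sequence, dialect.proteins):
        if col not in df.columns:
            raise PeptideTableFormatError(
                f"required column {col!r} missing from {path}"
            )
    intensity_cols = [
        c for c in df.columns if c.startswith(dialect.intensity_prefix)
    ]
    samples = tuple(c[len(dialect.intensity_prefix):] for c in intensity_cols)

    bad_rows: list[tuple[int, str]] = []
    records: list[PeptideRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        seq = row_d[dialect.sequence].strip().upper()
        if not seq or set(seq) - CANONICAL_AA:
            bad_rows.append((idx, seq))
            continue
        proteins = tuple(
            p for p in row_d[dialect.proteins].split(dialect.protein_sep) if p
        )
        intensity = {}
        for col, sample in zip(intensity_cols, samples):
            cell = row_d[col].strip()
            intensity[sample] = float(cell) if cell else 0.0
        records.append(
            PeptideRecord(
                sequence=seq,
                proteins=proteins,
                intensity=intensity,
                is_reverse=row_d.get(dialect.reverse, "") == dialect.flag_marker,
                is_contaminant=row_d.get(dialect.contaminant, "")
                == dialect.flag_marker,
            )
        )
    if bad_rows:
        shown = ", ".join(f"row {i}: {s!r}" for i, s in bad_rows[:10])
        raise PeptideTableFormatError(
            f"{len(bad_rows)} row(s) with empty or non-canonical sequences: {shown}"
        )
    return PeptideTable(records=tuple(records), samples=samples)


def write_peptide_table(
    table: PeptideTable, path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Write a table as TSV in the same dialect :func:`read_peptide_table` consumes."""
    dialect = dialect or TableDialect()
    rows = []
    for rec in table.records:
        row = {
            dialect.sequence: rec.sequence,
            dialect.proteins: dialect.protein_sep.join(rec.proteins),
            dialect.reverse: dialect.flag_marker if rec.is_reverse else "",
            dialect.contaminant: dialect.flag_marker if rec.is_contaminant else "",
        }
        for sample in table.samples:
            value = rec.intensity.get(sample, 0.0)
            row[dialect.intensity_prefix + sample] = repr(value)
        rows.append(row)
    columns = [dialect.sequence, dialect.proteins, dialect.reverse, dialect.contaminant]
    columns += [dialect.intensity_prefix + s for s in table.samples]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> ProteinDB:
    """Read a protein FASTA file; the header token before the first whitespace is the accession."""
    entries: dict[str, str] = {}
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        accession = record.id
        if accession in entries:
            raise PeptideTableFormatError(f"duplicate accession {accession!r}")
        entries[accession] = str(record.seq).upper()
    if n == 0:
        raise PeptideTableFormatError(f"no FASTA records in {path}")
    return ProteinDB(entries=entries)


def write_fasta(db: ProteinDB, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for accession, seq in db.entries.items():
            fh.write(f">{accession}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def filter_peptides(
    table: PeptideTable,
    min_len: int = 3,
    max_len: int = 65,
    drop_flags: bool = True,
) -> tuple[PeptideTable, FilterReport]:
    """Remove reverse/contaminant hits and out-of-range lengths.

    Flag precedence: reverse first, then contaminant, then length, so each
    removed record is counted under exactly one reason and the report counts
    sum to the input size. Idempotent: filtering a filtered table is a no-op.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    kept: list[PeptideRecord] = []
    n_rev = n_con = n_short = n_long = 0
    for rec in table.records:
        if drop_flags and rec.is_reverse:
            n_rev += 1
        elif drop_flags and rec.is_contaminant:
            n_con += 1
        elif len(rec) < min_len:
            n_short += 1
        elif len(rec) > max_len:
            n_long += 1
        else:
            kept.append(rec)
    report = FilterReport(
        n_input=len(table.records),
        n_retained=len(kept),
        removed_reverse=n_rev,
        removed_contaminant=n_con,
        removed_too_short=n_short,
        removed_too_long=n_long,
    )
    return PeptideTable(records=tuple(kept), samples=table.samples), report


def collapse_duplicates(table: PeptideTable) -> PeptideTable:
    """Collapse duplicate sequences to one record per peptide, summing intensities."""
    merged: dict[str, PeptideRecord] = {}
    order: list[str] = []
    for rec in table.records:
        if rec.sequence not in merged:
            merged[rec.sequence] = rec
            order.append(rec.sequence)
        else:
            prev = merged[rec.sequence]
            intensity = dict(prev.intensity)
            for sample, value in rec.intensity.items():
                intensity[sample] = intensity.get(sample, 0.0) + value
            merged[rec.sequence] = replace(
                prev,
                proteins=tuple(dict.fromkeys(prev.proteins + rec.proteins)),
                intensity=intensity,
            )
    return PeptideTable(
        records=tuple(merged[s] for s in order), samples=table.samples
    )
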