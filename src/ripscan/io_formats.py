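"""Readers and writers for the file formats the pipeline exchanges.

Every downstream stage consumes only the types defined here: FASTA locus
sequences and repeat libraries, and tab-separated genotype, primer and
trait tables.  All text I/O is UTF-8.  Genotype symbols are normalized to
ASCII internally ("+/-", "-/-"); the Unicode minus sign U+2212, which
appears in typeset tables, is accepted on input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = set("ACGTN")

#: canonical genotype symbols: insertion homozygote, heterozygote, empty homozygote
GENOTYPE_SYMBOLS = ("+/+", "+/-", "-/-")

#: number of copies of the insertion allele carried by each genotype
GENOTYPE_DOSE = {"+/+": 2, "+/-": 1, "-/-": 0}

GENOTYPE_COLUMNS = ["individual_id", "breed", "locus", "genotype"]
TRAIT_COLUMNS = ["individual_id", "TNB", "NBA", "LW"]
PRIMER_COLUMNS = ["locus", "fwd", "rev", "expected_empty", "expected_filled"]


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass(frozen=True)
class SequenceRecord:
    """One locus sequence from one assembly/breed."""

    id: str
    seq: str
    assembly: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RepeatConsensus:
    """A named transposable-element family consensus with its class label.

    ``te_class`` is one of SINE, LINE or LTR (endogenous retroviruses such
    as the pig ERVI/ERVIII families are LTR retrotransposons).
    """

    family: str
    te_class: str
    seq: str

    VALID_CLASSES = ("SINE", "LINE", "LTR")

    def __post_init__(self) -> None:
        if self.te_class not in self.VALID_CLASSES:
            raise FormatError(
                f"family {self.family!r}: class {self.te_class!r} "
                f"not one of {self.VALID_CLASSES}"
            )
        if not 100 <= len(self.seq) <= 5000:
            raise FormatError(
                f"family {self.family!r}: consensus length {len(self.seq)} "
                "outside [100, 5000]"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_genotype(symbol: str) -> str:
    """Map a genotype symbol to canonical ASCII form.

    Accepts the Unicode minus sign (U+2212) used in typeset tables.
    Empty/whitespace fields are explicit missing (returned as ``None``).
    """
    s = symbol.strip().replace("−", "-")
    if s == "":
        return None
    if s not in GENOTYPE_SYMBOLS:
        raise FormatError(f"unknown genotype symbol {symbol!r}")
    return s


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, assembly: str = "") -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Sequences are uppercased; ids must be unique within the file.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), assembly=assembly))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="")
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_repeat_library(path) -> list[RepeatConsensus]:
    """Read a repeat consensus library FASTA with ``family#class`` headers."""
    out: list[RepeatConsensus] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if "#" not in rec.id:
            raise FormatError(
                f"library header {rec.id!r} not of the form family#class"
            )
        family, te_class = rec.id.split("#", 1)
        if family in seen:
            raise FormatError(f"duplicate family {family!r} in library")
        seen.add(family)
        out.append(RepeatConsensus(family=family, te_class=te_class, seq=str(rec.seq).upper()))
    if not out:
        raise FormatError(f"{path}: empty repeat library")
    return out


def write_repeat_library(library: Iterable[RepeatConsensus], path) -> None:
    recs = [
        SequenceRecord(id=f"{c.family}#{c.te_class}", seq=c.seq) for c in library
    ]
    write_fasta(recs, path)


# ---------------------------------------------------------------------------
# TSV tables


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_genotype_table(path) -> pd.DataFrame:
    """Read a genotype table: individual_id / breed / locus / genotype.

    Genotype symbols are validated and normalized; an empty field is
    explicit missing (``None``).  Duplicate (individual, locus) pairs and
    unknown symbols are errors that name the offending row.
    """
    df = _read_tsv(path, GENOTYPE_COLUMNS)
    genotypes = []
    for i, raw in enumerate(df["genotype"]):
        try:
            genotypes.append(normalize_genotype(raw))
        except FormatError as exc:
            raise FormatError(f"{path}, row {i + 2}: {exc}") from None
    out = df[["individual_id", "breed", "locus"]].copy()
    out["genotype"] = genotypes
    dup = out.duplicated(subset=["individual_id", "locus"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise FormatError(f"{path}, row {row}: duplicate (individual, locus) pair")
    return out


def write_genotype_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["genotype"] = out["genotype"].map(lambda g: "" if g is None else g)
    out.to_csv(path, sep="\t", index=False, columns=GENOTYPE_COLUMNS)


def read_trait_table(path) -> pd.DataFrame:
    """Read a reproductive-trait table: TNB and NBA litter counts, LW in kg.

    Enforces TNB >= NBA >= 0 and LW >= 0 row by row.
    """
    df = _read_tsv(path, TRAIT_COLUMNS)
    out = df.copy()
    for col, caster in (("TNB", int), ("NBA", int), ("LW", float)):
        try:
            out[col] = [caster(v) for v in df[col]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric {col}: {exc}") from None
    bad = out.index[(out["NBA"] > out["TNB"]) | (out["NBA"] < 0) | (out["LW"] < 0)]
    if len(bad):
        raise FormatError(
            f"{path}, row {int(bad[0]) + 2}: trait invariant TNB >= NBA >= 0, LW >= 0 violated"
        )
    return out[TRAIT_COLUMNS]


def write_trait_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=TRAIT_COLUMNS)


def read_primer_table(path) -> pd.DataFrame:
    """Read a primer table: locus, fwd, rev, expected_empty, expected_filled."""
    df = _read_tsv(path, PRIMER_COLUMNS)
    out = df.copy()
    for col in ("fwd", "rev"):
        out[col] = out[col].str.upper()
        for i, p in enumerate(out[col]):
            if not 15 <= len(p) <= 35:
                raise FormatError(
                    f"{path}, row {i + 2}: primer length {len(p)} outside [15, 35]"
                )
            if set(p) - VALID_BASES:
                raise FormatError(f"{path}, row {i + 2}: non-IUPAC primer {p!r}")
    for col in ("expected_empty", "expected_filled"):
        out[col] = out[col].astype(int)
    return out[PRIMER_COLUMNS]


def write_primer_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=PRIMER_COLUMNS)
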