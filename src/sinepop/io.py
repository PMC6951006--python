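"""Typed readers and writers for the external formats the pipeline touches.

Sequence data travel as :class:`SequenceRecord` (a thin, validated wrapper kept
deliberately independent of Biopython's ``SeqRecord`` so invariants — upper-case
``ACGTN`` alphabet, non-empty id — hold everywhere downstream).  Genotype
tables are pandas DataFrames wrapped by :class:`LocusTable`.  All coordinates
exchanged between modules are 0-based, half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = frozenset("ACGTN")
GENOTYPES = ("II", "IA", "AA", "missing")
GENOTYPE_COLUMNS = ["locus_id", "population_id", "individual_id", "genotype"]


class ParseError(ValueError):
    """Raised when an input file fails validation; carries file/line context."""


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with id and free-text description.

    ``seq`` is stored upper-case over ``{A, C, G, T, N}``; ``N`` is a legal
    character but never counts as a match in any comparison performed by this
    package.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        norm = self.seq.upper()
        if not norm:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(norm) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )
        object.__setattr__(self, "seq", norm)

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """Return ``seq[start:end]`` (0-based, half-open)."""
        if not (0 <= start <= end <= len(self.seq)):
            raise IndexError(f"span [{start}, {end}) outside record of length {len(self)}")
        return self.seq[start:end]


def _prescan_fasta(path: str) -> None:
    """Validate raw FASTA lines so errors can name the offending line."""
    seen_header = False
    body_len = 0
    header_line = 0
    ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if seen_header and body_len == 0:
                    raise ParseError(f"{path}:{header_line}: header with empty sequence")
                name = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                if not name:
                    raise ParseError(f"{path}:{lineno}: malformed header (no id)")
                if name in ids:
                    raise ParseError(f"{path}:{lineno}: duplicate record id {name!r}")
                ids.add(name)
                seen_header = True
                header_line = lineno
                body_len = 0
            else:
                if not seen_header:
                    raise ParseError(f"{path}:{lineno}: sequence data before any header")
                bad = set(line.strip().upper()) - DNA_ALPHABET
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal character(s) {sorted(bad)}"
                    )
                body_len += len(line.strip())
    if not seen_header:
        raise ParseError(f"{path}: no FASTA records found")
    if body_len == 0:
        raise ParseError(f"{path}:{header_line}: header with empty sequence")


def read_fasta(path: str) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Order is preserved; lower-case bodies are normalized to upper-case.
    Malformed headers, empty sequences and illegal characters raise
    :class:`ParseError` naming the line.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _prescan_fasta(path)
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description))
    return records


def write_fasta(records: list[SequenceRecord], path: str, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description.removeprefix(r.id).strip())
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


@dataclass
class LocusTable:
    """Diploid presence/absence genotypes, one row per (population, individual, locus).

    ``I`` is the insertion-bearing allele, ``A`` the insertion-free allele;
    genotypes are ``II``/``IA``/``AA`` or explicit ``missing``.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENOTYPE_COLUMNS))

    def __post_init__(self) -> None:
        df = self.df
        missing_cols = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ParseError(f"genotype table lacks column(s) {missing_cols}")
        df = df[GENOTYPE_COLUMNS].copy()
        df["locus_id"] = df["locus_id"].astype(str)
        df["population_id"] = df["population_id"].astype(str)
        df["individual_id"] = df["individual_id"].astype(str)
        df["genotype"] = df["genotype"].astype(str)
        bad = df[~df["genotype"].isin(GENOTYPES)]
        if len(bad):
            rows = ", ".join(str(i) for i in bad.index[:10])
            raise ParseError(
                f"unknown genotype symbol(s) {sorted(bad['genotype'].unique())} at row(s) {rows}"
            )
        dup = df.duplicated(subset=["population_id", "individual_id", "locus_id"])
        if dup.any():
            rows = ", ".join(str(i) for i in df.index[dup][:10])
            raise ParseError(f"duplicated (population, individual, locus) triple(s) at row(s) {rows}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def loci(self) -> list[str]:
        return sorted(self.df["locus_id"].unique())

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population_id"].unique())


def read_genotypes(path: str) -> LocusTable:
    """Read a genotype TSV with header locus_id/population_id/individual_id/genotype."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(df.columns) and set(GENOTYPE_COLUMNS) - set(df.columns):
        raise ParseError(
            f"{path}: expected header {GENOTYPE_COLUMNS}, found {list(df.columns)}"
        )
    return LocusTable(df)


def write_genotypes(table: LocusTable, path: str) -> None:
    table.df.to_csv(path, sep="\t", index=False)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def write_newick(tree, path: str) -> None:
    """Write a tree (any object with ``.to_newick()`` or a Newick string) to a file."""
    if hasattr(tree, "to_newick"):
        text = tree.to_newick()
    elif isinstance(tree, str):
        text = tree if tree.rstrip().endswith(";") else tree + ";"
    else:
        raise TypeError("tree must expose to_newick() or be a Newick string")
    with open(path, "w") as fh:
        fh.write(text.rstrip() + "\n")


def read_newick(path: str):
    """Parse a Newick file with dendropy; returns a ``dendropy.Tree``."""
    import dendropy

    return dendropy.Tree.get(path=path, schema="newick")
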