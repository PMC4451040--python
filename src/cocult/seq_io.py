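"""Readers and writers for the plain-text formats every pipeline stage touches.

All sequence input is canonicalised to a single alphabet on read: upper case,
``U`` mapped to ``T``, and anything outside ``{A, C, G, T, N, -}`` rejected.
FASTA/FASTQ parsing is delegated to Biopython; Newick handling to dendropy.
No science lives here.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd
from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN-")

__all__ = [
    "SeqRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_newick",
    "write_newick",
    "newick_to_tree",
    "tree_to_newick",
    "read_coverage_table",
    "write_coverage_table",
    "read_tsv",
    "write_tsv",
]


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass
class SeqRecord:
    """A named DNA (or gapped alignment) sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.sequence = canonicalise_sequence(self.sequence, context=self.id)

    def __len__(self) -> int:
        return len(self.sequence)


def canonicalise_sequence(seq: str, context: str = "?") -> str:
    """Upper-case, map RNA U->T, and reject characters outside the alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise FormatError(
            f"record {context!r}: illegal characters {sorted(bad)!r} "
            f"(allowed: A, C, G, T, N, -)"
        )
    return s


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Raises :class:`FormatError` on a missing ``>`` header, duplicate ids,
    or illegal sequence characters. An empty file yields an empty list.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            return []
        if first != ">":
            raise FormatError(f"{path}: line 1: FASTA must start with '>'")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip()
            records.append(SeqRecord(rec.id, str(rec.seq), desc))
    return records


def write_fasta(records, path, wrap_width: int = 60):
    """Write records to FASTA, wrapping sequence lines at ``wrap_width``."""
    if wrap_width < 1:
        raise ValueError("wrap_width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap_width):
                fh.write(rec.sequence[i : i + wrap_width] + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTQ (Sanger qualities; qualities are carried but unused downstream)
# ---------------------------------------------------------------------------

def read_fastq(path) -> list[tuple[SeqRecord, str]]:
    """Read a 4-line-per-record FASTQ file into (record, quality) pairs."""
    out: list[tuple[SeqRecord, str]] = []
    with open(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                quals = rec.letter_annotations["phred_quality"]
                qual = "".join(chr(q + 33) for q in quals)
                sr = SeqRecord(rec.id, str(rec.seq))
                if len(qual) != len(sr.sequence):
                    raise FormatError(
                        f"{path}: record {rec.id!r}: quality length "
                        f"{len(qual)} != sequence length {len(sr.sequence)}"
                    )
                out.append((sr, qual))
        except ValueError as exc:  # Biopython signals truncation/mismatch
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fastq(pairs, path):
    """Write (record, quality) pairs as 4-line FASTQ."""
    with open(path, "w") as fh:
        for rec, qual in pairs:
            if len(qual) != len(rec.sequence):
                raise FormatError(
                    f"record {rec.id!r}: quality length {len(qual)} != "
                    f"sequence length {len(rec.sequence)}"
                )
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
    return path


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def newick_to_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree (branch lengths kept)."""
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"malformed Newick: {exc}") from exc


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def read_newick(path) -> dendropy.Tree:
    with open(path) as fh:
        return newick_to_tree(fh.read())


def write_newick(tree: dendropy.Tree, path):
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")
    return path


# ---------------------------------------------------------------------------
# TSV tables (header row required; unknown columns preserved)
# ---------------------------------------------------------------------------

def read_tsv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def write_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)
    return path


def read_coverage_table(path) -> pd.DataFrame:
    """Read a per-contig coverage table with columns ``contig_id``, ``coverage``."""
    df = read_tsv(path, required=("contig_id", "coverage"))
    if (df["coverage"] < 0).any():
        raise FormatError(f"{path}: negative coverage values")
    if df["contig_id"].duplicated().any():
        dup = df.loc[df["contig_id"].duplicated(), "contig_id"].iloc[0]
        raise FormatError(f"{path}: duplicate contig id {dup!r}")
    return df


def write_coverage_table(df: pd.DataFrame, path):
    return write_tsv(df, path)
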