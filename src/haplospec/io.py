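"""Shared readers and writers: FASTA, FASTQ(.gz), TSV tables, newick trees.

All coordinates in reports are 1-based inclusive.  FASTA/FASTQ parsing goes
through Biopython; tables through pandas (tab-separated, header row);
trees through dendropy newick serialization.  Sequence case is normalized
to upper on read.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Contig, ContigSet, PairedReadSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq_pair",
    "read_table",
    "write_table",
    "read_newick",
    "write_newick",
]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> ContigSet:
    with _open_text(path) as fh:
        records = [
            Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")
        ]
    return ContigSet(records)


def write_fasta(contigs: ContigSet | Iterable[Contig], path) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(*paths) -> list[str]:
    """Read one or more FASTQ files (gz-aware) into a flat sequence list.

    A quality line whose length differs from its sequence raises a parse
    error naming the offending record (Biopython enforces this).
    """
    out: list[str] = []
    for path in paths:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                out.append(str(rec.seq).upper())
    return out


def write_fastq_pair(reads: PairedReadSet, path1, path2, quality_char="I") -> None:
    for mates, path in ((reads.r1, path1), (reads.r2, path2)):
        with open(path, "w") as fh:
            for rec in mates:
                fh.write(
                    f"@{rec.id}\n{rec.seq}\n+\n{quality_char * len(rec.seq)}\n"
                )


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
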