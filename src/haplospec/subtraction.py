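"""In-silico subtraction of contigs against a reference k-mer set.

The screen that found the short-style-specific gene: build the set of all
32-mers occurring in reads from the long-styled (s/s) transcriptome, then
retain only those short-morph contigs that share none of their 32-mers with
that set.  Genes hemizygous on the dominant S haplotype are absent from the
long-morph reads and therefore survive; everything expressed in both morphs
is eliminated.

K-mers are stored as 2-bit-encoded integers in a hash set (exact membership,
no probabilistic filters).  Canonical form — the lexicographic minimum of a
k-mer and its reverse complement, which coincides with the numeric minimum
of the encodings — makes the screen strand-independent and is on by default
since cDNA reads may derive from either strand.  Windows containing N are
skipped rather than expanded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .simulate import Contig, ContigSet

__all__ = [
    "KmerSet",
    "build_kmer_set",
    "screen_contig",
    "subtract",
    "iter_kmers",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_RC = {0: 3, 1: 2, 2: 1, 3: 0}


def iter_kmers(seq: str, k: int, canonical: bool = True):
    """Yield the (canonical) 2-bit encodings of all N-free k-mers of seq.

    Uses rolling updates of the forward and reverse-complement encodings;
    any non-ACGT character resets the window.
    """
    seq = seq.upper()
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = rev = 0
    run = 0
    for ch in seq:
        code = _ENC.get(ch)
        if code is None:
            run = 0
            fwd = rev = 0
            continue
        fwd = ((fwd << 2) | code) & mask
        rev = (rev >> 2) | (_RC[code] << shift)
        run += 1
        if run >= k:
            yield min(fwd, rev) if canonical else fwd


def decode_kmer(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


@dataclass
class KmerSet:
    """Exact set of (canonical) k-mers from a read collection."""

    k: int
    members: set = field(default_factory=set)
    canonical: bool = True
    n_source_reads: int = 0

    def __contains__(self, encoded: int) -> bool:
        return encoded in self.members

    def __len__(self) -> int:
        return len(self.members)


def _as_sequences(reads) -> list[str]:
    if hasattr(reads, "sequences"):
        return list(reads.sequences)
    out = []
    for r in reads:
        out.append(r.seq if hasattr(r, "seq") else str(r))
    return out


def build_kmer_set(reads, k: int = 32, canonical: bool = True) -> KmerSet:
    """Index every distinct (canonical) k-mer occurring in the reads."""
    if k < 2:
        raise ValueError("k must be >= 2")
    seqs = _as_sequences(reads)
    if not seqs:
        raise ValueError("read set is empty")
    members: set = set()
    for seq in seqs:
        members.update(iter_kmers(seq, k, canonical))
    if not members and max(len(s) for s in seqs) < k:
        warnings.warn(f"k={k} exceeds every read length; k-mer set is empty")
    return KmerSet(k=k, members=members, canonical=canonical, n_source_reads=len(seqs))


def screen_contig(
    contig: str, kset: KmerSet, max_shared_fraction: float = 0.0
) -> dict:
    """Screen one contig against the reference k-mer set.

    Returns a report row with the total and shared k-mer window counts and a
    verdict: ``retained`` iff the shared fraction does not exceed the
    threshold (default 0 — any shared k-mer eliminates), ``too_short`` when
    the contig has no valid k-mer window.
    """
    if not 0.0 <= max_shared_fraction <= 1.0:
        raise ValueError("max_shared_fraction must be in [0, 1]")
    n_total = 0
    n_shared = 0
    for enc in iter_kmers(contig, kset.k, kset.canonical):
        n_total += 1
        if enc in kset.members:
            n_shared += 1
    if n_total == 0:
        return {
            "n_kmers_total": 0,
            "n_kmers_shared": 0,
            "shared_fraction": 0.0,
            "verdict": "too_short",
        }
    frac = n_shared / n_total
    verdict = "retained" if frac <= max_shared_fraction else "eliminated"
    return {
        "n_kmers_total": n_total,
        "n_kmers_shared": n_shared,
        "shared_fraction": frac,
        "verdict": verdict,
    }


def subtract(
    contigs: ContigSet | Iterable[Contig],
    reads,
    k: int = 32,
    canonical: bool = True,
    max_shared_fraction: float = 0.0,
) -> tuple[pd.DataFrame, ContigSet]:
    """Screen every contig against the read k-mer set.

    Returns the per-contig report (contig_id, length, n_kmers, n_shared,
    fraction, verdict) and the retained contigs.  The report's ``attrs``
    carry the summary counts.
    """
    records = list(contigs)
    rows = []
    retained = []
    kset = build_kmer_set(reads, k=k, canonical=canonical)
    for rec in records:
        row = screen_contig(rec.seq, kset, max_shared_fraction)
        rows.append(
            {
                "contig_id": rec.id,
                "length": len(rec.seq),
                "n_kmers": row["n_kmers_total"],
                "n_shared": row["n_kmers_shared"],
                "fraction": row["shared_fraction"],
                "verdict": row["verdict"],
            }
        )
        if row["verdict"] == "retained":
            retained.append(rec)
    report = pd.DataFrame(
        rows,
        columns=["contig_id", "length", "n_kmers", "n_shared", "fraction", "verdict"],
    )
    summary = {
        "n_input": len(records),
        "n_retained": len(retained),
        "n_eliminated": int((report["verdict"] == "eliminated").sum()) if len(report) else 0,
        "n_too_short": int((report["verdict"] == "too_short").sum()) if len(report) else 0,
        "k": k,
        "canonical": canonical,
        "max_shared_fraction": max_shared_fraction,
        "n_reference_kmers": len(kset),
    }
    report.attrs["summary"] = summary
    return report, ContigSet(retained)
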