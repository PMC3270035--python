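"""Synthetic inputs for every stage of the pipeline.

Emulates the study design end to end at desk scale: two-morph stylar
transcriptomes in which a handful of genes sit hemizygously on the dominant
S haplotype (present in short-styled plants only), short paired reads from
those transcriptomes, testcross progeny with a configurable recombination
fraction between a presence/absence marker and the S-locus, and in-frame
codon alignments evolved along a tree to controlled synonymous divergences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq

from .evolution import SENSE_CODONS, _AA, _is_transition, count_sites, pathway_differences

__all__ = [
    "Contig",
    "ContigSet",
    "PairedReadSet",
    "TranscriptomeSpec",
    "ReadSimParams",
    "CrossSimParams",
    "CodonSimParams",
    "generate_transcriptomes",
    "simulate_reads",
    "simulate_testcross",
    "evolve_codon_sequences",
    "codon_rate_matrix",
    "expected_ng_ds",
    "branch_length_for_ds",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ContigSet:
    """Ordered collection of named sequences (transcripts or contigs)."""

    records: list[Contig] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class PairedReadSet:
    """Paired-end reads; mates share an index in the two lists."""

    r1: list[Contig] = field(default_factory=list)
    r2: list[Contig] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.r1)

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self.r1] + [r.seq for r in self.r2]


# ---------------------------------------------------------------------------
# Transcriptomes
# ---------------------------------------------------------------------------


@dataclass
class TranscriptomeSpec:
    """Two-morph transcriptome layout.

    ``n_s_specific_genes`` genes exist only on the S haplotype and hence only
    in the short-styled transcriptome; ``n_shared_genes`` are present in both
    morphs, differing at fixed allelic SNPs placed at rate
    ``allelic_snp_rate`` per site.
    """

    n_shared_genes: int
    n_s_specific_genes: int
    gene_length_range: tuple[int, int] = (200, 3000)
    allelic_snp_rate: float = 0.001
    seed: int = 0
    min_length_floor: int = 64  # 2 x default subtraction k

    def validate(self) -> None:
        if self.n_shared_genes < 0 or self.n_s_specific_genes < 0:
            raise ValueError("gene counts must be non-negative")
        lo, hi = self.gene_length_range
        if lo < self.min_length_floor:
            raise ValueError(
                f"minimum gene length {lo} below floor {self.min_length_floor}"
                " (genes must be at least twice the subtraction k-mer size)"
            )
        if hi < lo:
            raise ValueError("gene_length_range must be (low, high) with low <= high")
        if not 0.0 <= self.allelic_snp_rate <= 1.0:
            raise ValueError("allelic_snp_rate must be in [0, 1]")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_transcriptomes(
    spec: TranscriptomeSpec,
) -> tuple[ContigSet, ContigSet, pd.DataFrame]:
    """Generate short-morph and long-morph transcript sets with truth labels.

    Sequences are i.i.d. uniform over A,C,G,T, which at desk scale makes
    accidental 32-mer sharing between unrelated genes vanishingly unlikely —
    mirroring the discriminative assumption of the k-mer screen.

    Returns ``(short_morph, long_morph, truth)`` where ``truth`` has columns
    ``gene_id`` and ``label`` in {shared, s_specific}.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range
    short_recs: list[Contig] = []
    long_recs: list[Contig] = []
    truth_rows = []
    for i in range(spec.n_shared_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        alt = np.array(list(seq))
        snps = rng.random(length) < spec.allelic_snp_rate
        for pos in np.flatnonzero(snps):
            choices = [b for b in "ACGT" if b != alt[pos]]
            alt[pos] = choices[rng.integers(0, 3)]
        gid = f"shared_{i:04d}"
        short_recs.append(Contig(gid, seq))
        long_recs.append(Contig(gid, "".join(alt)))
        truth_rows.append((gid, "shared"))
    for i in range(spec.n_s_specific_genes):
        length = int(rng.integers(lo, hi + 1))
        gid = f"s_specific_{i:04d}"
        short_recs.append(Contig(gid, _random_seq(rng, length)))
        truth_rows.append((gid, "s_specific"))
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "label"])
    return ContigSet(short_recs), ContigSet(long_recs), truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@dataclass
class ReadSimParams:
    """Paired short-read simulation settings (substitution errors only)."""

    n_pairs: int
    read_length: int = 50
    per_base_error: float = 0.0
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 20.0
    strand_model: str = "both-strands"  # or "forward-only"
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")
        if not 0.0 <= self.per_base_error <= 0.1:
            raise ValueError("per_base_error must be in [0, 0.1]")
        if self.strand_model not in ("both-strands", "forward-only"):
            raise ValueError(f"unknown strand model {self.strand_model!r}")
        if self.read_length > self.fragment_length_mean:
            raise ValueError("read_length must not exceed mean fragment length")


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for pos in hits:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_reads(
    transcripts: ContigSet | Iterable[Contig], params: ReadSimParams
) -> PairedReadSet:
    """Draw paired reads from transcripts under simple fragment geometry.

    Fragments are sampled from transcripts in proportion to the number of
    valid start positions; mates are the two fragment ends in standard
    forward/reverse orientation.  Under the both-strands model the whole
    fragment is flipped to the opposite strand with probability 1/2.
    Transcripts shorter than the drawn fragment are never used; transcripts
    shorter than the read length are skipped entirely with a warning.
    """
    params.validate()
    records = list(transcripts)
    if not records:
        raise ValueError("transcript set is empty")
    # separate streams so fragment geometry is invariant to the error rate
    frag_ss, err_ss = np.random.SeedSequence(params.seed).spawn(2)
    rng = np.random.default_rng(frag_ss)
    err_rng = np.random.default_rng(err_ss)
    usable = [r for r in records if len(r) >= params.read_length]
    skipped = len(records) - len(usable)
    if skipped:
        warnings.warn(
            f"{skipped} transcript(s) shorter than the read length were skipped"
        )
    if not usable:
        raise ValueError("no transcript is long enough to draw reads from")
    weights = np.array([len(r) for r in usable], dtype=float)
    weights /= weights.sum()
    out = PairedReadSet()
    for i in range(params.n_pairs):
        t = usable[rng.choice(len(usable), p=weights)]
        frag_len = int(
            round(rng.normal(params.fragment_length_mean, params.fragment_length_sd))
        )
        frag_len = max(params.read_length, min(frag_len, len(t)))
        start = int(rng.integers(0, len(t) - frag_len + 1))
        frag = t.seq[start : start + frag_len]
        if params.strand_model == "both-strands" and rng.random() < 0.5:
            frag = revcomp(frag)
        m1 = frag[: params.read_length]
        m2 = revcomp(frag[-params.read_length :])
        m1 = _add_errors(m1, params.per_base_error, err_rng)
        m2 = _add_errors(m2, params.per_base_error, err_rng)
        out.r1.append(Contig(f"read_{i:07d}/1", m1))
        out.r2.append(Contig(f"read_{i:07d}/2", m2))
    return out


# ---------------------------------------------------------------------------
# Testcross
# ---------------------------------------------------------------------------


@dataclass
class CrossSimParams:
    """Testcross of a short-styled S/s plant to a long-styled s/s plant.

    Each offspring reveals one meiosis of the short parent: the S gamete is
    transmitted with probability 1/2 (expected 1:1 morph ratio) and a
    crossover between the marker and the S-locus occurs with probability
    ``r``.  With ``marker_on_S`` the marker allele starts in coupling with S.
    """

    n_plants: int
    r: float
    marker_on_S: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if not 0.0 <= self.r <= 0.5:
            raise ValueError("recombination fraction must be in [0, 0.5]")


def simulate_testcross(params: CrossSimParams) -> pd.DataFrame:
    """Simulate a testcross population.

    Returns a DataFrame with columns ``plant_id``, ``morph`` (S=short,
    L=long), ``marker`` (1=present, 0=absent) and the truth column
    ``recombinant`` marking offspring whose informative gamete recombined.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    got_S = rng.random(params.n_plants) < 0.5
    recomb = rng.random(params.n_plants) < params.r
    if params.marker_on_S:
        marker = got_S ^ recomb
    else:
        marker = (~got_S) ^ recomb
    return pd.DataFrame(
        {
            "plant_id": [f"plant_{i:05d}" for i in range(params.n_plants)],
            "morph": np.where(got_S, "S", "L"),
            "marker": marker.astype(int),
            "recombinant": recomb,
        }
    )


# ---------------------------------------------------------------------------
# Codon evolution
# ---------------------------------------------------------------------------


@dataclass
class CodonSimParams:
    """Codon-alignment simulation along a tree.

    ``tree`` is a newick string with branch lengths in expected nucleotide
    substitutions per site.  Substitution follows a 61-state sense-codon
    continuous-time Markov chain with transition/transversion ratio
    ``kappa`` and dN/dS ratio ``omega`` (uniform codon frequencies); stop
    codons are unreachable by construction.
    """

    n_codons: int
    tree: str
    kappa: float = 1.0
    omega: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


def codon_rate_matrix(kappa: float, omega: float) -> np.ndarray:
    """61x61 sense-codon rate matrix, scaled to 1 substitution per nt site.

    Off-diagonal rates are nonzero only between codons differing at one
    position: ``kappa`` multiplies transitions, ``omega`` multiplies
    nonsynonymous changes.  The matrix is symmetric, so the stationary
    distribution is uniform over the 61 sense codons; it is scaled so that
    a branch of length t accrues 3t expected substitutions per codon
    (t per nucleotide site).
    """
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            rate = kappa if _is_transition(ci[p], cj[p]) else 1.0
            if _AA[ci] != _AA[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.mean(np.diag(Q))  # per codon per unit time
    if mean_rate == 0:
        raise ValueError("degenerate rate matrix")
    return Q * (3.0 / mean_rate)


def expected_ng_ds(
    t: float, kappa: float = 1.0, omega: float = 0.2, R: float = 1.0
) -> float:
    """Expected Nei–Gojobori dS between two sequences separated by t.

    Computed exactly from the codon chain: the joint distribution of an
    ancestral/descendant codon pair at separation ``t`` gives the expected
    pathway-counted synonymous differences and site totals, from which the
    Jukes–Cantor-corrected dS the estimator would report (in the large-
    sequence limit) follows.
    """
    Q = codon_rate_matrix(kappa, omega)
    P = expm(Q * t)
    n = len(SENSE_CODONS)
    pi = 1.0 / n
    e_sd = 0.0
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if P[i, j] <= 0:
                continue
            sd, _ = pathway_differences(ci, cj)
            e_sd += pi * P[i, j] * sd
    s_bar = float(np.mean([count_sites(c, R)[0] for c in SENSE_CODONS]))
    ps = e_sd / s_bar
    if ps >= 0.75:
        raise ValueError("separation saturates the synonymous distance")
    return float(-0.75 * np.log1p(-4 * ps / 3))


def branch_length_for_ds(
    target_ds: float, kappa: float = 1.0, omega: float = 0.2, R: float = 1.0
) -> float:
    """Total tree separation (subs/nt site) giving an expected NG dS.

    Numerically inverts :func:`expected_ng_ds`; use half the returned value
    on each of two sister branches.
    """
    if target_ds <= 0:
        raise ValueError("target dS must be positive")
    hi = 0.05
    while expected_ng_ds(hi, kappa, omega, R) < target_ds:
        hi *= 2
        if hi > 50:
            raise ValueError("target dS unreachable")
    return float(
        brentq(
            lambda t: expected_ng_ds(t, kappa, omega, R) - target_ds,
            1e-9,
            hi,
            xtol=1e-10,
        )
    )


def _sample_children(
    parent_idx: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(parent_idx))
    rows = cum[parent_idx]
    return (rows < u[:, None]).sum(axis=1)


def evolve_codon_sequences(params: CodonSimParams) -> dict[str, str]:
    """Simulate an in-frame codon alignment along a tree.

    The root sequence is drawn uniformly over sense codons; each branch
    applies the codon chain's transition kernel exp(Qt) site-by-site
    (rate-matrix simulation, no acceptance/rejection).  Returns a mapping
    from leaf name to nucleotide sequence; all sequences are stop-free and
    of equal length ``3 * n_codons``.
    """
    params.validate()
    tree = dendropy.Tree.get(data=params.tree, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("branch lengths must be non-negative")
    rng = np.random.default_rng(params.seed)
    Q = codon_rate_matrix(params.kappa, params.omega)
    kernels: dict[float, np.ndarray] = {}

    def kernel(t: float) -> np.ndarray:
        if t not in kernels:
            kernels[t] = expm(Q * t)
        return kernels[t]

    root_state = rng.integers(0, len(SENSE_CODONS), size=params.n_codons)
    states = {id(tree.seed_node): root_state}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        parent_state = states[id(node.parent_node)]
        if t == 0:
            states[id(node)] = parent_state.copy()
        else:
            states[id(node)] = _sample_children(parent_state, kernel(t), rng)
    out = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else f"leaf_{id(leaf)}"
        idx = states[id(leaf)]
        out[name] = "".join(SENSE_CODONS[i] for i in idx)
    return out
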