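"""Molecular-evolution analyses for haplotype-specific genes.

Implements the evolutionary half of the pipeline: synonymous/nonsynonymous
distances by the (modified) Nei–Gojobori method, p-distance matrices with
complete or pairwise deletion, neighbor-joining trees with nonparametric
bootstrap, strict-clock rate calibration and divergence dating, polymorphic
site counting, and degenerate protein-motif scanning.

The modified Nei–Gojobori scheme weights candidate changes at each codon
position by the transition/transversion rate ratio R when counting
synonymous and nonsynonymous *sites*; with R = 1 it reduces exactly to the
classical Nei–Gojobori counts.  Observed differences are partitioned by
averaging over all minimal substitution pathways between two codons, with
pathways through stop codons excluded.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "count_sites",
    "ng_distance",
    "NGResult",
    "DistanceMatrix",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "tree_bipartitions",
    "sum_branch_lengths",
    "calibrate_rate",
    "divergence_time",
    "coevolution_time",
    "count_polymorphic_sites",
    "MotifPattern",
    "scan_motif",
]

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _is_transition(b1: str, b2: str) -> bool:
    return (b1 in _PURINES and b2 in _PURINES) or (
        b1 in _PYRIMIDINES and b2 in _PYRIMIDINES
    )


# ---------------------------------------------------------------------------
# Nei–Gojobori site and pathway counting
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def count_sites(codon: str, R: float = 1.0) -> tuple[float, float]:
    """Fractional synonymous and nonsynonymous site counts for one codon.

    Each of the three positions contributes exactly one site, split between
    synonymous and nonsynonymous according to the weighted fraction of
    single-base changes that preserve the encoded amino acid.  Transitions
    receive weight ``R``, transversions weight 1 (modified Nei–Gojobori;
    ``R=1`` gives the classical unweighted counts).  Changes to stop codons
    are excluded from the weighting, following the usual convention.

    Returns ``(s_sites, n_sites)`` with ``s_sites + n_sites == 3``.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    if codon not in _AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    if R <= 0:
        raise ValueError("transition/transversion ratio R must be > 0")
    aa = _AA[codon]
    s_total = 0.0
    for pos in range(3):
        w_syn = 0.0
        w_all = 0.0
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            w = R if _is_transition(codon[pos], alt) else 1.0
            w_all += w
            if _AA[mutant] == aa:
                w_syn += w
        s_total += 0.0 if w_all == 0 else w_syn / w_all
    return s_total, 3.0 - s_total


@lru_cache(maxsize=None)
def pathway_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two sense codons.

    For codons differing at 2–3 positions the counts are averaged with equal
    weight over all minimal substitution pathways whose intermediates are
    sense codons; pathways through stops are excluded.  In the degenerate
    case where every pathway passes through a stop, all pathways are used.
    """
    codon1, codon2 = codon1.upper(), codon2.upper()
    for c in (codon1, codon2):
        if c not in _AA:
            raise ValueError(f"not a sense codon: {c!r}")
    diff = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        current = codon1
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon2:
                return None
            if nxt in STOP_CODONS:
                return None
            if _AA[current] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        return sd, nd

    results = [walk(order) for order in itertools.permutations(diff)]
    valid = [r for r in results if r is not None]
    if not valid:
        # all minimal pathways blocked by stops; fall back to counting
        # through them (differences still classified per step)
        valid = []
        for order in itertools.permutations(diff):
            sd = nd = 0.0
            current = codon1
            for pos in order:
                nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
                a1 = _AA.get(current, "*")
                a2 = _AA.get(nxt, "*")
                if a1 == a2:
                    sd += 1
                else:
                    nd += 1
                current = nxt
            valid.append((sd, nd))
    sd = float(np.mean([v[0] for v in valid]))
    nd = float(np.mean([v[1] for v in valid]))
    return sd, nd


@dataclass
class NGResult:
    """Pairwise Nei–Gojobori distance decomposition."""

    dS: float
    dN: float
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    n_codons: int
    correction: str
    undefined: bool = False


def _codon_iter(seq: str) -> Iterable[str]:
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i : i + 3].upper()


def ng_distance(
    seq1: str,
    seq2: str,
    R: float = 1.0,
    correction: str = "jukes_cantor",
) -> NGResult:
    """Synonymous and nonsynonymous distances between two in-frame sequences.

    Codon pairs in which either codon contains a gap, an ambiguity or a stop
    are excluded pairwise.  Site totals are averaged between the two
    sequences; ``ps = Sd/S`` and ``pn = Nd/N`` are optionally Jukes–Cantor
    corrected, ``d = -(3/4) ln(1 - 4p/3)``, undefined for ``p >= 3/4``.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    if correction not in ("none", "jukes_cantor"):
        raise ValueError(f"unknown correction {correction!r}")
    S1 = S2 = N1 = N2 = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    for c1, c2 in zip(_codon_iter(seq1), _codon_iter(seq2)):
        if c1 not in _AA or c2 not in _AA:
            if c1 in STOP_CODONS or c2 in STOP_CODONS:
                warnings.warn("stop codon encountered; codon pair excluded")
            continue
        s1, n1 = count_sites(c1, R)
        s2, n2 = count_sites(c2, R)
        S1 += s1
        S2 += s2
        N1 += n1
        N2 += n2
        sd, nd = pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons between the two sequences")
    S = (S1 + S2) / 2
    N = (N1 + N2) / 2
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    undefined = False
    if correction == "jukes_cantor":
        if ps >= 0.75 or pn >= 0.75:
            undefined = True
            warnings.warn("proportion >= 3/4; Jukes-Cantor distance undefined")
        dS = float("nan") if ps >= 0.75 else -0.75 * np.log1p(-4 * ps / 3)
        dN = float("nan") if pn >= 0.75 else -0.75 * np.log1p(-4 * pn / 3)
    else:
        dS, dN = ps, pn
    return NGResult(
        dS=float(dS),
        dN=float(dN),
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        ps=ps,
        pn=pn,
        n_codons=n_codons,
        correction=correction,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# p-distances and trees
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: list[str]
    matrix: np.ndarray
    deletion: str = "complete"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


_VALID = frozenset("ACGT")


def _alignment_array(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(alignment)
    lengths = {len(alignment[x]) for x in labels}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    arr = np.array([list(alignment[x].upper()) for x in labels])
    return labels, arr


def complete_deletion(alignment: Mapping[str, str]) -> dict[str, str]:
    """Remove every column containing a gap or ambiguity in any sequence."""
    labels, arr = _alignment_array(alignment)
    keep = np.all(np.isin(arr, list(_VALID)), axis=0)
    return {lab: "".join(row[keep]) for lab, row in zip(labels, arr)}


def p_distance_matrix(
    alignment: Mapping[str, str], deletion: str = "complete"
) -> DistanceMatrix:
    """Proportion-of-differences matrix under complete or pairwise deletion."""
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    labels, arr = _alignment_array(alignment)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    n = len(labels)
    valid = np.isin(arr, list(_VALID))
    if deletion == "complete":
        keep = np.all(valid, axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed all sites")
        arr = arr[:, keep]
        valid = valid[:, keep]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            if not both.any():
                raise ValueError(
                    f"no comparable sites between {labels[i]} and {labels[j]}"
                )
            D[i, j] = D[j, i] = np.mean(arr[i, both] != arr[j, both])
    return DistanceMatrix(labels=labels, matrix=D, deletion=deletion)


def neighbor_joining(
    dm: DistanceMatrix, clamp_negative: bool = True
) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the smallest (i, j) index pair in the current
    label ordering, making the result deterministic under label permutation
    up to relabelling.  Negative branch lengths are clamped to zero when
    ``clamp_negative`` is set; the pre-clamp lengths are preserved on each
    node as the ``preclamp_length`` attribute and in the tree's
    ``preclamp_total_length`` annotation so the unclamped total remains
    auditable.
    """
    labels = list(dm.labels)
    n = len(labels)
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    if n < 3:
        warnings.warn("fewer than 3 taxa; returning trivial tree")
        for lab in labels:
            child = tree.seed_node.new_child(
                taxon=taxa.get_taxon(lab),
                edge_length=float(dm.matrix[0, 1]) / 2 if n == 2 else 0.0,
            )
            child.preclamp_length = child.edge.length
        tree.preclamp_total_length = sum_branch_lengths(tree)
        return tree

    D = dm.matrix.astype(float).copy()
    nodes: list[dendropy.Node] = [
        dendropy.Node(taxon=taxa.get_taxon(lab)) for lab in labels
    ]
    active = list(range(n))
    preclamp_total = 0.0

    def attach(parent: dendropy.Node, child: dendropy.Node, length: float) -> float:
        nonlocal preclamp_total
        preclamp_total += length
        child.preclamp_length = length
        if clamp_negative and length < 0:
            warnings.warn("negative branch length clamped to 0")
            length = 0.0
        parent.add_child(child)
        child.edge.length = float(length)
        return length

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, f, g = best
        lf = 0.5 * D[f, g] + (r[f] - r[g]) / (2 * (m - 2))
        lg = D[f, g] - lf
        u = dendropy.Node()
        attach(u, nodes[f], lf)
        attach(u, nodes[g], lg)
        for k in active:
            if k in (f, g):
                continue
            duk = 0.5 * (D[f, k] + D[g, k] - D[f, g])
            D[f, k] = D[k, f] = duk
        nodes[f] = u
        active.remove(g)

    # final unrooted resolution of the remaining three nodes
    x, y, z = active
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    root = dendropy.Node()
    attach(root, nodes[x], lx)
    attach(root, nodes[y], ly)
    attach(root, nodes[z], lz)
    tree.seed_node = root
    tree.preclamp_total_length = preclamp_total
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Internal-edge bipartitions as canonical leaf-label sets with lengths.

    Each internal edge splits the leaves in two; the side *not* containing
    the alphabetically first leaf is used as the canonical key, so keys are
    comparable across differently rooted representations of the same
    unrooted tree.
    """
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    all_set = frozenset(leaves)
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else all_set - below
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        length = node.edge.length or 0.0
        out[side] = out.get(side, 0.0) + length
    return out


def terminal_branch_lengths(tree: dendropy.Tree) -> dict[str, float]:
    return {
        lf.taxon.label: (lf.edge.length or 0.0) for lf in tree.leaf_node_iter()
    }


def sum_branch_lengths(tree: dendropy.Tree) -> float:
    """Arithmetic total of all branch lengths in the tree."""
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has branches without lengths")
        total += edge.length
    return total


def bootstrap_support(
    alignment: Mapping[str, str],
    n_replicates: int = 500,
    seed: int | None = None,
    deletion: str = "complete",
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """Nonparametric bootstrap supports for the NJ tree of an alignment.

    Alignment columns are resampled with replacement; each replicate tree is
    built by p-distance + neighbor joining, and support for each internal
    bipartition of the reference tree is the percentage of replicates
    containing it.  Supports are written onto the internal node labels of
    the returned tree.
    """
    labels, arr = _alignment_array(alignment)
    rng = np.random.default_rng(seed)
    ref_dm = p_distance_matrix(alignment, deletion=deletion)
    ref_tree = neighbor_joining(ref_dm)
    ref_bip = tree_bipartitions(ref_tree)
    if not np.any(arr != arr[0]):
        warnings.warn("alignment has no variable sites; supports degenerate")
    counts = {bip: 0 for bip in ref_bip}
    L = arr.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = {lab: "".join(arr[i, cols]) for i, lab in enumerate(labels)}
        try:
            rep_tree = neighbor_joining(p_distance_matrix(rep, deletion=deletion))
        except ValueError:
            continue
        rep_bip = tree_bipartitions(rep_tree)
        for bip in counts:
            if bip in rep_bip:
                counts[bip] += 1
    supports = {bip: 100.0 * c / n_replicates for bip, c in counts.items()}
    leaves = sorted(alignment)
    all_set = frozenset(leaves)
    ref = leaves[0]
    for node in ref_tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else all_set - below
        if side in supports:
            node.label = f"{supports[side]:.0f}"
    return ref_tree, supports


# ---------------------------------------------------------------------------
# Rate calibration and dating
# ---------------------------------------------------------------------------


def calibrate_rate(distance: float, split_time: float) -> float:
    """Substitution rate per site per year from a dated species split.

    ``rate = distance / (2 * split_time)`` — the pairwise distance accumulates
    along both descendant lineages.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if split_time <= 0:
        raise ValueError("split time must be positive")
    return distance / (2.0 * split_time)


def divergence_time(distance: float, rate: float) -> float:
    """Years since two lineages split, under a strict clock."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance / (2.0 * rate)


def coevolution_time(total_branch_length: float, rate: float) -> float:
    """Years of evolution represented by a genealogy's total branch length.

    Applies the tree-length clock used for within-species allele genealogies:
    total length divided by the per-year rate (not halved, since the total
    already sums over lineages).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if total_branch_length < 0:
        raise ValueError("total branch length must be non-negative")
    return total_branch_length / rate


# ---------------------------------------------------------------------------
# Polymorphism and motifs
# ---------------------------------------------------------------------------


def count_polymorphic_sites(alignment: Mapping[str, str]) -> tuple[int, int]:
    """Segregating and total sites after complete-deletion filtering."""
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    clean = complete_deletion(alignment)
    _, arr = _alignment_array(clean)
    total = arr.shape[1]
    seg = int(np.sum([len(set(arr[:, j])) >= 2 for j in range(total)]))
    return seg, total


_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class MotifPattern:
    """Degenerate protein motif: one allowed-residue set per position.

    Parsed from compact notation such as ``GGP(R/K)(P/A)PPRNKMA`` where
    ``(A/B)`` allows either residue and ``X`` matches any residue.
    """

    positions: list[frozenset] = field(default_factory=list)
    source: str = ""

    @classmethod
    def parse(cls, text: str) -> "MotifPattern":
        positions: list[frozenset] = []
        i = 0
        text = text.strip()
        if not text:
            raise ValueError("empty motif pattern")
        while i < len(text):
            ch = text[i]
            if ch == "(":
                j = text.index(")", i)
                residues = frozenset(
                    r.strip().upper() for r in text[i + 1 : j].split("/")
                )
                if not residues or not residues <= _AA_ALPHABET:
                    raise ValueError(f"bad residue group {text[i:j + 1]!r}")
                positions.append(residues)
                i = j + 1
            elif ch.upper() == "X":
                positions.append(_AA_ALPHABET)
                i += 1
            elif ch.upper() in _AA_ALPHABET:
                positions.append(frozenset(ch.upper()))
                i += 1
            else:
                raise ValueError(f"unexpected character {ch!r} in motif")
        return cls(positions=positions, source=text)

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        if len(window) != len(self.positions):
            return False
        return all(
            res.upper() in allowed
            for res, allowed in zip(window, self.positions)
        )


def scan_motif(
    protein_sequence: str, pattern: MotifPattern | str
) -> list[tuple[int, str]]:
    """All (possibly overlapping) motif matches, 1-based start positions."""
    if isinstance(pattern, str):
        pattern = MotifPattern.parse(pattern)
    if len(pattern) == 0:
        raise ValueError("empty motif pattern")
    seq = protein_sequence.upper()
    hits = []
    for start in range(len(seq) - len(pattern) + 1):
        window = seq[start : start + len(pattern)]
        if pattern.matches(window):
            hits.append((start + 1, window))
    return hits
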