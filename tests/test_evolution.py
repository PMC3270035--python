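"""Nei-Gojobori distances, p-distances, NJ trees, dating, motifs."""

import numpy as np
import pytest

from haplospec.evolution import (
    DistanceMatrix,
    MotifPattern,
    bootstrap_support,
    calibrate_rate,
    coevolution_time,
    complete_deletion,
    count_polymorphic_sites,
    count_sites,
    divergence_time,
    neighbor_joining,
    ng_distance,
    p_distance_matrix,
    pathway_differences,
    scan_motif,
    sum_branch_lengths,
    tree_bipartitions,
    terminal_branch_lengths,
    SENSE_CODONS,
    STOP_CODONS,
)

from conftest import random_unrooted_tree, tree_distance_matrix, true_bipartitions

_CODE = {}


def _translate(codon):
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def classical_site_count(codon):
    """Independent unweighted Nei-Gojobori site oracle."""
    s = 0.0
    for pos in range(3):
        syn = 0
        total = 0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            total += 1
            if _translate(mutant) == _translate(codon):
                syn += 1
        if total:
            s += syn / total
    return s


class TestCountSites:
    def test_phe_third_position(self):
        s, n = count_sites("TTT", R=1.0)
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_met_has_no_synonymous_sites(self):
        for R in (0.5, 1.0, 4.0):
            assert count_sites("ATG", R)[0] == 0.0

    def test_fourfold_third_position_full_site(self):
        for codon in ("GGA", "GGC", "GGG", "GGT", "CTC", "GTA"):
            s, _ = count_sites(codon, R=1.0)
            assert s >= 1.0 - 1e-12

    def test_sites_sum_to_three(self):
        for codon in SENSE_CODONS:
            for R in (0.5, 1.0, 2.0):
                s, n = count_sites(codon, R)
                assert s + n == pytest.approx(3.0)

    def test_reduces_to_classical_at_R_one(self):
        for codon in SENSE_CODONS:
            assert count_sites(codon, 1.0)[0] == pytest.approx(
                classical_site_count(codon)
            )

    def test_weighting_shifts_sites(self):
        # TTT: the only synonymous change (T->C) is a transition, so raising
        # R must raise the synonymous site count
        s1 = count_sites("TTT", 1.0)[0]
        s4 = count_sites("TTT", 4.0)[0]
        assert s4 > s1

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")


class TestPathways:
    def test_identical_codons(self):
        assert pathway_differences("AAA", "AAA") == (0.0, 0.0)

    def test_single_synonymous_difference(self):
        sd, nd = pathway_differences("TTT", "TTC")
        assert (sd, nd) == (1.0, 0.0)

    def test_two_position_pathway_average(self):
        # TTT (Phe) <-> GTA (Val): pathways via GTT (Val) and TTA (Leu)
        # path1: TTT->GTT (nonsyn) ->GTA (syn);  path2: TTT->TTA (nonsyn) ->GTA (nonsyn)
        sd, nd = pathway_differences("TTT", "GTA")
        assert sd == pytest.approx(0.5)
        assert nd == pytest.approx(1.5)

    def test_pathways_through_stops_excluded(self):
        # TGT (Cys) <-> AGA (Arg): via TGA (stop, excluded) or AGT (Ser)
        sd, nd = pathway_differences("TGT", "AGA")
        # remaining single pathway TGT->AGT (nonsyn) ->AGA (nonsyn)
        assert (sd, nd) == (0.0, 2.0)


class TestNGDistance:
    def test_identical_sequences(self):
        seq = "ATGGCTAAA" * 10
        res = ng_distance(seq, seq)
        assert res.dS == 0.0 and res.dN == 0.0

    def test_hand_computed_single_difference(self):
        codons = ["GCT"] * 100  # Ala, fourfold third position
        s1 = "".join(codons)
        codons[0] = "GCC"  # synonymous change
        s2 = "".join(codons)
        res = ng_distance(s1, s2, correction="none")
        exp_S = sum(count_sites(c)[0] for c in ["GCT"] * 100)
        # S averaged over both sequences; GCC has the same site count as GCT
        assert res.S_sites == pytest.approx(exp_S)
        assert res.dS == pytest.approx(1.0 / exp_S)
        assert res.dN == 0.0

    def test_gapped_codons_excluded_pairwise(self):
        s1 = "ATG" + "GCT" + "AAA"
        s2 = "ATG" + "GC-" + "AAA"
        res = ng_distance(s1, s2)
        assert res.n_codons == 2

    def test_jukes_cantor_exceeds_p(self):
        rng = np.random.default_rng(0)
        codons1 = [SENSE_CODONS[i] for i in rng.integers(0, 61, 200)]
        codons2 = [SENSE_CODONS[i] for i in rng.integers(0, 61, 200)]
        raw = ng_distance("".join(codons1), "".join(codons2), correction="none")
        if raw.ps < 0.75:
            jc = ng_distance("".join(codons1), "".join(codons2))
            assert jc.dS >= raw.dS

    def test_saturation_flagged(self):
        # doubly-synonymous codon pairs can push ps >= 3/4; the Jukes-Cantor
        # correction must then flag the distance as undefined
        s1 = "CGA" * 50
        s2 = "AGG" * 50
        raw = ng_distance(s1, s2, correction="none")
        assert raw.ps >= 0.75
        with pytest.warns(UserWarning, match="undefined"):
            res = ng_distance(s1, s2, correction="jukes_cantor")
        assert res.undefined
        assert np.isnan(res.dS)

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            ng_distance("ATGGCT", "ATG")


class TestPDistance:
    def test_identical_pair_zero(self):
        dm = p_distance_matrix({"a": "ACGT", "b": "ACGT"})
        assert dm.matrix[0, 1] == 0.0

    def test_one_of_four(self):
        dm = p_distance_matrix({"a": "ACGT", "b": "ACGA"})
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_complete_deletion_strikes_gap_columns(self):
        aln = {"a": "ACGTA", "b": "AC-TA", "c": "ACGTT"}
        struck = {"a": "ACTA", "b": "ACTA", "c": "ACTT"}
        dm = p_distance_matrix(aln, deletion="complete")
        dm2 = p_distance_matrix(struck, deletion="complete")
        assert np.allclose(dm.matrix, dm2.matrix)

    def test_all_gap_column_invariance(self):
        aln = {"a": "ACGT", "b": "ACGA", "c": "TCGA"}
        padded = {k: v + "-" for k, v in aln.items()}
        assert np.allclose(
            p_distance_matrix(aln).matrix, p_distance_matrix(padded).matrix
        )

    def test_zero_retained_sites_error(self):
        with pytest.raises(ValueError):
            p_distance_matrix({"a": "--", "b": "AC"})


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) as an additive matrix
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 8, 9],
                [3, 0, 9, 10],
                [8, 9, 0, 9],
                [9, 10, 9, 0],
            ],
            float,
        )
        tree = neighbor_joining(DistanceMatrix(labels, D))
        bips = tree_bipartitions(tree)
        assert bips == {frozenset({"C", "D"}): pytest.approx(3.0)}
        term = terminal_branch_lengths(tree)
        assert term == {
            "A": pytest.approx(1.0),
            "B": pytest.approx(2.0),
            "C": pytest.approx(4.0),
            "D": pytest.approx(5.0),
        }
        assert sum_branch_lengths(tree) == pytest.approx(15.0)

    def test_three_taxon_closed_form(self):
        labels = ["x", "y", "z"]
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, D))
        term = terminal_branch_lengths(tree)
        assert term["x"] == pytest.approx((5 + 9 - 10) / 2)
        assert term["y"] == pytest.approx((5 + 10 - 9) / 2)
        assert term["z"] == pytest.approx((9 + 10 - 5) / 2)

    def test_label_permutation_invariance(self, rng):
        edges, leaves = random_unrooted_tree(rng, 6)
        labels, D = tree_distance_matrix(edges, leaves)
        tree1 = neighbor_joining(DistanceMatrix(labels, D))
        perm = rng.permutation(len(labels))
        labels2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        tree2 = neighbor_joining(DistanceMatrix(labels2, D2))
        b1 = tree_bipartitions(tree1)
        b2 = tree_bipartitions(tree2)
        assert set(b1) == set(b2)
        for k in b1:
            assert b1[k] == pytest.approx(b2[k])

    def test_random_additive_trees_exact(self, rng):
        for n_taxa in (4, 5, 6, 8):
            edges, leaves = random_unrooted_tree(rng, n_taxa)
            labels, D = tree_distance_matrix(edges, leaves)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            got = tree_bipartitions(tree)
            want = true_bipartitions(edges, leaves)
            assert set(got) == set(want)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-9)
            assert sum_branch_lengths(tree) == pytest.approx(
                sum(edges.values()), abs=1e-9
            )

    def test_agrees_with_scikit_bio(self, rng):
        """Independent NJ oracle: scikit-bio's implementation."""
        skbio = pytest.importorskip("skbio")
        edges, leaves = random_unrooted_tree(rng, 7)
        labels, D = tree_distance_matrix(edges, leaves)
        ours = neighbor_joining(DistanceMatrix(labels, D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        ref = sorted(labels)[0]
        all_set = frozenset(labels)
        their_bips = set()
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = all_set - side
            if 2 <= len(side) <= len(labels) - 2:
                their_bips.add(side)
        assert set(tree_bipartitions(ours)) == their_bips

    def test_two_taxa_trivial(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            tree = neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0, 2.0], [2.0, 0]]))
            )
        assert sum_branch_lengths(tree) == pytest.approx(2.0)


class TestBootstrap:
    def _diagnostic_alignment(self, rng):
        # two clearly separated pairs: (a,b) vs (c,d) differ at many sites
        base = "".join(rng.choice(list("ACGT"), size=300))
        arr = np.array(list(base))
        flip = {"A": "G", "C": "T", "G": "A", "T": "C"}
        other = np.array([flip[ch] for ch in arr])
        sites = rng.choice(300, size=80, replace=False)
        seq_cd = arr.copy()
        seq_cd[sites] = other[sites]
        noise = lambda s, k: _mutate(s, rng, k)
        return {
            "a": "".join(arr),
            "b": _mutate("".join(arr), rng, 3),
            "c": "".join(seq_cd),
            "d": _mutate("".join(seq_cd), rng, 3),
        }

    def test_strong_split_high_support(self, rng):
        aln = self._diagnostic_alignment(rng)
        tree, supports = bootstrap_support(aln, n_replicates=200, seed=5)
        split = frozenset({"c", "d"})
        assert split in supports
        assert supports[split] >= 99.0

    def test_seed_determinism(self, rng):
        aln = self._diagnostic_alignment(rng)
        _, s1 = bootstrap_support(aln, n_replicates=50, seed=11)
        _, s2 = bootstrap_support(aln, n_replicates=50, seed=11)
        assert s1 == s2

    def test_invariant_alignment_flagged(self):
        aln = {"a": "ACGT" * 20, "b": "ACGT" * 20, "c": "ACGT" * 20, "d": "ACGT" * 20}
        with pytest.warns(UserWarning, match="no variable sites"):
            bootstrap_support(aln, n_replicates=10, seed=0)


def _mutate(seq, rng, n_changes):
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=n_changes, replace=False)
    for p in pos:
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    return "".join(arr)


class TestDating:
    def test_rate_calibration(self):
        assert calibrate_rate(0.108, 5.4e6) == pytest.approx(1.0e-8)

    def test_zero_distance_zero_rate(self):
        assert calibrate_rate(0.0, 1e6) == 0.0

    def test_algebraic_round_trip(self):
        r, T = 3.3e-9, 7.1e6
        assert calibrate_rate(2 * r * T, T) == pytest.approx(r)

    def test_persistence_dating(self):
        assert divergence_time(0.27, 1.0e-8) == pytest.approx(13.5e6)

    def test_coevolution_dating(self):
        assert coevolution_time(0.010, 1.0e-8) == pytest.approx(1.0e6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            calibrate_rate(0.1, 0)
        with pytest.raises(ValueError):
            divergence_time(0.1, 0)
        with pytest.raises(ValueError):
            coevolution_time(0.1, -1)


class TestPolymorphism:
    def test_identical_sequences(self):
        seqs = {f"s{i}": "ACGTACGT" for i in range(5)}
        assert count_polymorphic_sites(seqs) == (0, 8)

    def test_planted_variable_columns(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=60))
        seqs = {f"s{i}": base for i in range(5)}
        arr = {k: list(v) for k, v in seqs.items()}
        for col in (3, 17, 42):
            arr["s1"][col] = {"A": "C", "C": "A", "G": "T", "T": "G"}[base[col]]
        seqs = {k: "".join(v) for k, v in arr.items()}
        assert count_polymorphic_sites(seqs) == (3, 60)

    def test_gap_columns_excluded_from_total(self):
        seqs = {"a": "ACGT-", "b": "ACGA-", "c": "ACGAC"}
        assert count_polymorphic_sites(seqs) == (1, 4)

    def test_complete_deletion_helper(self):
        clean = complete_deletion({"a": "AC-T", "b": "ACGT"})
        assert clean == {"a": "ACT", "b": "ACT"}


class TestMotifScan:
    NLS = "RVPLRKKKKAL"

    def test_planted_literal(self, rng):
        aas = list("ACDEFGHIKLMNPQSTVWY")
        background = "".join(rng.choice(aas, size=600))
        seq = background[:299] + self.NLS + background[299:]
        hits = scan_motif(seq, self.NLS)
        assert (300, self.NLS) in hits

    def test_degenerate_pattern_with_wildcard(self):
        pattern = "(A/V)(M/A/V)(K/R)IF(R/Q)SIQXER"
        assert scan_motif("AMKIFRSIQAER", pattern) == [(1, "AMKIFRSIQAER")]
        assert scan_motif("VVRIFQSIQZER".replace("Z", "W"), pattern) == [
            (1, "VVRIFQSIQWER")
        ]

    def test_absent_pattern(self):
        assert scan_motif("AAAAAA", "GGP(R/K)") == []

    def test_n_terminal_elf3_motif(self):
        pattern = "GGP(R/K)(P/A)PPRNKMA"
        assert scan_motif("XGGPRPPPRNKMAX".replace("X", "G"), pattern) == [
            (2, "GGPRPPPRNKMA")
        ]
        assert scan_motif("GGGPKAPPRNKMA", pattern) == [(2, "GGPKAPPRNKMA")]

    def test_overlapping_matches(self):
        assert scan_motif("AAAA", "AA") == [(1, "AA"), (2, "AA"), (3, "AA")]

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern.parse("")
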