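# Methods

## The setting

Heteromorphic self-incompatibility couples a floral dimorphism (short- vs
long-styled flowers) to intra-morph incompatibility, both controlled by a
single *S*-locus: short-styled plants are *S/s*, long-styled plants *s/s*.
A gene present on the *S* haplotype and absent from *s* is hemizygous,
inherited as a dominant presence/absence character, and a natural
candidate for the morph-determining function. The package implements the
computational chain by which such a gene is found (differential k-mer
screening of two-morph transcriptomes), genetically validated (testcross
cosegregation, landrace association, and a model of how association would
decay if the gene were merely linked), and evolutionarily characterized
(synonymous-distance dating of its persistence and disruption).

## K-mer subtraction

A contig assembled from the short-morph transcriptome is screened against
the set of all k-mers (default k = 32) occurring in reads from the
long-morph transcriptome. The verdict is `retained` iff the fraction of
the contig's k-mer windows found in the reference set is ≤
`max_shared_fraction` (default 0: any shared k-mer eliminates, the strict
reading of the screen); contigs with no valid window are `too_short`.

Numerical/representation choices:

* K-mers are 2-bit encoded (A=0, C=1, G=2, T=3) and stored in a Python
  hash set — exact membership, no probabilistic filters. Canonical form is
  the minimum of a k-mer and its reverse complement; because the encoding
  is order-preserving, numeric and lexicographic minima coincide.
* Canonicalization is on by default: cDNA reads may come from either
  strand, and the canonical set of a read equals that of its reverse
  complement.
* Windows containing any non-ACGT character are skipped, not expanded.
* The configurable shared-fraction threshold exists because sequencing
  errors and repeats make the strict zero-sharing rule brittle on real
  data; the default keeps the strict rule.

Correctness is checked against an independent quadratic substring oracle
(every contig window searched literally in every read and its reverse
complement) on hundreds of random instances, and against planted truth in
the synthetic demo. Monotonicity properties (adding reads can only
eliminate; raising the threshold can only retain) are tested directly.

## Linkage and association

A testcross (short *S/s* × long *s/s*) exposes one informative meiosis per
offspring — the short parent's; the long parent is homozygous at *S*.
Recombinants are the (short, marker−) and (long, marker+) offspring. The
one-sided exact upper bound on the recombination fraction is the
Clopper–Pearson beta quantile `Beta(conf; x+1, n−x)`; for x = 0 this is
1 − (1−conf)^(1/n). Map distance defaults to cM = 100·r (at the
sub-centimorgan scale involved, Haldane and Kosambi corrections change the
third decimal; both are offered). Confidence defaults to 95%; with 1,373
meioses and zero recombinants the bound is 0.218 cM, which falls inside —
and is tighter than — the published 0.0–0.4 cM statement, whose derivation
(confidence level or rounding allowance) is not stated; the package
asserts only that its exact bound lies within the printed interval.

The association test is the two-sided Fisher exact probability of the 2×2
morph × marker table, computed by direct hypergeometric enumeration (sum
of pmf over tables with the observed margins whose probability does not
exceed the observed one, with a 1+1e−9 slack factor against floating-point
ties). An empty margin degenerates to p = 1 with a warning.

### Decay of association under heteromorphic SI

Obligate intermorph mating means every cross is *S/s* × *s/s* with morphs
at equal frequency. Haplotypes fall in three classes — *S* (all in short
plants, population share ¼), *s* in short plants (share ¼), and *s* in
long plants (share ½) — with marker-positive frequencies a, b, c. Only
the *S/s* parent's meiosis can recombine, so:

    a′ = (1−r)a + r·b          (S gamete, to a short offspring)
    b′ = c                     (short offspring's s comes from the long parent)
    c′ = ½[(1−r)b + r·a] + ½c  (long offspring's two s haplotypes)

The population marker frequency a/4 + b/4 + c/2 is conserved exactly (to
1e−12 over 10⁴ generations in tests, limited only by float rounding).
From the initial population — short plants marker+ *S* / marker− *s*
heterozygotes, long plants marker− homozygotes, i.e. (a,b,c) = (1,0,0) —
any r > 0 drives the state to the fixed point (¼,¼,¼), where the fraction
of marker-carrying plants is Sx = Lx = 1 − (¾)² = 7/16 in both morphs.
Carrier fractions along the trajectory use the exact offspring pairing:
Sx = 1 − (1−a)(1−b); Lx pairs the short parent's s gamete frequency
(1−r)b + ra with the long parent's c (at generation 0, both long-plant
haplotypes are class c). These conservation and fixed-point properties,
rather than printed curves, validate the recurrence.

## Molecular evolution

**Site counting (modified Nei–Gojobori).** Each codon position contributes
one site, split synonymous/nonsynonymous by the weighted fraction of
single-base changes preserving the amino acid; transitions carry weight R,
transversions 1; changes to stops are excluded from the weighting. R = 1
recovers classical NG exactly (verified against an independent
enumeration oracle across all 61 sense codons). R defaults to 1 because
the ratio actually used in the original analysis is unstated.

**Difference counting.** Codon pairs differing at 2–3 positions average
synonymous/nonsynonymous step counts over all minimal pathways with equal
weights; pathways through stop codons are excluded (if all are blocked —
not reachable for sense-codon pairs in practice — all pathways are used as
a documented fallback). ps = Sd/S and pn = Nd/N; the Jukes–Cantor
correction d = −¾ln(1 − 4p/3) is applied by default and flagged undefined
at p ≥ ¾. Codons with gaps, ambiguity or stops are excluded pairwise.
Note two NG artifacts surfaced by tests: Sd can exceed S for
doubly-synonymous codon pairs (ps > 1 is possible and is flagged through
the JC guard), and pathway averaging can attribute fractional
nonsynonymous differences even when every substitution event was
synonymous.

**p-distances, NJ, bootstrap.** Complete deletion removes every column
with a gap/ambiguity in any sequence before counting mismatches. Neighbor
joining is the standard Saitou–Nei agglomeration on the Q-criterion with
two-point branch-length formulas and a closed-form final three-node
resolution; ties in Q break to the smallest index pair, making the result
deterministic up to relabelling. Negative branch lengths are clamped to
zero for display, with pre-clamp lengths preserved per node and in the
tree's `preclamp_total_length` so the unclamped total stays auditable. NJ
is exact on additive matrices (tested on random 4–8-taxon trees) and
cross-checked against scikit-bio's implementation. Bootstrap resamples
alignment columns (nucleotide sites) with replacement, rebuilds
p-distance + NJ trees, and reports each reference bipartition's frequency
as a percentage; 500 replicates is the conventional default.

**Dating.** Strict clock throughout: rate = d/(2T) from a calibration
split (0.108/site and 5.4 MY give 1.0×10⁻⁸/site/yr); pairwise divergence
time = d/(2·rate); for a within-species allele genealogy the coevolution
time is total tree length divided by the rate (the total already sums over
lineages, so it is not halved).

## Synthetic data

The generator reproduces the study conditions at desk scale:

* **Transcriptomes** — i.i.d. uniform ACGT sequences, lengths uniform on
  200–3,000 bp (the real contigs spanned 61–5,334 bp; the floor of twice
  the k-mer size keeps every gene screenable). Shared genes differ between
  morphs at fixed allelic SNPs (default rate 10⁻³ per site, reflecting a
  sib-mated line with little inter-morph background divergence);
  *S*-specific genes exist only in the short-morph set. Uniform random
  sequence makes accidental 32-mer sharing between unrelated genes
  vanishingly rare, matching the screen's discriminative assumption; the
  generator does not emulate repeats, paralogy or assembly artifacts, so
  passing tests demonstrate the screen's logic, not its robustness to
  repetitive real transcriptomes (the shared-fraction threshold exists for
  that).
* **Reads** — 50-mer pairs (the study's read length) under normal fragment
  geometry (mean 200, sd 20), substitution errors only (bounded at 10%),
  both-strands by default since library strandedness is unstated; fragment
  and error random streams are separated so fragment geometry is invariant
  to the error rate. No quality-score or coverage-bias modelling.
* **Testcross** — each offspring draws the S gamete with probability ½ and
  a recombination event with probability r; recombinant offspring are
  exactly the morph/marker-discordant ones. The default population size is
  1,373, the study's panel.
* **Codon alignments** — a 61-state sense-codon CTMC with uniform codon
  frequencies and symmetric structure (transition factor κ, nonsynonymous
  factor ω), scaled so branch length is expected substitutions per
  nucleotide site; branches apply exp(Qt) site-by-site (rate-matrix
  simulation, not acceptance/rejection), so stops are unreachable by
  construction. The mapping from a target NG-estimated dS to a separation
  t is computed exactly from the chain (expected pathway-counted
  differences under exp(Qt), JC-corrected) and inverted numerically —
  estimator-recovery tests therefore close the simulator/estimator loop
  without free constants. Simulations behind the published divergences use
  κ = 2, ω = 0.2 (typical coding-gene values) and the S-ELF3 coding length
  (1,362 codons ≈ 4,087 nt) or 5,000 codons for variance-sensitive
  recovery checks; recovery runs use 6–10 replicates, sized so the
  standard error of the mean dS sits well inside the two-decimal rounding
  the published values carry.

## Design choices on open points

* The association-decay recurrence is this package's derivation from the
  stated mating system and initial condition; it is validated by its exact
  conservation law and fixed point rather than by curve comparison.
* Coverage of the exact linkage interval is verified analytically — the
  coverage probability computed from the binomial distribution of
  recombinant counts is ≥ 0.95 for each tested r — with empirical
  simulation required only to agree within binomial noise; at n = 5,000
  the true coverage is 0.9505–0.9534, so a raw empirical threshold at 0.95
  would reject a correct implementation about half the time.
* Real-data contigs are accepted as assembler output (FASTA); assembly is
  not reimplemented. The deposited accession sequences are not bundled, so
  distance checks against the published self-compatible-lineage dS values
  run on synthetic alignments evolved to those divergences.

## Limitations

No indel or quality modelling in reads; no expression-level simulation;
no population structure in the landrace association (protein-variation
data argue structure is negligible in this crop); NG dating inherits the
strict-clock and JC assumptions; maximum-likelihood protein trees are out
of scope (existing phylogenetics software covers them).
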