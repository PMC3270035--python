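# haplospec

Discovery and genetic/evolutionary validation of **haplotype-specific
genes** — genes present on only one haplotype of a supergene region, such
as the *S*-locus controlling heteromorphic self-incompatibility (SI) in
buckwheat (*Fagopyrum esculentum*). In heterostylous species the
short-styled morph is heterozygous *S/s* and the long-styled morph is
*s/s*; a gene carried hemizygously on the dominant *S* haplotype is
present in every short-styled plant and absent from every long-styled
plant, so it behaves as a dominant presence/absence marker — and is a
candidate for controlling the morph itself.

The package implements the complete desk-side analysis chain for such a
gene:

1. **k-mer in-silico subtraction** (`haplospec.subtraction`) — screen
   contigs assembled from the short-morph transcriptome against the set of
   all 32-mers occurring in long-morph reads; a contig is retained iff it
   shares no 32-mer with the reference set (threshold configurable).
   K-mers are stored canonically (lexicographic min of a word and its
   reverse complement) in an exact 2-bit-encoded hash set.
2. **Cosegregation and association genetics** (`haplospec.genetics`) —
   recombinant counting in a testcross (*S/s* × *s/s*), exact one-sided
   Clopper–Pearson upper bounds on the recombination fraction *r*
   (for zero recombinants, *r*₉₅ = 1 − 0.05^(1/n), mapped to cM),
   Fisher's exact test by hypergeometric enumeration, and a recurrence for
   the decay of marker–morph association under obligate intermorph mating:
   *a′* = (1−*r*)*a* + *rb*, *b′* = *c*, *c′* = ½[(1−*r*)*b* + *ra*] + ½*c*,
   with the invariant *a*/4 + *b*/4 + *c*/2 and limit (¼, ¼, ¼) where the
   marker-carrier fraction is 7/16 in both morphs.
3. **Molecular evolution** (`haplospec.evolution`) — synonymous and
   nonsynonymous distances by the (modified) Nei–Gojobori method with
   transition/transversion-weighted site counting (reducing to classical
   NG at *R* = 1) and equal-weight minimal-pathway counting of
   differences; p-distance matrices with complete deletion; Saitou–Nei
   neighbor joining with column-bootstrap supports; strict-clock rate
   calibration (rate = *d*/2*T*) and dating (*T* = *d*/2·rate for splits,
   *T* = tree length/rate for allele genealogies); polymorphic-site
   counts; degenerate protein-motif scanning.
4. **Synthetic data** (`haplospec.simulate`) — two-morph transcriptomes
   with planted *S*-specific genes, paired short reads, testcross
   populations with configurable *r*, and codon alignments evolved under a
   61-state sense-codon Markov chain to controlled synonymous divergence.

## Worked example

```sh
python examples/01_kmer_subtraction.py
```

```
screened 55 short-morph contigs against 88,548 long-morph 32-mers
retained 5, eliminated 50
retained contigs: s_specific_0000, s_specific_0001, s_specific_0002, s_specific_0003, s_specific_0004
exact recovery of planted S-specific genes: True
```

Fifty genes expressed in both morphs share essentially all their 32-mers
with the long-morph reads and are eliminated; the five genes planted only
on the *S* haplotype share none and survive — the subtraction recovers the
haplotype-specific genes exactly.

```sh
python examples/02_linkage_and_association.py
```

```
0 recombinants in 1373 informative meioses
exact one-sided 95% upper bound: r <= 0.00218 (0.218 cM)

47-pair panel, complete association: Fisher exact p = 1.230e-27
```

Zero recombinants among 1,373 meioses bounds the marker–*S* distance below
0.22 cM; complete association in 47 landrace pairs has probability
2/C(94,47) ≈ 10⁻²⁷ under independence. `examples/03_association_decay.py`
shows why this matters: even *r* = 0.001 would halve the association
within ~450 generations, so complete association today implies the gene
sits at the *S*-locus. `examples/04_molecular_dating.py` and
`examples/05_trees_and_motifs.py` cover the dating chain (rate 1.0×10⁻⁸
/site/yr from a 0.108 distance and 5.4 MY split; persistence 13.5 MY from
dS = 0.27; coevolution ~1 MY from a genealogy of total length 0.010) and
tree/motif analyses.

A thin CLI mirrors the library: `haplospec subtract`, `linkage`, `assoc`,
`decay`, `distances`, `tree`, `date`, `motif`, `simulate-*`, and `run`
(YAML-configured multi-stage pipeline with a reproducibility manifest).

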