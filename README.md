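# mycomob

A curation toolkit for **transposable-element (TE) consensus libraries**,
built around the computational rules used to assemble large fungal TE
databases (MycoMobilome-style releases). Automated de novo repeat
discovery run across thousands of genome assemblies produces enormous
consensus libraries that are contaminated with multicopy host genes,
fragmentary sequences, and redundant family variants. `mycomob`
implements the decision core that turns such raw libraries into a
curated, consistently named resource — and quantifies, at base-pair
resolution, how two TE annotation methods agree on a genome.

It is a library-plus-CLI for bioinformaticians who already have the
outputs of the standard search tools (DIAMOND/BLASTp tabular hits,
HMMER domain tables, mmseqs-style cluster tables, BED/GFF3 annotations)
and need the curation logic applied reproducibly.

## What it computes

**Host-gene designation.** All six frames of each consensus are
translated and searched against a host reference proteome (RefSeq) and
against known TE proteins (peptide library + domain HMMs). After
threshold filtering (E ≤ 10⁻³ for BLAST-type hits; full-sequence
E ≤ 10⁻³ and bit score ≥ 50 for HMM hits), nested hits are resolved to
the best hit and adjacent/overlapping hits merged. With R the RefSeq
coverage and T the TE-protein coverage projected onto the consensus
(forward-strand nucleotide coordinates), a consensus is a putative host
gene iff

```
R ≠ ∅  and  ( T = ∅   or   ⌊ |R \ T| / 3 ⌋ ≥ 90 residues )
```

Consensus sequences with no protein hits at all are kept as putative
non-autonomous TEs.

**Evidence codes.** Each consensus gets `_PE` (protein evidence
concordant with its classification), `_DA` (discordant/conflicting
evidence), or `_NE` (no evidence), by mapping TE-protein subjects to
classifications through a user-supplied table.

**Quality filters.** Sequences < 120 bp or with ≥ 5% N are removed;
sequences curated from assemblies with N50 < 50 kb **and** BUSCO
completeness < 90% are flagged `LQGenome`.

**80-80-80 family clustering.** A greedy, longest-first,
link-to-representative clusterer accepts a member when it aligns to the
representative at ≥ 80% identity over ≥ 80% of the shorter sequence
(both strands checked; sequences ≥ 80 bp). Large libraries can instead
be clustered externally; the two-column cluster table is the adapter
contract.

**Persistent naming.** Families and members receive round-trippable
names:

```
MycMob1.1_family-12-ZymTri_PE#LTR/Gypsy @Zymoseptoria tritici
MycMob1.1_family-12_member-3-ZymTri_PE#LTR/Gypsy @Zymoseptoria tritici
```

**Annotation comparison.** Two annotation sets of one genome are
partitioned into shared / method-unique base pairs, with per-method
widths at shared loci and per-classification breakdowns.

## Worked example

All inputs can be generated synthetically — no downloads:

```bash
mycomob fixture --seed 42 --out fx
mycomob curate \
    --fasta fx/library.fasta \
    --refseq-blast fx/refseq_hits.blast.tsv \
    --te-blast fx/te_peptide_hits.blast.tsv \
    --te-domtbl fx/te_hmm_hits.domtbl \
    --genomes fx/genomes.tsv \
    --source-genomes fx/source_genomes.tsv \
    --class-map fx/te_class_map.tsv \
    --out curated
```

which logs:

```
INFO mycomob: input_records: 11
INFO mycomob: host_gene_removed: 4
INFO mycomob: quality_removed: 3
INFO mycomob: retained: 4
INFO mycomob: non_autonomous: 1
INFO mycomob: lq_genome_flagged: 1
```

The 11-record fixture plants 2 branch-(i) and 2 branch-(ii) host genes
(all 4 removed), 2 too-short and 1 N-rich record (3 removed by quality),
and 4 genuine TEs — including one at exactly 89 exclusive RefSeq
residues, which correctly survives the 90-residue rule. The retained
clustered library (`curated/clustered.fasta`) starts:

```
>MycMob1.1_family-1-ZymTri_PE#LTR/Gypsy @Zymoseptoria tritici
GATTTCACCTGTTGAAAGATATGAACCCGAAGTCTCCACCGAACAAGTGATGGAGAGATA
...
```

`curated/verdicts.tsv` records the per-record outcome (host-gene flag,
evidence code, quality reasons, exclusive residues) and
`curated/name_map.tsv` maps original ids to assigned names.

Comparing the fixture's planted annotation pair:

```bash
mycomob compare --a fx/annotations_methodA.bed --b fx/annotations_methodB.bed --out cmp
# INFO mycomob: shared 67.51% | unique methodA 13.26% | unique methodB 19.22% of all annotated bp
```

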