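# Methods

## Coordinate conventions and frame projection

All interval logic is 0-based half-open on a single axis; 1-based
inclusive coordinates exist only at the parse/emit boundary of external
formats (BLAST tabular query coordinates, HMMER envelope coordinates,
GFF3). Protein hits arrive in residue coordinates of one of six
translation frames (1–3 forward at offsets 0–2; 4–6 on the reverse
complement at offsets 0–2, transeq numbering). A residue span
`[a, b)` in frame *f* projects to nucleotides

* forward: `[3a + (f−1), 3b + (f−1))`
* reverse: computed on the reverse complement and mirrored through the
  sequence length, so the result is always on the forward strand.

The projected interval always has length `3(b − a)` and lies inside
`[0, L)`; this is what makes RefSeq and TE-protein coverage comparable
when the underlying hits sit in different frames. Translation uses the
standard genetic code; stop codons are kept as `*` internally (an
emit-time `clean` option renders them `X`, matching the common
translator behaviour), and any codon containing `N` renders `X`.
Soft-masking (lowercase) is discarded on read; nothing downstream uses
it.

## Hit processing

Three hit categories are filtered independently with inclusive
comparisons, exactly as the thresholds are stated: hits against the
host proteome and against the TE peptide library at E ≤ 10⁻³; HMM
domain hits at full-sequence E ≤ 10⁻³ **and** full-sequence bit score
≥ 50. Domain tables are parsed per domain line with envelope
coordinates as the span and full-sequence statistics as the scores (the
statistics the filter is defined on). BLAST rows with `qstart > qend`
are normalized by swapping, since the frame already lives in the query
id suffix.

Nested-hit resolution keeps, for any containment pair, the
higher-quality hit (bit score, then E-value, then span length, then
subject id) — including the case where a weak container loses to a
strong contained hit. Hits are processed best-first against the kept
set, which realizes the pairwise fixpoint deterministically. Merging
then coalesces spans that overlap, touch, or are separated by at most
`gap_max_nt` (default 30 nt = 10 residues; configurable). The default
tolerates short indels/frameshifts between split HSPs of one protein
without bridging unrelated domains. Both steps run per subject
category, so host and TE coverage are each built the same way before
the rule compares them.

## Host-gene rule

Branch (i): RefSeq coverage present, TE coverage empty → host gene.
Branch (ii): both present → exclusive residues =
`⌊ covered(R \ T) / 3 ⌋`, host gene iff ≥ 90. Counting happens on the
shared nucleotide axis because the two hit classes generally occupy
different frames; dividing by three converts back to residue units
after the set subtraction. By default the RefSeq coverage is the union
over all RefSeq subjects — the conservative reading, leaning toward
removal; a `per_subject` mode instead requires a single subject to
reach 90 exclusive residues on its own (the phrase "aligned to a RefSeq
query" admits both readings; the union is the default and the choice is
part of the run configuration). Records with no hits at all are
retained as putative non-autonomous TEs.

Trade-off inherited from the design: domesticated transposase genes are
indistinguishable from TEs by this rule and are not treated specially.

## Evidence codes

A mapped TE-protein hit is *concordant* with the consensus
classification iff the high-level classes match and the sub-level
classes match whenever both are defined; any mapped non-concordant hit
is *discordant*. `PE` requires at least one concordant and zero
discordant hits; any discordant hit forces `DA` — conflict is exactly
the signal `DA` exists to carry, so a Gypsy-classified element
supported only by Copia proteins is `DA`, and a consensus classified
`Unknown` with mapped hits is `DA` (the evidence contradicts the
absence of a classification). `NE` means no mapped TE-protein evidence,
which includes unmapped or blank mapping entries (these emit a warning
and are ignored). Subject resolution is exact-match first, then longest
prefix, so both accession prefixes and profile-name families work.

In the end-to-end pipeline, family-level evidence is the
representative's code, propagated to members at naming time; each
member's verdict also records its own per-record code.

## Quality and genome flags

A poor-quality consensus is `< 120 bp` (strict) or `≥ 5% N`
(inclusive) — both boundaries are tested at 119/120 nt and 4.9/5.0%.
`LQGenome` requires **both** low contiguity (N50 < 50 kb) and low
completeness (BUSCO complete < 90%); N50 is the smallest contig length
whose descending cumulative sum reaches half the assembly total, and
can be supplied precomputed or derived from contig lengths. A missing
BUSCO value is an error rather than a silent pass.

Stage order follows the library-construction accounting: host-gene
removal runs first, then quality filtering of the survivors, then
evidence and genome flags; a record failing both rules is counted once,
as a host gene. Every record ends in exactly one of
{host gene, quality-removed, retained}.

## Clustering

The 80-80-80 family criterion (≥ 80% identity over ≥ 80% of the shorter
sequence, sequences ≥ 80 bp) is realized as greedy longest-first
clustering against representatives, CD-HIT style: identity =
matches / alignment columns and coverage = aligned span of the shorter
sequence / its length, from a best local alignment (match +1,
mismatch −1, gap open −2, gap extend −1; all configurable). Coverage of
the shorter sequence mirrors target-coverage clustering mode.
Reverse-complement matching is on by default because nucleotide TE
copies occur on both strands. Clustering operates in nucleotide space.

This is a reference implementation for desk-scale libraries (≲ 10⁴
sequences), not a cascaded indexer; production-scale libraries should
be clustered externally, and the two-column
(representative, member) TSV is the adapter contract that makes the
two interchangeable. Greedy linking to a representative approximates,
but does not replicate, cascaded clustering; downstream family
semantics depend only on the acceptance rule itself. Records below the
80 bp rule floor are rejected by the clusterer; the end-to-end pipeline
routes them into singleton clusters (they are removed by the 120 bp
quality filter anyway).

## Naming

Family numbers are assigned in deterministic order (descending cluster
size, ties by representative id) so renaming is a pure function of its
inputs; an identity map pins representative→number across releases, and
new numbers continue after the largest pinned value. The clustered
template carries the six-letter species code in the family block; the
member template carries it in the member block only, with the family
number shared. The species code is the first three alphabetic
characters of genus and epithet, each capitalized and padded with `x`
(`Zymoseptoria tritici` → `ZymTri`); collisions are tolerated because
the family number, not the code, is the unique key. The `LQGenome`
token sits after the evidence code. Member numbers run 1..k over
retained members of a family, representative first.

## Annotation comparison

Two accounting modes are always computed and clearly labelled.
Position-level: a genomic position is shared when covered by both
methods; the three categories partition all annotated positions, giving
the conservation identity `covered_A = shared + unique_A` that the test
suite asserts on random instances. Feature-width level: each method's
merged feature counts its full width as shared when it overlaps the
other method's coverage — annotation widths differ between methods at
the same locus, so shared bp are reported per method rather than as one
number. Percentages are of all annotated base pairs and sum to 100
within rounding. Strand is ignored; within-method features of the same
class are merged before comparison, and per-class breakdowns follow the
owning method's high-level classification.

## Synthetic data

The fixture generator emulates hit *geometry*: where alignments fall on
a consensus, in which frame, with what scores. The default library
(11 records) plants both host-gene branches, one borderline case at
exactly 89 exclusive residues, sub-threshold hits that must be filtered
out, nested hits, the PE/DA/NE evidence situations, short and N-rich
sequences, and one record from a low-quality assembly. Family sets for
clustering derive each family from a random 300–2000 nt ancestor by
per-position substitution (rate 0.05 by default, comfortably inside the
80% identity rule); split tests forge pseudo-families from one root at
35% divergence (expected cross-identity ≈ 0.65, comfortably outside).
Annotation pairs plant shared loci with method-specific widths plus
unique loci per method.

All expected outcomes are computed at generation time by private
per-position brute-force routines (boolean masks, literal threshold
constants) that re-derive the projection and gap-fill arithmetic
independently of the package modules. One seed drives everything;
outputs are byte-identical across runs. What the generator does *not*
emulate: realistic TE evolution (terminal repeats, nesting, indels,
chimerism) — so green fixture tests certify the decision rules, not
discovery performance on real repeat landscapes.

## Numerical and testing choices

Interval sets are canonical (sorted, disjoint, touching intervals
merged), so equality is structural. The clustering tests verify scores
against an independently written full-DP affine-gap Smith–Waterman
oracle and verify every clustered member against its representative
with that oracle; identity of co-optimal alignments can differ between
tracebacks, so oracle identity comparisons are restricted to geometries
where the optimum is effectively unique (mutated copies without
indels). Oracle-equivalence checks run on 1000 random interval
geometries for the host-gene rule and interval merging, 200–1000 for
the comparison accounting, and 20 seeded replicates for clustering
recovery — sizes chosen to exercise the combinatorics densely while
keeping the default suite fast.

## Known limitations

* Greedy clustering is order-dependent by construction (longest-first,
  ties by id); it honors the acceptance rule exactly but can differ
  from cascaded clusterers on borderline members.
* The 80-80-80 rule itself over-merges young families and over-splits
  ancient ones; both clustered and unclustered outputs are emitted so
  users can re-cluster under other criteria.
* Evidence mapping quality is bounded by the supplied subject→class
  table; unmapped subjects silently become `NE` (with a warning).
* The comparison treats annotations as genomic extents; it does not
  resolve overlapping annotations within a method beyond per-class
  merging, and it ignores strand.
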