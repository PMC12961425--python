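"""Curation rules: host-gene designation, evidence codes, quality filters.

A consensus produced by automated repeat discovery may actually be a
multicopy host gene. The host-gene rule compares, on the shared
nucleotide axis of the consensus, coverage by host-proteome (RefSeq)
hits against coverage by known-TE-protein hits:

* branch (i): RefSeq hits present and no TE hits -> host gene;
* branch (ii): both present -> the consensus is a host gene iff at least
  ``exclusive_residues_min`` residues (default 90) aligned to RefSeq lie
  outside all TE-hit coverage.

Consensus sequences with no hits at all are retained as putative
non-autonomous TEs. Retained sequences then pass quality filters
(minimum length, maximum N fraction), receive an evidence code
(PE = protein evidence concordant with the assigned classification,
DA = discordant/conflicting evidence, NE = no evidence), and are flagged
``LQGenome`` when their source assembly has both low contiguity
(N50 < 50 kb) and low completeness (BUSCO < 90%).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from . import hitio
from .hitio import HOST_REFSEQ, TE_HMM, TE_PEP, IntervalSet, ProteinHit
from .seqio import ConsensusRecord, copy_with, n_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "CurationThresholds",
    "GenomeMetadata",
    "CurationVerdict",
    "ClassMap",
    "n50",
    "classify_host_gene",
    "label_evidence",
    "quality_filter",
    "flag_lq_genome",
    "curate_library",
    "read_genome_metadata_tsv",
    "read_class_map_tsv",
    "write_verdicts_tsv",
]

REASON_HOST_GENE_NO_TE = "HOST_GENE_NO_TE_HITS"
REASON_HOST_GENE_EXCLUSIVE = "HOST_GENE_EXCLUSIVE_RESIDUES"
REASON_SHORT = "SHORT"
REASON_N_RICH = "N_RICH"


@dataclass(frozen=True)
class CurationThresholds:
    """Decision thresholds of the curation protocol.

    ``exclusive_residues_min``: RefSeq-aligned residues outside TE coverage
    needed to call a host gene (branch ii). ``min_length_nt`` / ``n_fraction_max``
    define a poor-quality consensus (< 120 bp, or >= 5% N). ``n50_min_bp`` and
    ``busco_complete_min_pct`` jointly define a low-quality source genome.
    """

    exclusive_residues_min: int = 90
    min_length_nt: int = 120
    n_fraction_max: float = 0.05
    n50_min_bp: int = 50_000
    busco_complete_min_pct: float = 90.0

    def __post_init__(self) -> None:
        if min(
            self.exclusive_residues_min,
            self.min_length_nt,
            self.n_fraction_max,
            self.n50_min_bp,
            self.busco_complete_min_pct,
        ) <= 0:
            raise ValueError("all curation thresholds must be positive")


@dataclass
class GenomeMetadata:
    """Assembly-quality metadata for one source genome."""

    assembly_id: str
    genus: str = ""
    species_epithet: str = ""
    contig_lengths: list[int] | None = None
    n50_bp: int | None = None
    busco_complete_pct: float | None = None

    def __post_init__(self) -> None:
        if self.contig_lengths is None and self.n50_bp is None:
            raise ValueError(
                f"{self.assembly_id}: need contig_lengths or a precomputed n50_bp"
            )

    @property
    def n50(self) -> int:
        if self.n50_bp is not None:
            return self.n50_bp
        return n50(self.contig_lengths)


@dataclass
class CurationVerdict:
    """Per-consensus outcome of the full curation pass."""

    consensus_id: str
    host_gene: bool = False
    non_autonomous: bool = False
    evidence: str = "NE"
    removed_quality: bool = False
    lq_genome: bool = False
    exclusive_refseq_residues: int = 0
    reasons: list[str] = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return not (self.host_gene or self.removed_quality)


def n50(contig_lengths: Sequence[int]) -> int:
    """Smallest contig length whose descending cumulative sum reaches half
    the assembly total."""
    if not contig_lengths:
        raise ValueError("no contig lengths")
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def classify_host_gene(
    refseq_cov: IntervalSet,
    te_cov: IntervalSet,
    th: CurationThresholds | None = None,
) -> tuple[bool, int]:
    """Apply the host-gene designation rule to one consensus.

    Both interval sets are forward-strand nucleotide coverage on the
    consensus. Returns ``(host_gene, exclusive_residues)`` where
    ``exclusive_residues = floor(bp covered by RefSeq but not TE / 3)``.
    """
    th = th or CurationThresholds()
    if not refseq_cov:
        return (False, 0)
    exclusive_nt = (refseq_cov - te_cov).total_length()
    exclusive_residues = exclusive_nt // 3
    if not te_cov:
        return (True, exclusive_residues)  # branch (i)
    return (exclusive_residues >= th.exclusive_residues_min, exclusive_residues)


class ClassMap:
    """Mapping from protein subject ids / profile names to TE classifications.

    Lookup is exact-match first, then longest matching prefix, so accession
    prefixes and profile-name families both work. Entries with an empty
    high-level class are uninformative and resolve to nothing.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]]):
        self._exact = {k: v for k, v in entries.items()}
        self._prefixes = sorted(self._exact, key=len, reverse=True)
        self._warned: set[str] = set()

    def resolve(self, subject_id: str) -> tuple[str, str] | None:
        hit = self._exact.get(subject_id)
        if hit is None:
            for p in self._prefixes:
                if subject_id.startswith(p):
                    hit = self._exact[p]
                    break
        if hit is None or not hit[0]:
            if subject_id not in self._warned:
                self._warned.add(subject_id)
                logger.warning(
                    "subject %r has no TE classification mapping; treated as unmapped",
                    subject_id,
                )
            return None
        return hit


def _concordant(
    class_high: str, class_sub: str, hit_high: str, hit_sub: str
) -> bool:
    if class_high != hit_high:
        return False
    if class_sub and hit_sub and class_sub != hit_sub:
        return False
    return True


def label_evidence(
    class_high: str,
    class_sub: str,
    te_hits: Iterable[ProteinHit],
    mapping: ClassMap | Mapping[str, tuple[str, str]],
) -> str:
    """Assign the PE / DA / NE evidence code for one consensus.

    ``te_hits`` must already be threshold-filtered. A mapped hit is
    concordant iff its high-level class matches the consensus
    classification, refined by the sub-level class when both sides define
    one; any mapped non-concordant hit is discordant. ``PE`` requires at
    least one concordant hit and no discordant hit; any discordant hit
    forces ``DA`` (conflicting evidence is the signal DA must carry);
    ``NE`` means no mapped TE-protein evidence at all. A consensus
    classified "Unknown" can never match, so mapped hits there yield DA.
    """
    if not isinstance(mapping, ClassMap):
        mapping = ClassMap(mapping)
    any_concordant = any_discordant = False
    for h in te_hits:
        if h.subject_category == HOST_REFSEQ:
            continue
        resolved = mapping.resolve(h.subject_id)
        if resolved is None:
            continue
        if _concordant(class_high, class_sub, resolved[0], resolved[1]):
            any_concordant = True
        else:
            any_discordant = True
    if any_discordant:
        return "DA"
    if any_concordant:
        return "PE"
    return "NE"


def quality_filter(
    record: ConsensusRecord, th: CurationThresholds | None = None
) -> tuple[bool, list[str]]:
    """Poor-quality test: length < 120 bp (strict) or N fraction >= 5%
    (inclusive). Returns (removed, reasons)."""
    th = th or CurationThresholds()
    reasons = []
    if len(record.sequence) < th.min_length_nt:
        reasons.append(REASON_SHORT)
    if n_fraction(record) >= th.n_fraction_max:
        reasons.append(REASON_N_RICH)
    return (bool(reasons), reasons)


def flag_lq_genome(
    meta: GenomeMetadata, th: CurationThresholds | None = None
) -> bool:
    """LQGenome iff N50 below 50 kb AND BUSCO completeness below 90%."""
    th = th or CurationThresholds()
    if meta.busco_complete_pct is None:
        raise ValueError(f"{meta.assembly_id}: BUSCO completeness missing")
    return meta.n50 < th.n50_min_bp and meta.busco_complete_pct < th.busco_complete_min_pct


def _category_coverage(
    hits: Sequence[ProteinHit], gap_max_nt: int
) -> IntervalSet:
    if not hits:
        return IntervalSet()
    return hitio.merge_adjacent(hitio.resolve_nested(hits), gap_max_nt)


def build_coverage(
    hits: Sequence[ProteinHit], gap_max_nt: int = hitio.DEFAULT_GAP_MAX_NT
) -> dict[str, IntervalSet]:
    """Per-category consensus coverage for one consensus's hits.

    Nested-hit resolution and adjacent-hit merging run independently per
    subject category; the two TE categories are then unioned under the
    key ``"TE"``.
    """
    by_cat: dict[str, list[ProteinHit]] = defaultdict(list)
    for h in hits:
        by_cat[h.subject_category].append(h)
    cov = {
        cat: _category_coverage(by_cat.get(cat, []), gap_max_nt)
        for cat in hitio.CATEGORIES
    }
    cov["TE"] = cov[TE_HMM] | cov[TE_PEP]
    return cov


def _host_gene_per_subject(
    refseq_hits: Sequence[ProteinHit],
    te_cov: IntervalSet,
    th: CurationThresholds,
    gap_max_nt: int,
) -> tuple[bool, int]:
    """Branch-(ii) variant evaluating each RefSeq subject separately."""
    by_subject: dict[str, list[ProteinHit]] = defaultdict(list)
    for h in refseq_hits:
        by_subject[h.subject_id].append(h)
    best = 0
    is_host = False
    for subject_hits in by_subject.values():
        cov = _category_coverage(subject_hits, gap_max_nt)
        hg, excl = classify_host_gene(cov, te_cov, th)
        best = max(best, excl)
        is_host = is_host or hg
    return (is_host, best)


def curate_library(
    records: Sequence[ConsensusRecord],
    hits: Sequence[ProteinHit],
    genome_meta: Mapping[str, GenomeMetadata] | None = None,
    thresholds: CurationThresholds | None = None,
    *,
    class_map: ClassMap | Mapping[str, tuple[str, str]] | None = None,
    gap_max_nt: int = hitio.DEFAULT_GAP_MAX_NT,
    host_gene_mode: str = "union",
) -> tuple[list[ConsensusRecord], list[CurationVerdict]]:
    """Run the full per-record curation pass over a library.

    ``hits`` must be threshold-filtered and projected to nucleotide
    coordinates. Stage order: host-gene designation first, then quality
    filtering of the survivors, then evidence codes and LQGenome flags —
    a record failing both rules is accounted once, as a host gene.
    Records with no hits at all are retained as putative non-autonomous
    TEs with evidence NE.

    ``host_gene_mode``: ``"union"`` pools coverage over all RefSeq
    subjects before counting exclusive residues (conservative toward
    removal, the default); ``"per_subject"`` requires a single RefSeq
    subject to reach the threshold on its own.

    Returns ``(retained_records, verdicts)``; retained records carry their
    evidence code and LQGenome flag.
    """
    thresholds = thresholds or CurationThresholds()
    if host_gene_mode not in ("union", "per_subject"):
        raise ValueError(f"unknown host_gene_mode {host_gene_mode!r}")
    if class_map is None:
        class_map = ClassMap({})
    elif not isinstance(class_map, ClassMap):
        class_map = ClassMap(class_map)

    ids = {r.record_id for r in records}
    orphans = sorted({h.consensus_id for h in hits} - ids)
    if orphans:
        raise ValueError(f"hits reference unknown consensus ids: {orphans}")

    by_cons: dict[str, list[ProteinHit]] = defaultdict(list)
    for h in hits:
        by_cons[h.consensus_id].append(h)

    genome_meta = genome_meta or {}
    retained: list[ConsensusRecord] = []
    verdicts: list[CurationVerdict] = []
    for rec in records:
        rec_hits = by_cons.get(rec.record_id, [])
        cov = build_coverage(rec_hits, gap_max_nt)
        te_hits = [h for h in rec_hits if h.subject_category in (TE_HMM, TE_PEP)]
        refseq_hits = [h for h in rec_hits if h.subject_category == HOST_REFSEQ]

        if host_gene_mode == "per_subject" and refseq_hits and cov["TE"]:
            host_gene, exclusive = _host_gene_per_subject(
                refseq_hits, cov["TE"], thresholds, gap_max_nt
            )
        else:
            host_gene, exclusive = classify_host_gene(
                cov[HOST_REFSEQ], cov["TE"], thresholds
            )

        evidence = label_evidence(rec.class_high, rec.class_sub, te_hits, class_map)

        verdict = CurationVerdict(
            consensus_id=rec.record_id,
            host_gene=host_gene,
            non_autonomous=not rec_hits,
            evidence=evidence,
            exclusive_refseq_residues=exclusive,
        )
        if host_gene:
            verdict.reasons.append(
                REASON_HOST_GENE_NO_TE if not cov["TE"] else REASON_HOST_GENE_EXCLUSIVE
            )
            verdicts.append(verdict)
            continue

        removed, reasons = quality_filter(rec, thresholds)
        verdict.removed_quality = removed
        verdict.reasons.extend(reasons)
        if removed:
            verdicts.append(verdict)
            continue

        lq = False
        if rec.source_genome:
            meta = genome_meta.get(rec.source_genome)
            if meta is not None:
                lq = flag_lq_genome(meta, thresholds)
            else:
                logger.warning(
                    "no genome metadata for assembly %r (record %s); "
                    "LQGenome left unset",
                    rec.source_genome,
                    rec.record_id,
                )
        verdict.lq_genome = lq
        verdicts.append(verdict)
        retained.append(copy_with(rec, evidence=evidence, lq_genome=lq))

    assert len(verdicts) == len(records)
    return retained, verdicts


def read_genome_metadata_tsv(path: Union[str, Path]) -> dict[str, GenomeMetadata]:
    """Read assembly metadata. Columns: assembly_id, genus, species_epithet,
    n50_bp (or blank), busco_complete_pct, contig_lengths (comma-separated,
    optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"assembly_id", "busco_complete_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, GenomeMetadata] = {}
    for _, row in df.iterrows():
        contigs = None
        if row.get("contig_lengths", ""):
            contigs = [int(x) for x in str(row["contig_lengths"]).split(",") if x]
        out[row["assembly_id"]] = GenomeMetadata(
            assembly_id=row["assembly_id"],
            genus=row.get("genus", ""),
            species_epithet=row.get("species_epithet", ""),
            n50_bp=int(float(row["n50_bp"])) if row.get("n50_bp", "") else None,
            contig_lengths=contigs,
            busco_complete_pct=float(row["busco_complete_pct"])
            if row["busco_complete_pct"]
            else None,
        )
    return out


def read_class_map_tsv(path: Union[str, Path]) -> ClassMap:
    """Read the subject -> TE classification table. Columns:
    subject_pattern, class_high, class_sub."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"subject_pattern", "class_high"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    entries = {
        row["subject_pattern"]: (row["class_high"], row.get("class_sub", ""))
        for _, row in df.iterrows()
    }
    return ClassMap(entries)


def write_verdicts_tsv(
    verdicts: Iterable[CurationVerdict], path: Union[str, Path]
) -> None:
    cols = (
        "consensus_id host_gene non_autonomous evidence removed_quality "
        "lq_genome exclusive_refseq_residues reasons"
    ).split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in verdicts:
            fh.write(
                "\t".join(
                    [
                        v.consensus_id,
                        str(v.host_gene),
                        str(v.non_autonomous),
                        v.evidence,
                        str(v.removed_quality),
                        str(v.lq_genome),
                        str(v.exclusive_refseq_residues),
                        ",".join(v.reasons),
                    ]
                )
                + "\n"
            )
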