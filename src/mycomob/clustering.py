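"""80-80-80 family clustering for desk-scale consensus libraries.

Two consensus sequences belong to one TE family when they align at >= 80%
identity over >= 80% of the shorter sequence and are >= 80 bp long. This
module provides a greedy, longest-first, link-to-representative clusterer
(CD-HIT style) honoring exactly that acceptance rule, plus the adapter
contract for delegating large libraries to an external cascaded clusterer:
both sides speak the same two-column (representative, member) TSV, so they
are interchangeable downstream.

Identity and coverage come from a best local alignment (match +1,
mismatch -1, gap open -2, gap extend -1 by default); reverse-complement
matching is on by default since nucleotide TE copies occur on both strands.
Not a performance substitute for a cascaded indexer above ~10^4 sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import Align

from .seqio import ConsensusRecord, reverse_complement

__all__ = [
    "ClusterParams",
    "FamilyCluster",
    "pairwise_identity_coverage",
    "alignment_score",
    "greedy_cluster",
    "write_cluster_tsv",
    "read_cluster_tsv",
]


@dataclass(frozen=True)
class ClusterParams:
    """The 80-80-80 family criterion plus alignment scoring.

    ``min_coverage`` is a fraction of the *shorter* sequence (target
    coverage of the contained partner, mirroring `--cov-mode 1`).
    """

    min_identity: float = 0.80
    min_coverage: float = 0.80
    min_length_nt: int = 80
    check_reverse_complement: bool = True
    match_score: float = 1.0
    mismatch_score: float = -1.0
    open_gap_score: float = -2.0
    extend_gap_score: float = -1.0

    def __post_init__(self) -> None:
        for frac in (self.min_identity, self.min_coverage):
            if not 0 < frac <= 1:
                raise ValueError("identity/coverage fractions must be in (0, 1]")
        if self.min_length_nt < 1:
            raise ValueError("min_length_nt must be positive")


@dataclass
class FamilyCluster:
    """One family: a representative and its members (representative included)."""

    representative_id: str
    member_ids: list[str]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster must have members")
        if self.representative_id not in self.member_ids:
            raise ValueError(
                f"representative {self.representative_id!r} not among members"
            )

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _make_aligner(params: ClusterParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.open_gap_score
    aligner.extend_gap_score = params.extend_gap_score
    return aligner


def _identity_coverage_from_alignment(
    aln: Align.Alignment, len_a: int, len_b: int
) -> tuple[float, float]:
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return (0.0, 0.0)
    identity = counts.identities / columns
    blocks_a, blocks_b = aln.aligned
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    short_span, short_len = (span_a, len_a) if len_a <= len_b else (span_b, len_b)
    return (identity, short_span / short_len)


def pairwise_identity_coverage(
    a: str, b: str, params: ClusterParams | None = None
) -> tuple[float, float]:
    """Best-local-alignment identity and coverage of the shorter sequence.

    Identity = matches / alignment columns (gap columns included);
    coverage = aligned span on the shorter sequence / its length.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    params = params or ClusterParams()
    aligner = _make_aligner(params)
    alignments = aligner.align(a.upper(), b.upper())
    if len(alignments) == 0:
        return (0.0, 0.0)
    return _identity_coverage_from_alignment(alignments[0], len(a), len(b))


def alignment_score(a: str, b: str, params: ClusterParams | None = None) -> float:
    """Optimal local alignment score under the cluster scoring scheme."""
    params = params or ClusterParams()
    return float(_make_aligner(params).score(a.upper(), b.upper()))


def _accepts(rep_seq: str, seq: str, params: ClusterParams) -> bool:
    ident, cov = pairwise_identity_coverage(rep_seq, seq, params)
    if ident >= params.min_identity and cov >= params.min_coverage:
        return True
    if params.check_reverse_complement:
        ident, cov = pairwise_identity_coverage(
            rep_seq, reverse_complement(seq), params
        )
        if ident >= params.min_identity and cov >= params.min_coverage:
            return True
    return False


def greedy_cluster(
    records: Sequence[ConsensusRecord], params: ClusterParams | None = None
) -> list[FamilyCluster]:
    """Greedy incremental clustering under the 80-80-80 acceptance rule.

    Records are processed longest-first (ties by id); each joins the first
    existing cluster whose *representative* it satisfies on either strand,
    else founds a new cluster. The output partitions the input ids, and
    every member satisfies the rule against its representative.

    Records shorter than ``params.min_length_nt`` raise ``ValueError``;
    pre-filter such records (the family rule does not apply below 80 bp).
    """
    params = params or ClusterParams()
    too_short = sorted(
        r.record_id for r in records if len(r.sequence) < params.min_length_nt
    )
    if too_short:
        raise ValueError(
            f"records below the {params.min_length_nt} nt family-rule minimum: "
            f"{too_short}"
        )
    dup = _first_duplicate(r.record_id for r in records)
    if dup is not None:
        raise ValueError(f"duplicate record id {dup!r}")

    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.record_id))
    clusters: list[FamilyCluster] = []
    rep_seqs: list[str] = []
    for rec in ordered:
        for cluster, rep_seq in zip(clusters, rep_seqs):
            if _accepts(rep_seq, rec.sequence, params):
                cluster.member_ids.append(rec.record_id)
                break
        else:
            clusters.append(
                FamilyCluster(
                    representative_id=rec.record_id, member_ids=[rec.record_id]
                )
            )
            rep_seqs.append(rec.sequence)
    return clusters


def _first_duplicate(ids: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


def write_cluster_tsv(
    clusters: Iterable[FamilyCluster], path: Union[str, Path]
) -> None:
    """Two-column (representative_id, member_id) table, one row per member —
    the same shape an external cascaded clusterer emits, so adapter output
    and reference output are interchangeable."""
    with open(path, "w") as fh:
        for c in clusters:
            for m in c.member_ids:
                fh.write(f"{c.representative_id}\t{m}\n")


def read_cluster_tsv(path: Union[str, Path]) -> list[FamilyCluster]:
    """Read a two-column cluster table (the external-clusterer adapter
    contract). Representatives absent from their own member list are added."""
    members: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            rep, member = fields
            if rep not in members:
                members[rep] = []
                order.append(rep)
            members[rep].append(member)
    clusters = []
    for rep in order:
        ids = members[rep]
        if rep not in ids:
            ids.insert(0, rep)
        clusters.append(FamilyCluster(representative_id=rep, member_ids=ids))
    return clusters
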