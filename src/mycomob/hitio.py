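"""Protein-search hit tables: parsing, thresholds, projection, interval logic.

Three kinds of evidence feed the curation rules, unified into one
:class:`ProteinHit` model:

* ``HOST_REFSEQ`` — DIAMOND BLASTp hits of translated consensus frames
  against a host reference proteome (host-gene signal);
* ``TE_HMM`` — HMMscan per-domain hits against TE protein-domain profiles,
  filtered on full-sequence E-value and bit score;
* ``TE_PEP`` — BLASTp hits against a library of curated TE peptides.

Hits arrive in residue coordinates of one of six translation frames and are
projected onto forward-strand nucleotide coordinates of the consensus
(:func:`project_hits`) so that host and TE coverage can be compared on a
single axis. Nested hits are resolved to the highest-quality hit and
adjacent/overlapping hits are coalesced before any coverage accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .intervals import IntervalSet, merge_with_gap
from .seqio import residue_to_nt_interval

__all__ = [
    "HOST_REFSEQ",
    "TE_HMM",
    "TE_PEP",
    "CATEGORIES",
    "ProteinHit",
    "HitThresholds",
    "parse_blast_tab",
    "parse_domtbl",
    "filter_hits",
    "project_hits",
    "resolve_nested",
    "merge_adjacent",
    "write_hits_tsv",
    "read_hits_tsv",
    "IntervalSet",
]

HOST_REFSEQ = "HOST_REFSEQ"
TE_HMM = "TE_HMM"
TE_PEP = "TE_PEP"
CATEGORIES = (HOST_REFSEQ, TE_HMM, TE_PEP)

#: default gap (nt) bridged when combining adjacent hits; 10 residues,
#: tolerant of short indels/frameshifts between split HSPs without
#: bridging unrelated domains.
DEFAULT_GAP_MAX_NT = 30


@dataclass(frozen=True)
class ProteinHit:
    """One alignment of a translated consensus frame to a protein subject."""

    consensus_id: str
    frame: int
    q_start: int  # residue coords on the translated frame, 0-based half-open
    q_end: int
    subject_id: str
    subject_category: str
    evalue: float
    bitscore: float
    subject_class_high: str = ""
    subject_class_sub: str = ""
    nt_start: int | None = None  # forward-strand nt coords, filled by projection
    nt_end: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.frame <= 6:
            raise ValueError(f"{self.consensus_id}: frame must be 1..6, got {self.frame}")
        if self.q_start < 0 or self.q_start >= self.q_end:
            raise ValueError(
                f"{self.consensus_id}: empty residue span [{self.q_start}, {self.q_end})"
            )
        if self.evalue < 0:
            raise ValueError(f"{self.consensus_id}: negative evalue")
        if self.subject_category not in CATEGORIES:
            raise ValueError(f"unknown subject category {self.subject_category!r}")
        if self.nt_start is not None and self.nt_end is not None:
            if self.nt_end - self.nt_start != 3 * (self.q_end - self.q_start):
                raise ValueError(
                    f"{self.consensus_id}: nt span length must be 3x residue span"
                )

    @property
    def nt_span(self) -> tuple[int, int]:
        if self.nt_start is None or self.nt_end is None:
            raise ValueError(f"{self.consensus_id}: hit not projected yet")
        return (self.nt_start, self.nt_end)

    @property
    def q_span(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)


@dataclass(frozen=True)
class HitThresholds:
    """Inclusive score thresholds applied per evidence category.

    Defaults follow the search settings of the curation protocol:
    E-value <= 1e-3 for BLASTp/DIAMOND hits, and full-sequence
    E-value <= 1e-3 with bit score >= 50 for HMM domain hits.
    """

    host_evalue_max: float = 1e-3
    hmm_evalue_max: float = 1e-3
    hmm_bitscore_min: float = 50.0
    pep_evalue_max: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.host_evalue_max, self.hmm_evalue_max, self.pep_evalue_max) <= 0:
            raise ValueError("e-value thresholds must be positive")
        if self.hmm_bitscore_min < 0:
            raise ValueError("bitscore threshold must be >= 0")


def _split_frame_suffix(qseqid: str, where: str) -> tuple[str, int]:
    base, _, suffix = qseqid.rpartition("_")
    if base and suffix.isdigit() and 1 <= int(suffix) <= 6:
        return base, int(suffix)
    raise ValueError(
        f"{where}: cannot parse frame suffix from query id {qseqid!r} "
        "(expected '<consensus_id>_<frame 1-6>')"
    )


def parse_blast_tab(path: Union[str, Path], category: str) -> list[ProteinHit]:
    """Parse 12-column tabular BLAST/DIAMOND output (outfmt 6).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. The query id must carry the translation
    frame as a ``_<1-6>`` suffix (transeq convention); qstart/qend are
    1-based inclusive residue coordinates and are normalized (min/max
    swapped if needed) to a 0-based half-open span.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown subject category {category!r}")
    path = Path(path)
    hits: list[ProteinHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            where = f"{path}:{lineno}"
            cons_id, frame = _split_frame_suffix(fields[0], where)
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                evalue, bitscore = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{where}: {exc}") from None
            lo, hi = min(qstart, qend), max(qstart, qend)
            hits.append(
                ProteinHit(
                    consensus_id=cons_id,
                    frame=frame,
                    q_start=lo - 1,
                    q_end=hi,
                    subject_id=fields[1],
                    subject_category=category,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hits


def parse_domtbl(path: Union[str, Path]) -> list[ProteinHit]:
    """Parse a HMMER per-domain table (``--domtblout``) into TE_HMM hits.

    One hit per domain line. The full-sequence E-value and score columns
    supply ``evalue``/``bitscore`` (the statistics the curation filter is
    defined on); the envelope coordinates supply the residue span.
    """
    path = Path(path)
    hits: list[ProteinHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, 22)
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 22 whitespace-delimited "
                    f"columns in domain table, got {len(fields)}"
                )
            where = f"{path}:{lineno}"
            cons_id, frame = _split_frame_suffix(fields[3], where)
            try:
                fs_evalue = float(fields[6])
                fs_score = float(fields[7])
                env_from = int(fields[19])
                env_to = int(fields[20])
            except ValueError as exc:
                raise ValueError(f"{where}: {exc}") from None
            hits.append(
                ProteinHit(
                    consensus_id=cons_id,
                    frame=frame,
                    q_start=env_from - 1,
                    q_end=env_to,
                    subject_id=fields[0],
                    subject_category=TE_HMM,
                    evalue=fs_evalue,
                    bitscore=fs_score,
                )
            )
    return hits


def filter_hits(hits: Iterable[ProteinHit], th: HitThresholds | None = None) -> list[ProteinHit]:
    """Apply the per-category score thresholds; order preserved, idempotent.

    Comparisons are inclusive exactly as the thresholds are stated
    (``<=`` on E-values, ``>=`` on the HMM bit score).
    """
    th = th or HitThresholds()
    kept = []
    for h in hits:
        if h.subject_category == HOST_REFSEQ:
            ok = h.evalue <= th.host_evalue_max
        elif h.subject_category == TE_HMM:
            ok = h.evalue <= th.hmm_evalue_max and h.bitscore >= th.hmm_bitscore_min
        else:
            ok = h.evalue <= th.pep_evalue_max
        if ok:
            kept.append(h)
    return kept


def project_hits(
    hits: Iterable[ProteinHit], consensus_lengths: Mapping[str, int]
) -> list[ProteinHit]:
    """Fill each hit's nucleotide span by projecting its residue span."""
    out = []
    for h in hits:
        if h.consensus_id not in consensus_lengths:
            raise ValueError(f"no consensus length for {h.consensus_id!r}")
        s, e = residue_to_nt_interval(
            h.frame, consensus_lengths[h.consensus_id], h.q_start, h.q_end
        )
        out.append(replace(h, nt_start=s, nt_end=e))
    return out


def _quality_key(h: ProteinHit) -> tuple:
    # best first: higher bitscore, lower evalue, longer span, lexicographic subject
    return (-h.bitscore, h.evalue, -(h.nt_end - h.nt_start), h.subject_id)


def _check_homogeneous(hits: Sequence[ProteinHit], op: str) -> None:
    ids = {h.consensus_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"{op}: hits span multiple consensus ids: {sorted(ids)}")
    cats = {h.subject_category for h in hits}
    if len(cats) > 1:
        raise ValueError(f"{op}: hits span multiple subject categories: {sorted(cats)}")
    for h in hits:
        h.nt_span  # raises if not projected


def resolve_nested(hits: Sequence[ProteinHit]) -> list[ProteinHit]:
    """Remove nested hits, keeping the highest-quality hit of each pair.

    Whenever one hit's nucleotide span is fully contained in another's
    (either direction — a low-quality container loses to a high-quality
    contained hit), the lower-quality hit is dropped. Quality order:
    higher bitscore, then lower E-value, then longer span, then
    lexicographic subject id. Hits are processed best-first, which realizes
    the pairwise-removal fixpoint deterministically. Input order is
    preserved in the output.
    """
    hits = list(hits)
    _check_homogeneous(hits, "resolve_nested")
    kept: list[ProteinHit] = []
    for h in sorted(hits, key=_quality_key):
        hs, he = h.nt_span
        nested = any(
            (hs >= ks and he <= ke) or (ks >= hs and ke <= he)
            for ks, ke in (k.nt_span for k in kept)
        )
        if not nested:
            kept.append(h)
    kept_set = {id(k) for k in kept}
    return [h for h in hits if id(h) in kept_set]


def merge_adjacent(
    hits: Sequence[ProteinHit], gap_max_nt: int = DEFAULT_GAP_MAX_NT
) -> IntervalSet:
    """Coalesce overlapping, touching, or near-adjacent hit spans.

    Spans separated by at most ``gap_max_nt`` nucleotides are combined;
    the result is the consensus-coordinate coverage of this hit category.
    """
    if gap_max_nt < 0:
        raise ValueError("gap_max_nt must be >= 0")
    hits = list(hits)
    if not hits:
        return IntervalSet()
    _check_homogeneous(hits, "merge_adjacent")
    return merge_with_gap([h.nt_span for h in hits], gap_max_nt)


_TSV_COLUMNS = (
    "consensus_id frame q_start q_end subject_id subject_category "
    "evalue bitscore nt_start nt_end"
).split()


def write_hits_tsv(hits: Iterable[ProteinHit], path: Union[str, Path]) -> None:
    """Emit hits as a TSV with an explicit header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.consensus_id,
                        h.frame,
                        h.q_start,
                        h.q_end,
                        h.subject_id,
                        h.subject_category,
                        h.evalue,
                        h.bitscore,
                        "" if h.nt_start is None else h.nt_start,
                        "" if h.nt_end is None else h.nt_end,
                    )
                )
                + "\n"
            )


def read_hits_tsv(path: Union[str, Path]) -> list[ProteinHit]:
    """Read back a TSV produced by :func:`write_hits_tsv`."""
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected hit-table header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(
                ProteinHit(
                    consensus_id=f[0],
                    frame=int(f[1]),
                    q_start=int(f[2]),
                    q_end=int(f[3]),
                    subject_id=f[4],
                    subject_category=f[5],
                    evalue=float(f[6]),
                    bitscore=float(f[7]),
                    nt_start=int(f[8]) if f[8] else None,
                    nt_end=int(f[9]) if f[9] else None,
                )
            )
    return hits
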