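"""FASTA I/O, the MycoMobilome header grammar, and six-frame translation.

Consensus sequences live in nucleotide space over ``{A, C, G, T, N}``
(soft-masking lowercase is uppercased on read and discarded). Protein-search
hits arrive in residue coordinates of one of six translation frames;
:func:`residue_to_nt_interval` projects them back onto the forward strand of
the consensus so that hits from different frames can be compared on one
shared axis.

Header grammar
--------------
Clustered (family representatives)::

    MycMob<release>_family-<n>-<6code>_<PE|DA|NE>[_LQGenome]#<high>[/<sub>] @<Genus> <epithet>

Unclustered (family members)::

    MycMob<release>_family-<n>_member-<m>-<6code>_<PE|DA|NE>[_LQGenome]#<high>[/<sub>] @<Genus> <epithet>

``PE``/``DA``/``NE`` encode whether protein evidence matches, contradicts,
or is absent for the assigned classification; ``LQGenome`` marks consensus
sequences curated from low-contiguity, low-completeness assemblies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "ConsensusRecord",
    "MycoMobHeader",
    "FrameProjection",
    "parse_header",
    "format_header",
    "species_code",
    "read_fasta",
    "write_fasta",
    "n_fraction",
    "six_frame_translate",
    "translate_frame",
    "reverse_complement",
    "residue_to_nt_interval",
    "frame_length",
]

EVIDENCE_CODES = ("PE", "DA", "NE")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TABLE = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_SEQ_OK = re.compile(r"^[ACGTN]*$")
_ILLEGAL = re.compile(r"[^ACGTN]")


@dataclass
class ConsensusRecord:
    """One TE consensus sequence with classification and provenance.

    ``evidence`` is one of ``PE``/``DA``/``NE`` or ``""`` (unset).
    ``raw_header`` preserves the exact FASTA header the record was read
    with; it is cleared whenever derived fields are modified so stale
    headers are never re-emitted.
    """

    record_id: str
    sequence: str
    class_high: str = "Unknown"
    class_sub: str = ""
    genus: str = ""
    species_epithet: str = ""
    source_genome: str = ""
    lq_genome: bool = False
    evidence: str = ""
    raw_header: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.record_id:
            raise ValueError("record_id must be nonempty")
        if not self.sequence:
            raise ValueError(f"{self.record_id}: sequence must be nonempty")
        if not _SEQ_OK.match(self.sequence):
            pos = _ILLEGAL.search(self.sequence).start()
            raise ValueError(
                f"{self.record_id}: illegal character "
                f"{self.sequence[pos]!r} at position {pos + 1}"
            )
        if not self.class_high:
            raise ValueError(f"{self.record_id}: class_high must be nonempty")
        if self.evidence not in EVIDENCE_CODES + ("",):
            raise ValueError(f"{self.record_id}: bad evidence {self.evidence!r}")

    @property
    def species(self) -> tuple[str, str]:
        return (self.genus, self.species_epithet)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MycoMobHeader:
    """Parsed fields of one MycoMobilome name.

    ``member_number is None`` means the clustered (family-representative)
    template; otherwise the unclustered member template, where the
    six-letter species code sits inside the member block.
    """

    release: str
    family_number: int
    species_code: str
    evidence: str
    class_high: str
    genus: str
    epithet: str
    class_sub: str = ""
    member_number: int | None = None
    lq_genome: bool = False

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_CODES:
            raise ValueError(f"bad evidence code {self.evidence!r}")
        if self.family_number < 1:
            raise ValueError("family_number must be positive")
        if self.member_number is not None and self.member_number < 1:
            raise ValueError("member_number must be positive")
        if len(self.species_code) != 6 or not self.species_code.isalpha():
            raise ValueError(f"species code must be 6 letters: {self.species_code!r}")

    @property
    def name(self) -> str:
        """The identifier part of the header (everything before '#')."""
        return format_header(self).split("#", 1)[0]


_HEADER_RE = re.compile(
    r"^MycMob(?P<release>\d+(?:\.\d+)*)_family-(?P<family>\d+)"
    r"(?:-(?P<fam_code>[A-Za-z]{6})|_member-(?P<member>\d+)-(?P<mem_code>[A-Za-z]{6}))"
    r"_(?P<evidence>PE|DA|NE)(?P<lq>_LQGenome)?"
    r"#(?P<high>[^/\s#@]+)(?:/(?P<sub>[^\s#@]+))?"
    r" @(?P<genus>\S+) (?P<epithet>\S+)$"
)


def parse_header(header: str) -> MycoMobHeader:
    """Parse a grammar-conformant header; raise ``ValueError`` otherwise."""
    m = _HEADER_RE.match(header.strip())
    if m is None:
        raise ValueError(f"not a MycoMobilome header: {header!r}")
    member = m.group("member")
    return MycoMobHeader(
        release=m.group("release"),
        family_number=int(m.group("family")),
        member_number=int(member) if member is not None else None,
        species_code=m.group("fam_code") or m.group("mem_code"),
        evidence=m.group("evidence"),
        lq_genome=m.group("lq") is not None,
        class_high=m.group("high"),
        class_sub=m.group("sub") or "",
        genus=m.group("genus"),
        epithet=m.group("epithet"),
    )


def format_header(h: MycoMobHeader) -> str:
    """Render a header; inverse of :func:`parse_header`."""
    if h.member_number is None:
        core = f"MycMob{h.release}_family-{h.family_number}-{h.species_code}"
    else:
        core = (
            f"MycMob{h.release}_family-{h.family_number}"
            f"_member-{h.member_number}-{h.species_code}"
        )
    core += f"_{h.evidence}"
    if h.lq_genome:
        core += "_LQGenome"
    cls = h.class_high + (f"/{h.class_sub}" if h.class_sub else "")
    return f"{core}#{cls} @{h.genus} {h.epithet}"


def species_code(genus: str, epithet: str) -> str:
    """Six-letter species code: three letters of genus + three of epithet.

    Non-alphabetic characters are dropped; each half is capitalized and
    padded with ``x`` to three letters ("Zymoseptoria tritici" -> "ZymTri").
    Collisions are tolerated: the family number, not the code, is the key.
    """

    def part(s: str) -> str:
        letters = re.sub(r"[^A-Za-z]", "", s)[:3]
        return (letters[:1].upper() + letters[1:].lower()).ljust(3, "x")

    return part(genus) + part(epithet)


_SIMPLE_CLASS_RE = re.compile(
    r"^(?P<id>[^\s#]+)#(?P<high>[^/\s#@]+)(?:/(?P<sub>[^\s#@]+))?"
    r"(?: @(?P<genus>\S+) (?P<epithet>\S+))?$"
)


def _record_from_entry(record_id: str, header: str, seq: str) -> ConsensusRecord:
    try:
        h = parse_header(header)
    except ValueError:
        m = _SIMPLE_CLASS_RE.match(header.strip())
        if m is not None:
            # RepeatMasker library convention: `id#High/Sub [@Genus epithet]`
            return ConsensusRecord(
                record_id=m.group("id"),
                sequence=seq,
                class_high=m.group("high"),
                class_sub=m.group("sub") or "",
                genus=m.group("genus") or "",
                species_epithet=m.group("epithet") or "",
                raw_header=header,
            )
        return ConsensusRecord(record_id=record_id, sequence=seq, raw_header=header)
    return ConsensusRecord(
        record_id=h.name,
        sequence=seq,
        class_high=h.class_high,
        class_sub=h.class_sub,
        genus=h.genus,
        species_epithet=h.epithet,
        lq_genome=h.lq_genome,
        evidence=h.evidence,
        raw_header=header,
    )


def read_fasta(path: Union[str, Path]) -> list[ConsensusRecord]:
    """Read a nucleotide FASTA into consensus records.

    Headers matching the MycoMobilome grammar are parsed into fields;
    plain headers yield records with unset metadata. Sequences are
    uppercased. Empty files, duplicate IDs, and characters outside
    ``{A,C,G,T,N}`` raise ``ValueError``.
    """
    path = Path(path)
    records: list[ConsensusRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description
        seq = str(entry.seq).upper()
        rec = _record_from_entry(entry.id, header, seq)
        if rec.record_id in seen:
            raise ValueError(f"duplicate record id in {path}: {rec.record_id!r}")
        seen.add(rec.record_id)
        records.append(rec)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def default_header(rec: ConsensusRecord) -> str:
    """Fallback header for records without a stored raw header."""
    cls = rec.class_high + (f"/{rec.class_sub}" if rec.class_sub else "")
    if rec.genus:
        return f"{rec.record_id}#{cls} @{rec.genus} {rec.species_epithet}"
    if cls and cls != "Unknown":
        return f"{rec.record_id}#{cls}"
    return rec.record_id


def write_fasta(
    records: Iterable[ConsensusRecord], path: Union[str, Path], width: int = 60
) -> None:
    """Write records as multi-line FASTA (60-column wrap by default)."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.raw_header or default_header(rec)
            fh.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def n_fraction(record: Union[ConsensusRecord, str]) -> float:
    """Fraction of the sequence that is N (case-insensitive)."""
    seq = record.sequence if isinstance(record, ConsensusRecord) else record.upper()
    if not seq:
        raise ValueError("empty sequence")
    return seq.count("N") / len(seq)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate_frame(seq: str, frame: int, clean: bool = False) -> str:
    """Translate one frame with the standard genetic code.

    Frames 1-3 read the forward strand at offsets 0-2; frames 4-6 read
    the reverse complement at offsets 0-2. Trailing partial codons are
    dropped. Stops render as ``*`` (or ``X`` with ``clean=True``); any
    codon containing N renders as ``X``.
    """
    if not 1 <= frame <= 6:
        raise ValueError(f"frame must be in 1..6, got {frame}")
    seq = seq.upper()
    if frame >= 4:
        seq = reverse_complement(seq)
    off = (frame - 1) % 3
    aa = "".join(
        _CODON_TABLE.get(seq[i : i + 3], "X") for i in range(off, len(seq) - 2, 3)
    )
    return aa.replace("*", "X") if clean else aa


def six_frame_translate(
    record: Union[ConsensusRecord, str], clean: bool = False
) -> tuple[str, str, str, str, str, str]:
    """All six translation frames of a consensus, in frame order 1..6."""
    seq = record.sequence if isinstance(record, ConsensusRecord) else record
    if len(seq) < 3:
        raise ValueError(f"sequence too short to translate: {len(seq)} nt")
    return tuple(translate_frame(seq, f, clean=clean) for f in range(1, 7))


def frame_length(frame: int, consensus_length: int) -> int:
    """Number of complete codons (residues) in the given frame."""
    if not 1 <= frame <= 6:
        raise ValueError(f"frame must be in 1..6, got {frame}")
    off = (frame - 1) % 3
    return max(0, (consensus_length - off) // 3)


def residue_to_nt_interval(
    frame: int, consensus_length: int, residue_start: int, residue_end: int
) -> tuple[int, int]:
    """Project a residue span of a translation frame onto the forward strand.

    ``[residue_start, residue_end)`` is 0-based half-open in residue
    coordinates of ``frame``. The result is a 0-based half-open nucleotide
    interval on the forward strand of the consensus; reverse-frame spans
    are mirrored through the sequence length. The projected interval always
    has length ``3 * (residue_end - residue_start)``.
    """
    if residue_start < 0 or residue_start >= residue_end:
        raise ValueError(
            f"invalid residue span [{residue_start}, {residue_end})"
        )
    n_res = frame_length(frame, consensus_length)
    if residue_end > n_res:
        raise ValueError(
            f"residue span [{residue_start}, {residue_end}) exceeds frame {frame} "
            f"length {n_res} for a {consensus_length} nt consensus"
        )
    off = (frame - 1) % 3
    if frame <= 3:
        return (3 * residue_start + off, 3 * residue_end + off)
    s_rc = 3 * residue_start + off
    e_rc = 3 * residue_end + off
    return (consensus_length - e_rc, consensus_length - s_rc)


@dataclass(frozen=True)
class FrameProjection:
    """A translation frame bound to a consensus length, for hit projection."""

    frame: int
    consensus_length: int

    def __post_init__(self) -> None:
        if not 1 <= self.frame <= 6:
            raise ValueError(f"frame must be in 1..6, got {self.frame}")
        if self.consensus_length < 1:
            raise ValueError("consensus_length must be positive")

    @property
    def n_residues(self) -> int:
        return frame_length(self.frame, self.consensus_length)

    def project(self, residue_start: int, residue_end: int) -> tuple[int, int]:
        return residue_to_nt_interval(
            self.frame, self.consensus_length, residue_start, residue_end
        )


def copy_with(rec: ConsensusRecord, **changes) -> ConsensusRecord:
    """Copy a record with field changes; the stale raw header is dropped."""
    changes.setdefault("raw_header", "")
    return replace(rec, **changes)
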