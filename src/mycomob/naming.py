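"""Persistent MycoMobilome names for clustered families and their members.

Family numbers are assigned deterministically (descending cluster size,
ties by representative id) so renaming is a pure function of the cluster
set, the curation verdicts, and the release string. A supplied identity
map (old representative id -> family number) pins numbers across releases.
Family-level protein evidence is the representative's evidence code,
propagated to every member (the member template carries the *family*
evidence).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .clustering import FamilyCluster
from .curation import CurationVerdict
from .seqio import (
    ConsensusRecord,
    MycoMobHeader,
    copy_with,
    format_header,
    parse_header,
    species_code,
)

FamilyName = MycoMobHeader  # the grammar type; see seqio for parse/format

__all__ = ["FamilyName", "NameAssignment", "assign_names", "write_name_map_tsv"]


@dataclass
class NameAssignment:
    """Renamed libraries plus the old-id -> new-name traceability map."""

    clustered: list[ConsensusRecord]
    unclustered: list[ConsensusRecord]
    name_map: list[tuple[str, str]]
    family_numbers: dict[str, int]  # representative_id -> family number


def _header_for(
    rec: ConsensusRecord,
    family_number: int,
    member_number: int | None,
    evidence: str,
    lq: bool,
    release: str,
) -> MycoMobHeader:
    genus = rec.genus or "Unknown"
    epithet = rec.species_epithet or "sp"
    return MycoMobHeader(
        release=release,
        family_number=family_number,
        member_number=member_number,
        species_code=species_code(genus, epithet),
        evidence=evidence or "NE",
        lq_genome=lq,
        class_high=rec.class_high,
        class_sub=rec.class_sub,
        genus=genus,
        epithet=epithet,
    )


def assign_names(
    clusters: Sequence[FamilyCluster],
    records: Mapping[str, ConsensusRecord],
    verdicts: Mapping[str, CurationVerdict],
    release: str = "1.1",
    identity_map: Mapping[str, int] | None = None,
) -> NameAssignment:
    """Assign unique persistent names to families and members.

    ``clusters`` must have unique representatives; ``records`` and
    ``verdicts`` are keyed by original consensus id. Only records whose
    verdict is retained are named; a cluster with no retained member is
    skipped. Member numbers run 1..k within each family over retained
    members in sorted id order (the representative first when retained).
    ``identity_map`` pins family numbers for known representatives; new
    families continue after the largest pinned number.
    """
    reps = [c.representative_id for c in clusters]
    if len(set(reps)) != len(reps):
        dupes = sorted({r for r in reps if reps.count(r) > 1})
        raise ValueError(f"duplicate representative ids: {dupes}")

    identity_map = dict(identity_map or {})
    next_number = max(identity_map.values(), default=0) + 1

    def retained(cid: str) -> bool:
        v = verdicts.get(cid)
        return v is not None and v.retained

    ordered = sorted(clusters, key=lambda c: (-c.size, c.representative_id))
    clustered: list[ConsensusRecord] = []
    unclustered: list[ConsensusRecord] = []
    name_map: list[tuple[str, str]] = []
    family_numbers: dict[str, int] = {}

    for cluster in ordered:
        keep = [m for m in cluster.member_ids if retained(m)]
        if not keep:
            continue
        rep_id = cluster.representative_id
        if rep_id in identity_map:
            fam_no = identity_map[rep_id]
        else:
            fam_no = next_number
            next_number += 1
        family_numbers[rep_id] = fam_no

        rep_verdict = verdicts.get(rep_id)
        family_evidence = rep_verdict.evidence if rep_verdict else "NE"

        if retained(rep_id):
            rep_rec = records[rep_id]
            header = _header_for(
                rep_rec, fam_no, None, family_evidence, verdicts[rep_id].lq_genome, release
            )
            new = copy_with(
                rep_rec,
                record_id=header.name,
                evidence=header.evidence,
                lq_genome=header.lq_genome,
                raw_header=format_header(header),
            )
            clustered.append(new)
            name_map.append((rep_id, format_header(header)))

        members = sorted(keep, key=lambda m: (m != rep_id, m))
        for member_no, member_id in enumerate(members, start=1):
            rec = records[member_id]
            header = _header_for(
                rec,
                fam_no,
                member_no,
                family_evidence,
                verdicts[member_id].lq_genome,
                release,
            )
            new = copy_with(
                rec,
                record_id=header.name,
                evidence=header.evidence,
                lq_genome=header.lq_genome,
                raw_header=format_header(header),
            )
            unclustered.append(new)
            name_map.append((member_id, format_header(header)))

    _assert_unique([r.record_id for r in clustered], "clustered")
    _assert_unique([r.record_id for r in unclustered], "unclustered")
    for _, name in name_map:
        parse_header(name)  # every emitted name must round-trip the grammar
    return NameAssignment(
        clustered=clustered,
        unclustered=unclustered,
        name_map=name_map,
        family_numbers=family_numbers,
    )


def _assert_unique(names: Iterable[str], which: str) -> None:
    names = list(names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate names in {which} library: {dupes}")


def write_name_map_tsv(
    name_map: Iterable[tuple[str, str]], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("old_id\tnew_name\n")
        for old, new in name_map:
            fh.write(f"{old}\t{new}\n")
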