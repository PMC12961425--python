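"""End-to-end curation: cluster -> host-gene -> quality -> evidence -> name.

This mirrors the library-construction order of the curation protocol:
the combined library is clustered into 80-80-80 families first; host-gene
removal and quality filtering are then applied to every record (so both
the clustered and unclustered libraries receive the same filters);
evidence codes are computed per record, with *family* evidence taken from
the representative and propagated to members at naming time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import clustering, curation, hitio, naming
from .clustering import ClusterParams, FamilyCluster
from .curation import ClassMap, CurationThresholds, CurationVerdict, GenomeMetadata
from .hitio import ProteinHit
from .naming import NameAssignment
from .seqio import ConsensusRecord, copy_with

__all__ = ["PipelineResult", "apply_source_genomes", "run_curation"]


@dataclass
class PipelineResult:
    clusters: list[FamilyCluster]
    verdicts: list[CurationVerdict]
    retained: list[ConsensusRecord]
    names: NameAssignment
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def verdict_by_id(self) -> dict[str, CurationVerdict]:
        return {v.consensus_id: v for v in self.verdicts}


def apply_source_genomes(
    records: Sequence[ConsensusRecord],
    source_map: Mapping[str, str],
    genome_meta: Mapping[str, GenomeMetadata] | None = None,
) -> list[ConsensusRecord]:
    """Stamp each record with its source assembly and, when genome
    metadata is available, the species of that assembly."""
    genome_meta = genome_meta or {}
    out = []
    for rec in records:
        asm = source_map.get(rec.record_id, rec.source_genome)
        changes: dict = {"source_genome": asm}
        meta = genome_meta.get(asm)
        if meta is not None and meta.genus and not rec.genus:
            changes["genus"] = meta.genus
            changes["species_epithet"] = meta.species_epithet
        out.append(copy_with(rec, **changes) if asm or changes else rec)
    return out


def _cluster_with_short_singletons(
    records: Sequence[ConsensusRecord], params: ClusterParams
) -> list[FamilyCluster]:
    # the family rule does not apply below its length floor; such records
    # become singleton clusters and fall to the quality filter downstream
    long_recs = [r for r in records if len(r.sequence) >= params.min_length_nt]
    short_recs = [r for r in records if len(r.sequence) < params.min_length_nt]
    clusters = clustering.greedy_cluster(long_recs, params) if long_recs else []
    for r in sorted(short_recs, key=lambda r: r.record_id):
        clusters.append(
            FamilyCluster(representative_id=r.record_id, member_ids=[r.record_id])
        )
    return clusters


def run_curation(
    records: Sequence[ConsensusRecord],
    hits: Sequence[ProteinHit],
    genome_meta: Mapping[str, GenomeMetadata] | None = None,
    class_map: ClassMap | None = None,
    *,
    thresholds: CurationThresholds | None = None,
    cluster_params: ClusterParams | None = None,
    clusters: Sequence[FamilyCluster] | None = None,
    release: str = "1.1",
    gap_max_nt: int = hitio.DEFAULT_GAP_MAX_NT,
    host_gene_mode: str = "union",
    identity_map: Mapping[str, int] | None = None,
) -> PipelineResult:
    """Run the full pipeline over threshold-filtered, projected hits.

    ``clusters`` may be supplied from an external clusterer's two-column
    table (the adapter contract); otherwise the built-in greedy 80-80-80
    clusterer runs.
    """
    cluster_params = cluster_params or ClusterParams()
    if clusters is None:
        clusters = _cluster_with_short_singletons(records, cluster_params)

    retained, verdicts = curation.curate_library(
        records,
        hits,
        genome_meta,
        thresholds,
        class_map=class_map,
        gap_max_nt=gap_max_nt,
        host_gene_mode=host_gene_mode,
    )
    by_id = {r.record_id: r for r in records}
    vmap = {v.consensus_id: v for v in verdicts}
    names = naming.assign_names(
        list(clusters), by_id, vmap, release=release, identity_map=identity_map
    )
    audit = {
        "input_records": len(records),
        "clusters": len(clusters),
        "host_gene_removed": sum(v.host_gene for v in verdicts),
        "quality_removed": sum(v.removed_quality for v in verdicts),
        "retained": len(retained),
        "retained_clustered": len(names.clustered),
        "retained_unclustered": len(names.unclustered),
        "non_autonomous": sum(
            v.non_autonomous and v.retained for v in verdicts
        ),
        "lq_genome_flagged": sum(v.lq_genome for v in verdicts),
    }
    return PipelineResult(
        clusters=list(clusters),
        verdicts=verdicts,
        retained=retained,
        names=names,
        audit=audit,
    )
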