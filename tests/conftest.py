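from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default synthetic curation fixture, generated once per session."""
    from mycomob import fixtures

    outdir = tmp_path_factory.mktemp("fixture")
    spec = fixtures.FixtureSpec(seed=42)
    paths = fixtures.make_fixture(spec, outdir)
    return spec, paths


@pytest.fixture()
def load_fixture_inputs():
    """Loader running the fixture files through the real parsers."""

    def _load(paths):
        from mycomob import curation, hitio, pipeline, seqio

        records = seqio.read_fasta(paths.fasta)
        genome_meta = curation.read_genome_metadata_tsv(paths.genome_metadata)
        source = {}
        with open(paths.source_genomes) as fh:
            fh.readline()
            for line in fh:
                rid, asm = line.split()
                source[rid] = asm
        records = pipeline.apply_source_genomes(records, source, genome_meta)
        hits = (
            hitio.parse_blast_tab(paths.refseq_blast, hitio.HOST_REFSEQ)
            + hitio.parse_blast_tab(paths.te_blast, hitio.TE_PEP)
            + hitio.parse_domtbl(paths.te_domtbl)
        )
        hits = hitio.filter_hits(hits)
        hits = hitio.project_hits(
            hits, {r.record_id: len(r.sequence) for r in records}
        )
        class_map = curation.read_class_map_tsv(paths.class_map)
        return records, hits, genome_meta, class_map

    return _load
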