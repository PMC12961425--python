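"""Deterministic synthetic inputs with independently computed ground truth.

Every consumer-facing format of the toolkit (consensus FASTA, 12-column
BLAST tables, HMMER domain tables, genome metadata TSV, class-mapping TSV,
BED annotation pairs) can be generated here from a single seed, together
with an expected-outcome table. The expected outcomes are computed at
generation time by private per-position brute-force routines (boolean
masks over the consensus axis, literal threshold comparisons) — never by
the curation code under test — so fixtures double as end-to-end oracles.

The generator emulates hit *geometry* (where alignments fall on a
consensus, in which translation frame, with what scores), which is what
the curation rules act on. It does not emulate realistic TE sequence
evolution (no terminal repeats, no nesting, no indel mutation), so
passing fixture tests demonstrates rule correctness, not discovery
performance on real repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .compare import AnnotationFeature
from .seqio import ConsensusRecord

__all__ = [
    "FixtureSpec",
    "FixturePaths",
    "PlantedHit",
    "make_fixture",
    "make_family_set",
    "make_annotation_pair",
    "write_bed",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# literal protocol constants, restated here so fixture truth never depends
# on the package's threshold objects
_EVALUE_MAX = 1e-3
_HMM_BITSCORE_MIN = 50.0
_EXCLUSIVE_RESIDUES_MIN = 90
_MIN_LENGTH_NT = 120
_N_FRACTION_MAX = 0.05
_GAP_MAX_NT = 30

_CLASS_MAP = {
    "TEpep_Gypsy_pol": ("LTR", "Gypsy"),
    "TEpep_Copia_pol": ("LTR", "Copia"),
    "TEpep_LTR_generic": ("LTR", ""),
    "TEhmm_Copia_INT": ("LTR", "Copia"),
    "TEhmm_hAT_tnp": ("DNA", "hAT"),
    "TEpep_uninformative": ("", ""),
}

_GOOD_ASM = "ASM001"
_POOR_ASM = "ASM002"


@dataclass(frozen=True)
class PlantedHit:
    """One planted alignment, in residue coordinates of one frame."""

    category: str  # HOST_REFSEQ | TE_HMM | TE_PEP
    frame: int
    res_start: int  # 0-based half-open residue span
    res_end: int
    subject_id: str
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class FixtureSpec:
    """Composition of the default curation fixture.

    The default library holds 11 records: three clean TEs cycling through
    the PE / DA / NE evidence situations, two branch-(i) host genes, two
    branch-(ii) host genes (planted exclusive residues well above 90), one
    borderline record at exactly 89 exclusive residues (retained), two
    too-short records (119 and 60 nt), and one N-rich record.
    """

    seed: int = 42
    n_clean_te: int = 3
    n_host_gene_case_i: int = 2
    n_host_gene_case_ii: int = 2
    n_borderline: int = 1
    n_short: int = 2
    n_n_rich: int = 1
    n_families: int = 3
    copies_per_family: int = 4
    substitution_rate: float = 0.05
    # annotation-pair geometry: planted shared / unique loci
    ann_n_shared: int = 6
    ann_n_unique_a: int = 4
    ann_n_unique_b: int = 5

    def __post_init__(self) -> None:
        counts = (
            self.n_clean_te,
            self.n_host_gene_case_i,
            self.n_host_gene_case_ii,
            self.n_borderline,
            self.n_short,
            self.n_n_rich,
        )
        if any(c < 0 for c in counts):
            raise ValueError("fixture counts must be >= 0")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")


@dataclass
class FixturePaths:
    """Files written by :func:`make_fixture`."""

    fasta: Path
    refseq_blast: Path
    te_blast: Path
    te_domtbl: Path
    genome_metadata: Path
    source_genomes: Path
    class_map: Path
    expected_verdicts: Path
    annotations_a: Path
    annotations_b: Path
    expected_comparison: Path


def random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent per-position substitution to a *different* base."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# independent brute-force truth machinery


def _project_mask(L: int, frame: int, rs: int, re_: int) -> tuple[int, int]:
    # deliberate re-derivation of the frame projection arithmetic
    off = (frame - 1) % 3
    if frame <= 3:
        return (3 * rs + off, 3 * re_ + off)
    s_rc, e_rc = 3 * rs + off, 3 * re_ + off
    return (L - e_rc, L - s_rc)


def _fill_gaps(mask: np.ndarray, gap_max: int) -> np.ndarray:
    """Fill zero-runs of length <= gap_max lying between covered positions."""
    out = mask.copy()
    covered = np.flatnonzero(mask)
    if covered.size < 2:
        return out
    for a, b in zip(covered[:-1], covered[1:]):
        if 1 < b - a <= gap_max + 1:
            out[a:b] = True
    return out


def _passes(h: PlantedHit) -> bool:
    if h.category == "TE_HMM":
        return h.evalue <= _EVALUE_MAX and h.bitscore >= _HMM_BITSCORE_MIN
    return h.evalue <= _EVALUE_MAX


def _truth_verdict(
    record: ConsensusRecord,
    planted: Sequence[PlantedHit],
    lq_assemblies: frozenset[str],
    source_genome: str,
) -> dict:
    L = len(record.sequence)
    masks = {
        cat: np.zeros(L, dtype=bool) for cat in ("HOST_REFSEQ", "TE_HMM", "TE_PEP")
    }
    passing = [h for h in planted if _passes(h)]
    for h in passing:
        s, e = _project_mask(L, h.frame, h.res_start, h.res_end)
        masks[h.category][s:e] = True
    for cat in masks:
        masks[cat] = _fill_gaps(masks[cat], _GAP_MAX_NT)
    ref = masks["HOST_REFSEQ"]
    te = masks["TE_HMM"] | masks["TE_PEP"]

    exclusive_res = int((ref & ~te).sum()) // 3
    if not ref.any():
        host_gene = False
    elif not te.any():
        host_gene = True
    else:
        host_gene = exclusive_res >= _EXCLUSIVE_RESIDUES_MIN

    concordant = discordant = False
    for h in passing:
        if h.category == "HOST_REFSEQ":
            continue
        mapped = _CLASS_MAP.get(h.subject_id)
        if not mapped or not mapped[0]:
            continue
        high_ok = mapped[0] == record.class_high
        sub_ok = not (record.class_sub and mapped[1] and mapped[1] != record.class_sub)
        if high_ok and sub_ok:
            concordant = True
        else:
            discordant = True
    evidence = "DA" if discordant else ("PE" if concordant else "NE")

    removed_quality = False
    reasons = []
    if host_gene:
        reasons.append("HOST_GENE")
    else:
        n_frac = record.sequence.upper().count("N") / L
        if L < _MIN_LENGTH_NT:
            removed_quality = True
            reasons.append("SHORT")
        if n_frac >= _N_FRACTION_MAX:
            removed_quality = True
            reasons.append("N_RICH")

    return {
        "consensus_id": record.record_id,
        "host_gene": host_gene,
        "non_autonomous": not passing,
        "evidence": evidence,
        "removed_quality": removed_quality,
        "lq_genome": (not host_gene and not removed_quality)
        and source_genome in lq_assemblies,
        "exclusive_refseq_residues": exclusive_res,
        "retained": not host_gene and not removed_quality,
    }


# ---------------------------------------------------------------------------
# record construction


def _pick_span(rng: np.random.Generator, frame: int, L: int, min_res: int, max_res: int) -> tuple[int, int]:
    n_res = (L - (frame - 1) % 3) // 3
    span = int(rng.integers(min_res, min(max_res, n_res - 1) + 1))
    start = int(rng.integers(0, n_res - span + 1))
    return (start, start + span)


def _build_library(
    spec: FixtureSpec,
) -> tuple[list[ConsensusRecord], dict[str, list[PlantedHit]], dict[str, str]]:
    rng = np.random.default_rng(spec.seed)
    records: list[ConsensusRecord] = []
    planted: dict[str, list[PlantedHit]] = {}
    source: dict[str, str] = {}

    def add(rec: ConsensusRecord, hits: list[PlantedHit], asm: str) -> None:
        records.append(rec)
        planted[rec.record_id] = hits
        source[rec.record_id] = asm

    # clean TEs cycling PE / DA / NE evidence situations
    for i in range(spec.n_clean_te):
        rid = f"te_clean{i + 1:02d}"
        L = int(rng.integers(900, 1500))
        kind = i % 3
        if kind == 0:  # concordant peptide evidence -> PE
            rec = ConsensusRecord(rid, random_seq(rng, L), "LTR", "Gypsy")
            frame = int(rng.integers(1, 7))
            rs, re_ = _pick_span(rng, frame, L, 120, 250)
            hits = [
                PlantedHit("TE_PEP", frame, rs, re_, "TEpep_Gypsy_pol", 1e-40, 310.0),
                PlantedHit("TE_PEP", frame, rs, min(re_, rs + 60), "TEpep_LTR_generic", 1e-12, 95.0),
                # RefSeq hit nested inside TE coverage: exclusive residues 0
                PlantedHit("HOST_REFSEQ", frame, rs + 5, min(re_, rs + 40), "XP_900001.1", 1e-8, 88.0),
            ]
            asm = _POOR_ASM if i == 0 else _GOOD_ASM
            add(rec, hits, asm)
        elif kind == 1:  # discordant domain evidence -> DA
            rec = ConsensusRecord(rid, random_seq(rng, L), "DNA", "hAT")
            frame = int(rng.integers(1, 7))
            rs, re_ = _pick_span(rng, frame, L, 80, 200)
            hits = [
                PlantedHit("TE_HMM", frame, rs, re_, "TEhmm_Copia_INT", 2e-20, 120.0),
                # below the bit-score floor: must be filtered out upstream
                PlantedHit("TE_HMM", frame, rs, re_, "TEhmm_hAT_tnp", 5e-4, 49.0),
            ]
            add(rec, hits, _GOOD_ASM)
        else:  # no hits at all -> NE, putative non-autonomous
            rec = ConsensusRecord(rid, random_seq(rng, L), "Unknown")
            add(rec, [], _GOOD_ASM)

    # branch (i): RefSeq hits, no (surviving) TE hits
    for i in range(spec.n_host_gene_case_i):
        rid = f"hostgene_i{i + 1:02d}"
        L = int(rng.integers(800, 1400))
        rec = ConsensusRecord(rid, random_seq(rng, L), "Unknown")
        frame = int(rng.integers(1, 7))
        rs1, re1 = _pick_span(rng, frame, L, 100, 180)
        hits = [
            PlantedHit("HOST_REFSEQ", frame, rs1, re1, "XP_100001.1", 1e-60, 420.0),
            # overlapping second HSP of the same protein family
            PlantedHit("HOST_REFSEQ", frame, rs1 + 20, re1 + 10 if re1 + 10 <= (L - (frame - 1) % 3) // 3 else re1, "XP_100002.1", 1e-30, 200.0),
            # TE hit far above the e-value ceiling: filtered, does not rescue
            PlantedHit("TE_PEP", frame, rs1, re1, "TEpep_Copia_pol", 0.5, 30.0),
        ]
        add(rec, hits, _GOOD_ASM)

    # branch (ii): both evidence kinds, exclusive residues well above 90
    for i in range(spec.n_host_gene_case_ii):
        rid = f"hostgene_ii{i + 1:02d}"
        L = 900
        rec = ConsensusRecord(rid, random_seq(rng, L), "LTR", "Gypsy")
        hits = [
            # frame 1: RefSeq covers nt [0, 600), TE covers nt [447, 780)
            PlantedHit("HOST_REFSEQ", 1, 0, 200, "XP_200001.1", 1e-70, 500.0),
            PlantedHit("TE_PEP", 1, 149, 260, "TEpep_Gypsy_pol", 1e-25, 150.0),
        ]
        add(rec, hits, _GOOD_ASM)

    # borderline: exactly 89 exclusive residues -> retained
    for i in range(spec.n_borderline):
        rid = f"borderline{i + 1:02d}"
        L = 700
        rec = ConsensusRecord(rid, random_seq(rng, L), "LTR", "Gypsy")
        hits = [
            # frame 1: RefSeq nt [0, 567), TE nt [267, 567): exclusive 267 nt = 89 res
            PlantedHit("HOST_REFSEQ", 1, 0, 189, "XP_300001.1", 1e-50, 350.0),
            PlantedHit("TE_PEP", 1, 89, 189, "TEpep_Gypsy_pol", 1e-20, 140.0),
        ]
        add(rec, hits, _GOOD_ASM)

    # poor quality: too short
    short_lengths = [119, 60]
    for i in range(spec.n_short):
        rid = f"short{i + 1:02d}"
        L = short_lengths[i % len(short_lengths)]
        add(ConsensusRecord(rid, random_seq(rng, L), "Unknown"), [], _GOOD_ASM)

    # poor quality: N-rich (6% N, above the 5% ceiling)
    for i in range(spec.n_n_rich):
        rid = f"nrich{i + 1:02d}"
        L = 200
        seq = list(random_seq(rng, L))
        n_positions = rng.choice(L, size=12, replace=False)
        for p in n_positions:
            seq[p] = "N"
        add(ConsensusRecord(rid, "".join(seq), "Unknown"), [], _GOOD_ASM)

    return records, planted, source


# ---------------------------------------------------------------------------
# file emission


def _blast_line(rid: str, h: PlantedHit, rng: np.random.Generator) -> str:
    span = h.res_end - h.res_start
    pident = round(float(rng.uniform(40, 95)), 1)
    mismatch = int(span * (1 - pident / 100))
    return "\t".join(
        str(x)
        for x in (
            f"{rid}_{h.frame}",
            h.subject_id,
            pident,
            span,
            mismatch,
            0,
            h.res_start + 1,
            h.res_end,
            1,
            span,
            f"{h.evalue:.2g}",
            h.bitscore,
        )
    )


def _domtbl_line(rid: str, h: PlantedHit, qlen: int) -> str:
    span = h.res_end - h.res_start
    fields = [
        h.subject_id, "-", str(span), f"{rid}_{h.frame}", "-", str(qlen),
        f"{h.evalue:.2g}", str(h.bitscore), "0.1", "1", "1",
        f"{h.evalue:.2g}", f"{h.evalue:.2g}", str(h.bitscore), "0.1",
        "1", str(span), str(h.res_start + 1), str(h.res_end),
        str(h.res_start + 1), str(h.res_end), "0.90", "-",
    ]
    return " ".join(fields)


def make_fixture(spec: FixtureSpec, outdir: Union[str, Path]) -> FixturePaths:
    """Write the full synthetic input set plus expected-outcome tables.

    Byte-identical for identical specs (no timestamps, fixed ordering).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, planted, source = _build_library(spec)
    rng_scores = np.random.default_rng(spec.seed + 1)

    paths = FixturePaths(
        fasta=outdir / "library.fasta",
        refseq_blast=outdir / "refseq_hits.blast.tsv",
        te_blast=outdir / "te_peptide_hits.blast.tsv",
        te_domtbl=outdir / "te_hmm_hits.domtbl",
        genome_metadata=outdir / "genomes.tsv",
        source_genomes=outdir / "source_genomes.tsv",
        class_map=outdir / "te_class_map.tsv",
        expected_verdicts=outdir / "expected_verdicts.tsv",
        annotations_a=outdir / "annotations_methodA.bed",
        annotations_b=outdir / "annotations_methodB.bed",
        expected_comparison=outdir / "expected_comparison.tsv",
    )

    with open(paths.fasta, "w") as fh:
        for rec in records:
            cls = rec.class_high + (f"/{rec.class_sub}" if rec.class_sub else "")
            fh.write(f">{rec.record_id}#{cls}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")

    with open(paths.refseq_blast, "w") as ref_fh, open(paths.te_blast, "w") as pep_fh:
        for rec in records:
            for h in planted[rec.record_id]:
                if h.category == "HOST_REFSEQ":
                    ref_fh.write(_blast_line(rec.record_id, h, rng_scores) + "\n")
                elif h.category == "TE_PEP":
                    pep_fh.write(_blast_line(rec.record_id, h, rng_scores) + "\n")

    with open(paths.te_domtbl, "w") as fh:
        fh.write("# target name accession tlen query name accession qlen ...\n")
        fh.write("#" + "-" * 60 + "\n")
        for rec in records:
            qlen = len(rec.sequence) // 3
            for h in planted[rec.record_id]:
                if h.category == "TE_HMM":
                    fh.write(_domtbl_line(rec.record_id, h, qlen) + "\n")

    with open(paths.genome_metadata, "w") as fh:
        fh.write("assembly_id\tgenus\tspecies_epithet\tn50_bp\tbusco_complete_pct\tcontig_lengths\n")
        fh.write(f"{_GOOD_ASM}\tZymoseptoria\ttritici\t\t97.4\t400000,300000,200000,100000\n")
        fh.write(f"{_POOR_ASM}\tFusarium\tgraminearum\t40000\t85.0\t\n")

    with open(paths.source_genomes, "w") as fh:
        fh.write("consensus_id\tassembly_id\n")
        for rec in records:
            fh.write(f"{rec.record_id}\t{source[rec.record_id]}\n")

    with open(paths.class_map, "w") as fh:
        fh.write("subject_pattern\tclass_high\tclass_sub\n")
        for pattern, (high, sub) in _CLASS_MAP.items():
            fh.write(f"{pattern}\t{high}\t{sub}\n")

    lq = frozenset({_POOR_ASM})
    truths = [
        _truth_verdict(rec, planted[rec.record_id], lq, source[rec.record_id])
        for rec in records
    ]
    with open(paths.expected_verdicts, "w") as fh:
        cols = (
            "consensus_id host_gene non_autonomous evidence removed_quality "
            "lq_genome exclusive_refseq_residues retained"
        ).split()
        fh.write("\t".join(cols) + "\n")
        for t in truths:
            fh.write("\t".join(str(t[c]) for c in cols) + "\n")

    a_feats, b_feats, cmp_truth = make_annotation_pair(
        spec.seed + 2,
        n_shared=spec.ann_n_shared,
        n_unique_a=spec.ann_n_unique_a,
        n_unique_b=spec.ann_n_unique_b,
    )
    write_bed(a_feats, paths.annotations_a)
    write_bed(b_feats, paths.annotations_b)
    with open(paths.expected_comparison, "w") as fh:
        fh.write("quantity\tvalue\n")
        for k in sorted(cmp_truth):
            fh.write(f"{k}\t{cmp_truth[k]}\n")

    return paths


def read_expected_verdicts(path: Union[str, Path]) -> dict[str, dict]:
    """Load the expected-verdicts table back into per-record dicts."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            parsed = {
                k: (v == "True" if v in ("True", "False") else v)
                for k, v in row.items()
            }
            parsed["exclusive_refseq_residues"] = int(
                row["exclusive_refseq_residues"]
            )
            out[row["consensus_id"]] = parsed
    return out


# ---------------------------------------------------------------------------
# family sets for clustering


def make_family_set(
    n_families: int,
    copies: int,
    substitution_rate: float,
    seed: int,
    length_range: tuple[int, int] = (300, 2000),
    family_divergence: float | None = None,
    revcomp_fraction: float = 0.25,
) -> tuple[list[ConsensusRecord], dict[str, int]]:
    """Planted TE families for exercising the 80-80-80 criterion.

    Each family descends from one ancestor by independent per-position
    substitution at ``substitution_rate``; a fraction of non-founder
    copies is reverse-complemented. With ``family_divergence`` set, all
    family ancestors derive from a single root mutated at that rate
    (root itself is the first ancestor), planting known *between*-family
    identity (~``1 - family_divergence``) for split tests. Returns the
    records and the id -> family-index truth table.
    """
    rng = np.random.default_rng(seed)
    records: list[ConsensusRecord] = []
    truth: dict[str, int] = {}
    root = None
    if family_divergence is not None:
        root = random_seq(rng, int(rng.integers(*length_range)))
    for fam in range(n_families):
        if root is not None:
            ancestor = root if fam == 0 else mutate(rng, root, family_divergence)
        else:
            ancestor = random_seq(rng, int(rng.integers(*length_range)))
        for c in range(copies):
            seq = mutate(rng, ancestor, substitution_rate)
            if c > 0 and rng.random() < revcomp_fraction:
                seq = _revcomp(seq)
            rid = f"fam{fam + 1}-copy{c + 1}"
            records.append(ConsensusRecord(rid, seq, "Unknown"))
            truth[rid] = fam
    return records, truth


# ---------------------------------------------------------------------------
# annotation pairs


def make_annotation_pair(
    seed: int,
    n_shared: int = 6,
    n_unique_a: int = 4,
    n_unique_b: int = 5,
    seqid: str = "contig_1",
) -> tuple[list[AnnotationFeature], list[AnnotationFeature], dict[str, int]]:
    """Plant a pair of annotation sets with known shared/unique geometry.

    Shared loci get different widths per method (B's feature extends A's),
    exercising the per-method width accounting. Truth values come from a
    per-position mask oracle computed here, independent of the comparison
    code.
    """
    rng = np.random.default_rng(seed)
    classes = [("LTR", "Gypsy"), ("DNA", "hAT"), ("LINE", ""), ("Unknown", "")]
    a_feats: list[AnnotationFeature] = []
    b_feats: list[AnnotationFeature] = []
    cursor = 100

    def next_class():
        return classes[int(rng.integers(0, len(classes)))]

    for _ in range(n_shared):
        wa = int(rng.integers(200, 800))
        ext_left = int(rng.integers(0, 80))
        ext_right = int(rng.integers(0, 80))
        high, sub = next_class()
        a_feats.append(AnnotationFeature(seqid, cursor, cursor + wa, high, sub, "methodA"))
        b_feats.append(
            AnnotationFeature(
                seqid, max(0, cursor - ext_left), cursor + wa + ext_right, high, sub, "methodB"
            )
        )
        cursor += wa + ext_right + int(rng.integers(150, 400))
    for _ in range(n_unique_a):
        w = int(rng.integers(150, 600))
        high, sub = next_class()
        a_feats.append(AnnotationFeature(seqid, cursor, cursor + w, high, sub, "methodA"))
        cursor += w + int(rng.integers(150, 400))
    for _ in range(n_unique_b):
        w = int(rng.integers(150, 600))
        high, sub = next_class()
        b_feats.append(AnnotationFeature(seqid, cursor, cursor + w, high, sub, "methodB"))
        cursor += w + int(rng.integers(150, 400))

    size = cursor + 100
    mask_a = np.zeros(size, dtype=bool)
    mask_b = np.zeros(size, dtype=bool)
    for f in a_feats:
        mask_a[f.start : f.end] = True
    for f in b_feats:
        mask_b[f.start : f.end] = True
    truth = {
        "shared_positions": int((mask_a & mask_b).sum()),
        "unique_positions_a": int((mask_a & ~mask_b).sum()),
        "unique_positions_b": int((mask_b & ~mask_a).sum()),
        "shared_bp_a": sum(len(f) for f in a_feats if mask_b[f.start : f.end].any()),
        "shared_bp_b": sum(len(f) for f in b_feats if mask_a[f.start : f.end].any()),
        "unique_bp_a": sum(len(f) for f in a_feats if not mask_b[f.start : f.end].any()),
        "unique_bp_b": sum(len(f) for f in b_feats if not mask_a[f.start : f.end].any()),
    }
    return a_feats, b_feats, truth


def write_bed(features: Sequence[AnnotationFeature], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for f in features:
            cls = f.class_high + (f"/{f.class_sub}" if f.class_sub else "")
            fh.write(f"{f.seqid}\t{f.start}\t{f.end}\t{cls}\n")
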