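"""Base-pair agreement between two TE annotation sets of one genome.

Given the annotations produced by two methods over the same assembly, the
comparison reports, per category {shared, unique to A, unique to B}, the
annotated base pairs and their percentage of all annotated base pairs,
plus per-classification breakdowns. Two accounting modes are emitted:

* **position-level** — a genomic position is shared when covered by both
  methods; the category totals partition every annotated position, which
  gives the conservation identity ``A-covered = shared + unique_A``;
* **feature-width** — at shared loci the width of each method's own
  annotation is counted separately (annotation sizes differ between
  methods at the same locus, so a single shared width would misstate
  either method).

Strand is ignored: repeat annotations are compared as genomic extents.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .intervals import IntervalSet

__all__ = [
    "AnnotationFeature",
    "ComparisonSummary",
    "read_annotations",
    "categorize",
]


@dataclass(frozen=True)
class AnnotationFeature:
    """One TE annotation interval on a genomic sequence (0-based half-open)."""

    seqid: str
    start: int
    end: int
    class_high: str = "Unknown"
    class_sub: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        if not self.seqid:
            raise ValueError("seqid must be nonempty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"{self.seqid}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


def _split_class(label: str) -> tuple[str, str]:
    label = label.strip()
    if not label:
        return ("Unknown", "")
    high, _, sub = label.partition("/")
    return (high or "Unknown", sub)


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _class_from_gff3(type_col: str, attrs: Mapping[str, str]) -> str:
    for key in ("classification", "Classification", "Name", "family", "Target"):
        if attrs.get(key):
            # Target values look like "Name start end"; keep the name
            return attrs[key].split(" ")[0]
    return type_col


def read_annotations(
    path: Union[str, Path], format: str, method_label: str
) -> list[AnnotationFeature]:
    """Read TE annotations from BED or GFF3 and normalize them.

    BED intervals are used as-is (0-based half-open, name column 4 carries
    the classification); GFF3 is converted from 1-based inclusive, taking
    the classification from the ``classification``/``Name``/``family``/
    ``Target`` attribute, else the type column. Classification labels
    split on ``/`` into high/sub levels, defaulting to "Unknown".
    Within-method overlapping features of the same class on the same
    seqid are merged before comparison.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unknown annotation format {format!r}")
    path = Path(path)
    raw: list[AnnotationFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    if len(fields) < 3:
                        raise ValueError("BED needs >= 3 columns")
                    seqid, start, end = fields[0], int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 needs 9 columns")
                    seqid = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    label = _class_from_gff3(
                        fields[2], _parse_gff3_attributes(fields[8])
                    )
                if end <= start:
                    raise ValueError(f"end {end} <= start {start}")
                high, sub = _split_class(label)
                raw.append(
                    AnnotationFeature(
                        seqid=seqid,
                        start=start,
                        end=end,
                        class_high=high,
                        class_sub=sub,
                        method=method_label,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return merge_within_method(raw)


def merge_within_method(
    features: Iterable[AnnotationFeature],
) -> list[AnnotationFeature]:
    """Merge overlapping/touching same-class features of one method."""
    grouped: dict[tuple[str, str, str, str], list[tuple[int, int]]] = defaultdict(list)
    for f in features:
        grouped[(f.seqid, f.class_high, f.class_sub, f.method)].append(f.interval)
    merged = []
    for (seqid, high, sub, method), spans in sorted(grouped.items()):
        for s, e in IntervalSet(spans):
            merged.append(
                AnnotationFeature(
                    seqid=seqid,
                    start=s,
                    end=e,
                    class_high=high,
                    class_sub=sub,
                    method=method,
                )
            )
    merged.sort(key=lambda f: (f.seqid, f.start, f.end, f.class_high))
    return merged


@dataclass
class ComparisonSummary:
    """Shared/unique bp accounting between two annotation methods."""

    method_a: str
    method_b: str
    # position-level accounting
    shared_positions: int = 0
    unique_positions_a: int = 0
    unique_positions_b: int = 0
    # feature-width accounting at shared loci
    shared_bp_a: int = 0
    shared_bp_b: int = 0
    unique_bp_a: int = 0
    unique_bp_b: int = 0
    # per-class breakdowns (width accounting), class_high -> bp
    shared_by_class_a: dict[str, int] = field(default_factory=dict)
    shared_by_class_b: dict[str, int] = field(default_factory=dict)
    unique_by_class_a: dict[str, int] = field(default_factory=dict)
    unique_by_class_b: dict[str, int] = field(default_factory=dict)
    genome_size: int | None = None

    @property
    def covered_bp_a(self) -> int:
        return self.shared_positions + self.unique_positions_a

    @property
    def covered_bp_b(self) -> int:
        return self.shared_positions + self.unique_positions_b

    def percentages(self, mode: str = "width") -> dict[str, float]:
        """Category percentages of all annotated base pairs (sum to 100)."""
        if mode == "width":
            total = (
                self.shared_bp_a + self.shared_bp_b + self.unique_bp_a + self.unique_bp_b
            )
            parts = {
                "shared": self.shared_bp_a + self.shared_bp_b,
                "unique_a": self.unique_bp_a,
                "unique_b": self.unique_bp_b,
            }
        elif mode == "position":
            total = self.shared_positions + self.unique_positions_a + self.unique_positions_b
            parts = {
                "shared": self.shared_positions,
                "unique_a": self.unique_positions_a,
                "unique_b": self.unique_positions_b,
            }
        else:
            raise ValueError(f"unknown accounting mode {mode!r}")
        if total == 0:
            return {k: 0.0 for k in parts}
        return {k: 100.0 * v / total for k, v in parts.items()}

    def genome_fractions(self) -> dict[str, float] | None:
        if not self.genome_size:
            return None
        return {
            "covered_pct_a": 100.0 * self.covered_bp_a / self.genome_size,
            "covered_pct_b": 100.0 * self.covered_bp_b / self.genome_size,
            "shared_pct": 100.0 * self.shared_positions / self.genome_size,
        }

    def to_dict(self) -> dict:
        d = {
            "method_a": self.method_a,
            "method_b": self.method_b,
            "position": {
                "shared": self.shared_positions,
                "unique_a": self.unique_positions_a,
                "unique_b": self.unique_positions_b,
                "pct": self.percentages("position"),
            },
            "width": {
                "shared_bp_a": self.shared_bp_a,
                "shared_bp_b": self.shared_bp_b,
                "unique_a": self.unique_bp_a,
                "unique_b": self.unique_bp_b,
                "pct": self.percentages("width"),
                "shared_by_class_a": dict(sorted(self.shared_by_class_a.items())),
                "shared_by_class_b": dict(sorted(self.shared_by_class_b.items())),
                "unique_by_class_a": dict(sorted(self.unique_by_class_a.items())),
                "unique_by_class_b": dict(sorted(self.unique_by_class_b.items())),
            },
        }
        if self.genome_size:
            d["genome_size"] = self.genome_size
            d["genome_fractions"] = self.genome_fractions()
        return d

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=False)
            fh.write("\n")

    def to_tsv(self, path: Union[str, Path]) -> None:
        pct_w = self.percentages("width")
        pct_p = self.percentages("position")
        rows = [
            ("position", "shared", self.shared_positions, f"{pct_p['shared']:.2f}"),
            ("position", f"unique_{self.method_a}", self.unique_positions_a, f"{pct_p['unique_a']:.2f}"),
            ("position", f"unique_{self.method_b}", self.unique_positions_b, f"{pct_p['unique_b']:.2f}"),
            ("width", f"shared_{self.method_a}", self.shared_bp_a, ""),
            ("width", f"shared_{self.method_b}", self.shared_bp_b, ""),
            ("width", "shared", self.shared_bp_a + self.shared_bp_b, f"{pct_w['shared']:.2f}"),
            ("width", f"unique_{self.method_a}", self.unique_bp_a, f"{pct_w['unique_a']:.2f}"),
            ("width", f"unique_{self.method_b}", self.unique_bp_b, f"{pct_w['unique_b']:.2f}"),
        ]
        with open(path, "w") as fh:
            fh.write("accounting\tcategory\tbp\tpct_of_all_annotated\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")


def _coverage_by_seqid(
    features: Sequence[AnnotationFeature],
) -> dict[str, IntervalSet]:
    spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for f in features:
        spans[f.seqid].append(f.interval)
    return {sid: IntervalSet(sp) for sid, sp in spans.items()}


def categorize(
    a_features: Sequence[AnnotationFeature],
    b_features: Sequence[AnnotationFeature],
    genome_size: int | None = None,
) -> ComparisonSummary:
    """Compute shared/unique bp between two normalized annotation sets.

    Position-level: per seqid, positions covered by both methods are
    shared; positions covered by one method only are unique to it.
    Feature-width level: each merged feature of a method counts its full
    width under "shared" when it overlaps the other method's coverage,
    else under "unique"; per-class breakdowns follow the owning method's
    high-level classification.
    """
    method_a = a_features[0].method if a_features else "A"
    method_b = b_features[0].method if b_features else "B"
    summary = ComparisonSummary(
        method_a=method_a, method_b=method_b, genome_size=genome_size
    )

    cov_a = _coverage_by_seqid(a_features)
    cov_b = _coverage_by_seqid(b_features)
    for sid in set(cov_a) | set(cov_b):
        a = cov_a.get(sid, IntervalSet())
        b = cov_b.get(sid, IntervalSet())
        summary.shared_positions += (a & b).total_length()
        summary.unique_positions_a += (a - b).total_length()
        summary.unique_positions_b += (b - a).total_length()

    def tally(features, other_cov, shared_by_class, unique_by_class):
        shared_bp = unique_bp = 0
        for f in features:
            other = other_cov.get(f.seqid, IntervalSet())
            overlaps = bool((IntervalSet([f.interval]) & other).total_length())
            if overlaps:
                shared_bp += len(f)
                shared_by_class[f.class_high] = shared_by_class.get(f.class_high, 0) + len(f)
            else:
                unique_bp += len(f)
                unique_by_class[f.class_high] = unique_by_class.get(f.class_high, 0) + len(f)
        return shared_bp, unique_bp

    summary.shared_bp_a, summary.unique_bp_a = tally(
        a_features, cov_b, summary.shared_by_class_a, summary.unique_by_class_a
    )
    summary.shared_bp_b, summary.unique_bp_b = tally(
        b_features, cov_a, summary.shared_by_class_b, summary.unique_by_class_b
    )
    return summary
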