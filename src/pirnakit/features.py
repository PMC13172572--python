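"""Strand-aware, multimapper-weighted counting over feature intervals and
post-processing of protein-vs-genome homology hits.

Feature counting distributes multimappers evenly across repeats through
their 1/n weights: an alignment overlapping a feature by at least one base
contributes ``weight * count`` to the sense total when strands match and to
antisense otherwise. Homology hits (tBLASTn-style tabular input) are
filtered by ORF-class-specific bit-score thresholds, merged per class, and
size-filtered into candidate GAG/POL/ENV regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .reads import ProcessedRead, map_reads

ORF_CLASSES = ("GAG", "POL", "ENV")

POL_MIN_BITSCORE = 50.0     # strict: kept only when bitscore > 50
GAG_ENV_MIN_BITSCORE = 30.0
MAX_EVALUE = 1e-10          # inclusive
POL_MIN_REGION = 1500       # strict: regions must be larger than this
GAG_ENV_MIN_REGION = 300


@dataclass(frozen=True)
class FeatureInterval:
    contig: str
    start: int
    end: int
    strand: str
    feature_class: str = "other"
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty feature interval {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"feature strand {self.strand!r}")


@dataclass(frozen=True)
class BlastHit:
    bait_id: str
    orf_class: str
    contig: str
    start: int   # 0-based
    end: int     # half-open
    strand: str
    bitscore: float
    evalue: float


@dataclass
class MergedRegion:
    orf_class: str
    contig: str
    start: int
    end: int
    bait_ids: set = field(default_factory=set)

    @property
    def size(self) -> int:
        return self.end - self.start


def features_from_bed(df: pd.DataFrame, class_column: str = "name") -> list[FeatureInterval]:
    """BED6 rows to features; the class is the first '|'-token of the name."""
    feats = []
    for row in df.itertuples(index=False):
        name = str(getattr(row, class_column, "other"))
        feats.append(
            FeatureInterval(
                contig=row.contig, start=int(row.start), end=int(row.end),
                strand=getattr(row, "strand", "+"),
                feature_class=name.split("|")[0].split("_")[0], name=name,
            )
        )
    return feats


def weighted_strand_counts(
    alignments: pd.DataFrame, features: Sequence[FeatureInterval]
) -> pd.DataFrame:
    """Per-class sense/antisense weighted piRNA totals.

    An alignment overlapping several features of one class still contributes
    once per class (its full weight); classes are tallied independently, so
    the same placement may appear under two classes it overlaps.
    """
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)
    classes = sorted({f.feature_class for f in features})
    totals = {c: {"sense": 0.0, "antisense": 0.0} for c in classes}
    pir = alignments[alignments["is_pirna"]]
    for row in pir.itertuples(index=False):
        tree = trees.get(row.contig)
        if tree is None:
            continue
        w = row.weight * row.count
        hit_classes: dict[str, set[str]] = {}
        for iv in tree.overlap(row.start, row.end):
            f: FeatureInterval = iv.data
            orient = "sense" if f.strand == row.strand else "antisense"
            hit_classes.setdefault(f.feature_class, set()).add(orient)
        for cls, orients in hit_classes.items():
            # strand orientation decided per feature; a placement matching both
            # orientations within one class splits between them
            share = w / len(orients)
            for orient in orients:
                totals[cls][orient] += share
    return pd.DataFrame(
        [(c, totals[c]["sense"], totals[c]["antisense"]) for c in classes],
        columns=["feature_class", "sense", "antisense"],
    )


def _default_orf_class(bait_id: str) -> str:
    token = bait_id.split("|")[0].split("_")[0].upper()
    if token not in ORF_CLASSES:
        raise ValueError(f"cannot derive ORF class from bait id {bait_id!r}")
    return token


def parse_blast_tabular(
    path_or_lines,
    orf_class_from: Callable[[str], str] = _default_orf_class,
) -> list[BlastHit]:
    """Parse 12-column outfmt-6 rows into hits with 0-based half-open spans.

    Subject coordinates arriving in descending order indicate a minus-strand
    hit. Malformed rows raise with their line number.
    """
    if isinstance(path_or_lines, (str, bytes)) or hasattr(path_or_lines, "read"):
        fh = open(path_or_lines) if isinstance(path_or_lines, (str, bytes)) else path_or_lines
        lines = fh.read().splitlines()
    else:
        lines = list(path_or_lines)
    hits = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 12:
            raise ValueError(f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}")
        try:
            qseqid, sseqid = parts[0], parts[1]
            sstart, send = int(parts[8]), int(parts[9])
            evalue, bitscore = float(parts[10]), float(parts[11])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        strand = "+" if sstart <= send else "-"
        lo, hi = (sstart, send) if strand == "+" else (send, sstart)
        hits.append(
            BlastHit(
                bait_id=qseqid, orf_class=orf_class_from(qseqid), contig=sseqid,
                start=lo - 1, end=hi, strand=strand, bitscore=bitscore, evalue=evalue,
            )
        )
    return hits


def filter_blast_hits(hits: Iterable[BlastHit]) -> list[BlastHit]:
    """Class-specific bit-score filter plus the e-value ceiling.

    POL hits need bitscore strictly above 50; GAG and ENV strictly above 30;
    every hit must have evalue <= 1e-10.
    """
    out = []
    for h in hits:
        if h.evalue > MAX_EVALUE:
            continue
        threshold = POL_MIN_BITSCORE if h.orf_class == "POL" else GAG_ENV_MIN_BITSCORE
        if h.bitscore > threshold:
            out.append(h)
    return out


def merge_hit_regions(hits: Iterable[BlastHit], min_baits: int = 5) -> list[MergedRegion]:
    """Union overlapping or book-ended hits per ORF class and contig.

    A merged region survives only when it gathered hits from at least
    ``min_baits`` distinct baits.
    """
    regions: list[MergedRegion] = []
    by_key: dict[tuple[str, str], list[BlastHit]] = {}
    for h in hits:
        by_key.setdefault((h.orf_class, h.contig), []).append(h)
    for (orf_class, contig), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.start, h.end))
        current: MergedRegion | None = None
        for h in group:
            if current is not None and h.start <= current.end:
                current.end = max(current.end, h.end)
                current.bait_ids.add(h.bait_id)
            else:
                if current is not None:
                    regions.append(current)
                current = MergedRegion(orf_class, contig, h.start, h.end, {h.bait_id})
        if current is not None:
            regions.append(current)
    return [r for r in regions if len(r.bait_ids) >= min_baits]


def size_filter(regions: Iterable[MergedRegion]) -> list[MergedRegion]:
    """Keep POL regions larger than 1500 nt and GAG/ENV larger than 300 nt."""
    out = []
    for r in regions:
        minimum = POL_MIN_REGION if r.orf_class == "POL" else GAG_ENV_MIN_REGION
        if r.size > minimum:
            out.append(r)
    return out


def per_reference_strand_counts(
    reads: Iterable[ProcessedRead],
    references: Mapping[str, str],
    max_mismatches: int = 3,
    per_million: float | None = None,
) -> pd.DataFrame:
    """Sense/antisense cpm per reference sequence (e.g. virus segments).

    Reads are placed with up to ``max_mismatches`` mismatches and weighted
    1/n across their placements within the reference set. ``per_million``
    sets the cpm denominator (defaults to the total count of the input
    reads).
    """
    reads = list(reads)
    basis = per_million if per_million is not None else sum(r.count for r in reads)
    aln = map_reads(reads, references, max_mismatches=max_mismatches)
    rows = []
    for name in references:
        sub = aln[aln["contig"] == name] if not aln.empty else aln
        sense = float((sub.loc[sub["strand"] == "+", "weight"] * sub.loc[sub["strand"] == "+", "count"]).sum()) if not sub.empty else 0.0
        anti = float((sub.loc[sub["strand"] == "-", "weight"] * sub.loc[sub["strand"] == "-", "count"]).sum()) if not sub.empty else 0.0
        scale = 1e6 / basis if basis else 0.0
        rows.append((name, sense * scale, anti * scale))
    return pd.DataFrame(rows, columns=["reference", "sense_cpm", "antisense_cpm"])
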