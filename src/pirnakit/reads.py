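"""Raw-read processing: trimming, filtering, collapsing and mapping.

The mapper is a self-contained exact scanner for short (18-40 nt) reads:
exact occurrences are found by substring search on both strands, and the
k-mismatch stratum is reached through pigeonhole anchoring (a placement
with at most k mismatches contains at least one exact (k+1)-th part of the
read). Only placements at the minimal achievable mismatch count are
reported ("all-best-strata" semantics), each carrying a 1/n multimapper
weight so the weights of one read always sum to 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from ._seq import find_all, hamming, revcomp

MIN_READ_LEN = 18
MAX_READ_LEN = 40
PIRNA_MIN_LEN = 23

ALIGNMENT_COLUMNS = [
    "sequence", "contig", "start", "end", "strand", "mismatches",
    "n_instances", "weight", "count", "length", "five_prime", "three_prime",
    "is_unique", "is_pirna",
]


@dataclass(frozen=True)
class ProcessedRead:
    """A collapsed read species: one sequence with its multiplicity."""

    sequence: str
    count: int = 1


class Alignment(NamedTuple):
    sequence: str
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    n_instances: int
    weight: float
    count: int

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def trim_read(raw: str, adapter: str, umi_len: int = 4) -> str | None:
    """Remove the 3' adapter and the random UMI bases from both ends.

    The leftmost full adapter occurrence wins; a prefix of the adapter of at
    least 10 nt is also accepted at the very end of the read (the sequencer
    may have run out of cycles mid-adapter). Returns ``None`` when no adapter
    is found or when the remainder cannot contain both UMIs.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if umi_len < 0:
        raise ValueError("umi_len must be >= 0")
    raw = raw.upper()
    idx = raw.find(adapter)
    if idx == -1:
        min_prefix = min(10, len(adapter))
        for plen in range(len(adapter) - 1, min_prefix - 1, -1):
            if raw.endswith(adapter[:plen]):
                idx = len(raw) - plen
                break
    if idx == -1:
        return None
    remainder = raw[:idx]
    if len(remainder) < 2 * umi_len:
        return None
    return remainder[umi_len : len(remainder) - umi_len] if umi_len else remainder


def length_filter(
    reads: Iterable[ProcessedRead], min_len: int = MIN_READ_LEN, max_len: int = MAX_READ_LEN
) -> list[ProcessedRead]:
    """Keep reads with ``min_len <= length <= max_len`` (inclusive bounds)."""
    return [r for r in reads if min_len <= len(r.sequence) <= max_len]


def classify_pirna(read: ProcessedRead | str, min_len: int = PIRNA_MIN_LEN) -> bool:
    """A read counts as a piRNA iff it is at least 23 nt long."""
    seq = read if isinstance(read, str) else read.sequence
    return len(seq) >= min_len


def collapse_reads(sequences: Iterable[str]) -> list[ProcessedRead]:
    """Collapse identical sequences into species with counts (sorted)."""
    counts = Counter(s.upper() for s in sequences)
    return [ProcessedRead(seq, n) for seq, n in sorted(counts.items())]


_INDEX_K = 14


def _build_exact_index(contigs: Mapping[str, str], k: int = _INDEX_K) -> dict[str, list[tuple[str, int]]]:
    """Positions of every forward-strand k-mer, for exact-match seeding."""
    index: dict[str, list[tuple[str, int]]] = {}
    for name, g in contigs.items():
        for i in range(len(g) - k + 1):
            index.setdefault(g[i : i + k], []).append((name, i))
    return index


def _exact_hits(q: str, contigs: Mapping[str, str], index: dict | None) -> list[tuple[str, int]]:
    if index is None or len(q) < _INDEX_K:
        return [(name, p) for name, g in contigs.items() for p in find_all(g, q)]
    out = []
    for name, p in index.get(q[:_INDEX_K], ()):
        g = contigs[name]
        if g[p : p + len(q)] == q:
            out.append((name, p))
    return out


def _placements(
    seq: str, contigs: Mapping[str, str], max_mismatches: int, index: dict | None = None
) -> list[tuple[str, int, str, int]]:
    """All best-stratum placements of ``seq``: (contig, start, strand, mm)."""
    if seq.count("N") > max_mismatches:
        return []
    L = len(seq)
    hits: list[tuple[str, int, str, int]] = []
    queries = [("+", seq), ("-", revcomp(seq))]
    if "N" not in seq:
        for strand, q in queries:
            hits.extend((name, p, strand, 0) for name, p in _exact_hits(q, contigs, index))
        if hits:
            return hits
    if max_mismatches == 0:
        return []
    # pigeonhole: one of (max_mismatches + 1) parts must match exactly
    nparts = max_mismatches + 1
    bounds = [round(i * L / nparts) for i in range(nparts + 1)]
    best = max_mismatches + 1
    candidates: dict[tuple[str, int, str], int] = {}
    for strand, q in queries:
        for name, g in contigs.items():
            glen = len(g)
            seen: set[int] = set()
            for i in range(nparts):
                part = q[bounds[i] : bounds[i + 1]]
                if "N" in part or not part:
                    continue
                for p in find_all(g, part):
                    start = p - bounds[i]
                    if start < 0 or start + L > glen or start in seen:
                        continue
                    seen.add(start)
                    mm = hamming(q, g[start : start + L])
                    if mm <= max_mismatches:
                        candidates[(name, start, strand)] = mm
                        best = min(best, mm)
    return [(n, s, st, mm) for (n, s, st), mm in candidates.items() if mm == best]


def map_reads(
    reads: Iterable[ProcessedRead],
    genome: Mapping[str, str],
    max_mismatches: int = 1,
) -> pd.DataFrame:
    """Map collapsed reads to the genome, reporting the best stratum only.

    Returns an alignment table (one row per placement) with 1/n weights,
    genome-uniqueness flags and piRNA flags. Reads with no placement are
    dropped; a read with more Ns than the mismatch budget cannot map.
    """
    index = _build_exact_index(genome)
    rows = []
    for read in reads:
        hits = _placements(read.sequence.upper(), genome, max_mismatches, index)
        n_inst = len(hits)
        for contig, start, strand, mm in sorted(hits):
            rows.append(
                (read.sequence, contig, start, start + len(read.sequence), strand,
                 mm, n_inst, 1.0 / n_inst, read.count)
            )
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS[:9])
    if df.empty:
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS)
    df["length"] = df["end"] - df["start"]
    df["five_prime"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    df["three_prime"] = np.where(df["strand"] == "+", df["end"] - 1, df["start"])
    df["is_unique"] = df["n_instances"] == 1
    df["is_pirna"] = df["length"] >= PIRNA_MIN_LEN
    return df


def filter_contaminants(
    reads: Iterable[ProcessedRead],
    contaminant_refs: Mapping[str, str],
    max_mismatches: int = 1,
) -> list[ProcessedRead]:
    """Drop reads placeable on either strand of any contaminant reference."""
    reads = list(reads)
    if not contaminant_refs:
        return reads
    index = _build_exact_index(contaminant_refs)
    return [
        r for r in reads
        if not _placements(r.sequence.upper(), contaminant_refs, max_mismatches, index)
    ]


def process_fastq(
    records: Iterable[tuple[str, str]],
    adapter: str,
    umi_len: int = 4,
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
    contaminant_refs: Mapping[str, str] | None = None,
    max_contaminant_mismatches: int = 1,
) -> list[ProcessedRead]:
    """Trim, length-filter, contaminant-filter and collapse FASTQ records."""
    inserts = []
    for _, raw in records:
        insert = trim_read(raw, adapter, umi_len)
        if insert is not None:
            inserts.append(insert)
    reads = length_filter(collapse_reads(inserts), min_len, max_len)
    if contaminant_refs:
        reads = filter_contaminants(reads, contaminant_refs, max_contaminant_mismatches)
    return reads
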