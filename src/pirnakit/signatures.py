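"""Linkage statistics and nucleotide-bias profiles that classify the
dominant piRNA biogenesis mechanism.

Three diagnostic statistics are computed from weighted alignments:

* **Phasing** — head-to-tail production leaves uridine immediately
  downstream of piRNA 3' ends and a +1 linkage between 3' ends and the next
  5' end. The distance profile accumulates, for every 3'-end position with
  abundance a(t) and signed downstream offset d, the product a(t) * b(t+d)
  with b the 5'-end abundance, over a 20-nt window; the z-score at d = +1 is
  the phasing linkage.
* **Ping-pong** — reciprocal slicing produces plus/minus pairs whose 5'
  ends overlap by exactly 10 nt, with uridine at position 1 of one strand
  and adenosine at position 10 of the other. The overlap profile scores
  s in 1..20 as the sum over i of a_plus(i) * a_minus(i + s - 1); the
  z-score at s = 10 is the ping-pong linkage.
* **In-trans ping-pong** — trigger and responder piRNAs from different loci
  pair through g2-g10 complementarity. Reads are reduced to 9-mer frequency
  tables (g1-g9, last 9 nt, reverse-complemented g2-g10), each rescaled to
  sum to 1000; the linkage is the dot product of the g1g9 and g2g10revComp
  tables, with last9 x g2g10revComp as the genomic background.

z-scores are the deviation of the focal frequency from the window mean in
units of the population standard deviation of the window (focal included);
a flat window gives z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp

#: A well-characterised *Aedes aegypti* ovarian piRNA and its ping-pong
#: partner (from the canonical-pair tile on chromosome NC_035109.1); their
#: 5'-anchored antisense overlap is the canonical 10 nt, which makes them a
#: handy worked example for the pairing statistics.
AEDES_PINGPONG_PAIR = (
    "TTTCTATTAAATATGTTGCAATCAACCG",
    "TTAATAGAAATTACAGTGGTTGGTATCTT",
)

PHASE_WINDOW = np.arange(-9, 11)     # signed 3'-to-5' distances, 20 bins
OVERLAP_WINDOW = np.arange(1, 21)    # 5'-5' overlaps, 20 bins
PINGPONG_OVERLAP = 10
PHASING_LINKAGE = 1
NINEMER_TABLE_SUM = 1000.0


def z_score(frequencies: Sequence[float], focal: int) -> float:
    """z of the focal entry against the whole window (population sd).

    The focal value is part of the window mean and sd; a zero-variance
    window yields z = 0. Windows of fewer than 3 positions are rejected.
    """
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size < 3:
        raise ValueError("z-score window must have at least 3 positions")
    sd = freqs.std()
    if sd == 0:
        return 0.0
    return float((freqs[focal] - freqs.mean()) / sd)


@dataclass
class EndProfile:
    """Positional frequency profile around an anchored read end."""

    anchor: str
    positions: np.ndarray
    frequencies: pd.DataFrame  # offset x base (A/C/G/T), each row sums to 1
    focal_base: str
    focal_offset: int
    z: float

    def base_frequencies(self, base: str) -> np.ndarray:
        return self.frequencies[base].to_numpy()


@dataclass
class OverlapProfile:
    overlaps: np.ndarray
    frequencies: np.ndarray
    z: float

    @property
    def mode(self) -> int:
        return int(self.overlaps[int(np.argmax(self.frequencies))])


@dataclass
class DistanceProfile:
    distances: np.ndarray
    frequencies: np.ndarray
    z: float

    @property
    def mode(self) -> int:
        return int(self.distances[int(np.argmax(self.frequencies))])


@dataclass
class NineMerTable:
    view: str
    frequencies: dict[str, float]

    def dot(self, other: "NineMerTable") -> float:
        small, large = self.frequencies, other.frequencies
        if len(small) > len(large):
            small, large = large, small
        return float(sum(v * large.get(k, 0.0) for k, v in small.items()))


@dataclass
class InTransResult:
    linkage: float
    background: float
    tables: dict[str, NineMerTable] = field(repr=False, default_factory=dict)

    @property
    def ratio(self) -> float:
        if self.background > 0:
            return self.linkage / self.background
        return float("inf") if self.linkage > 0 else float("nan")


_ANCHORS = ("five_prime_pos1", "read_pos10", "three_prime_downstream")


def end_nucleotide_profile(
    alignments: pd.DataFrame,
    genome: Mapping[str, str],
    anchor: str,
    window: int = 11,
    focal_base: str | None = None,
) -> EndProfile:
    """Base frequencies in a centred window around a read-end anchor.

    ``five_prime_pos1`` anchors on the first read base, ``read_pos10`` on
    the tenth, ``three_prime_downstream`` on the base immediately 3' of the
    read's 3' end. Offsets run in read orientation; minus-strand reads are
    complemented. Frequencies are abundance-weighted (weight x count); the
    z-score is computed for ``focal_base`` at offset 0 across the window.
    The conventional focal base is U (T) at position 1 and downstream of 3'
    ends, and A at position 10.
    """
    if anchor not in _ANCHORS:
        raise ValueError(f"anchor must be one of {_ANCHORS}")
    if focal_base is None:
        focal_base = "A" if anchor == "read_pos10" else "T"
    half = window // 2
    offsets = np.arange(-half, window - half)
    counts = pd.DataFrame(0.0, index=offsets, columns=list("ACGT"))
    for row in alignments.itertuples(index=False):
        seq = genome[row.contig]
        w = row.weight * row.count
        sign = 1 if row.strand == "+" else -1
        if anchor == "five_prime_pos1":
            center = row.five_prime
        elif anchor == "read_pos10":
            center = row.five_prime + sign * 9
        else:
            center = row.three_prime + sign
        for off in offsets:
            pos = center + sign * off
            if not 0 <= pos < len(seq):
                continue
            base = seq[pos] if sign == 1 else revcomp(seq[pos])
            if base in "ACGT":
                counts.at[off, base] += w
    row_sums = counts.sum(axis=1)
    freqs = counts.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    profile = freqs[focal_base].to_numpy()
    z = z_score(profile, int(np.flatnonzero(offsets == 0)[0]))
    return EndProfile(anchor, offsets, freqs, focal_base, 0, z)


def _end_abundance(alignments: pd.DataFrame, column: str) -> dict[int, float]:
    w = alignments["weight"] * alignments["count"]
    return w.groupby(alignments[column]).sum().to_dict()


def phasing_distance_profile(
    alignments: pd.DataFrame, window: np.ndarray = PHASE_WINDOW
) -> DistanceProfile:
    """Signed 3'-to-5' distance profile over a 20-nt window; z at +1.

    d = +1 means a 5' end sits on the very next base after a 3' end —
    the head-to-tail signature of phased biogenesis. Both strands are
    accumulated in transcript orientation and the window frequencies are
    abundance-weighted products of 3'- and 5'-end abundances.
    """
    if alignments.empty:
        raise ValueError("no alignments: phasing profile undefined")
    scores = np.zeros(window.size)
    seen_three_prime = False
    for strand, sign in (("+", 1), ("-", -1)):
        sub = alignments[alignments["strand"] == strand]
        if sub.empty:
            continue
        seen_three_prime = True
        a3 = _end_abundance(sub, "three_prime")
        a5 = _end_abundance(sub, "five_prime")
        for t, a in a3.items():
            for j, d in enumerate(window):
                b = a5.get(t + sign * int(d))
                if b:
                    scores[j] += a * b
    if not seen_three_prime:
        raise ValueError("no 3' ends in the region: phasing profile undefined")
    total = scores.sum()
    freqs = scores / total if total > 0 else scores
    z = z_score(freqs, int(np.flatnonzero(window == PHASING_LINKAGE)[0]))
    return DistanceProfile(window, freqs, z)


def pingpong_overlap_profile(
    plus_5p: Mapping[int, float],
    minus_5p: Mapping[int, float],
    window: np.ndarray = OVERLAP_WINDOW,
    mode: str = "product",
) -> OverlapProfile:
    """5'-5' overlap profile between plus- and minus-strand reads; z at 10.

    score(s) sums a_plus(i) * a_minus(i + s - 1) over plus 5' positions i
    (``mode='min'`` replaces the product with the minimum, a sensitivity
    variant). An overlap of 10 is the ping-pong signature.
    """
    if mode not in ("product", "min"):
        raise ValueError("mode must be 'product' or 'min'")
    scores = np.zeros(window.size)
    for i, a in plus_5p.items():
        for j, s in enumerate(window):
            b = minus_5p.get(i + int(s) - 1)
            if b:
                scores[j] += a * b if mode == "product" else min(a, b)
    total = scores.sum()
    freqs = scores / total if total > 0 else scores
    z = z_score(freqs, int(np.flatnonzero(window == PINGPONG_OVERLAP)[0])) if total > 0 else 0.0
    return OverlapProfile(window, freqs, z)


def tile_pingpong(
    alignments: pd.DataFrame,
    tiles: pd.DataFrame,
    total_genome_mapped: float,
    min_plus_cpm: float = 1000.0,
    min_minus_cpm: float = 10.0,
    mode: str = "product",
) -> tuple[dict[tuple[str, int], OverlapProfile], list[tuple[str, int]]]:
    """Per-tile ping-pong profiles for tiles passing coverage thresholds.

    A tile qualifies when its plus- and minus-strand 5'-end coverage exceed
    ``min_plus_cpm`` and ``min_minus_cpm`` counts per million genome-mapped
    reads. Returns profiles keyed by (contig, tile start) plus the skipped
    tiles.
    """
    if total_genome_mapped <= 0:
        raise ValueError("total_genome_mapped must be positive")
    profiles: dict[tuple[str, int], OverlapProfile] = {}
    skipped: list[tuple[str, int]] = []
    for row in tiles.itertuples(index=False):
        in_tile = alignments[
            (alignments["contig"] == row.contig)
            & (alignments["five_prime"] >= row.start)
            & (alignments["five_prime"] < row.end)
        ]
        plus = in_tile[in_tile["strand"] == "+"]
        minus = in_tile[in_tile["strand"] == "-"]
        cpm_plus = (plus["weight"] * plus["count"]).sum() * 1e6 / total_genome_mapped
        cpm_minus = (minus["weight"] * minus["count"]).sum() * 1e6 / total_genome_mapped
        if cpm_plus <= min_plus_cpm or cpm_minus <= min_minus_cpm:
            skipped.append((row.contig, row.start))
            continue
        profiles[(row.contig, row.start)] = pingpong_overlap_profile(
            _end_abundance(plus, "five_prime"), _end_abundance(minus, "five_prime"), mode=mode
        )
    return profiles, skipped


def strand_size_stats(alignments: pd.DataFrame) -> dict[str, dict]:
    """Abundance-weighted length histogram and mean per strand."""
    out: dict[str, dict] = {}
    for strand in "+-":
        sub = alignments[alignments["strand"] == strand]
        if sub.empty:
            out[strand] = {"mean": float("nan"), "histogram": pd.Series(dtype=float)}
            continue
        w = sub["weight"] * sub["count"]
        hist = w.groupby(sub["length"]).sum().sort_index()
        out[strand] = {"mean": float((sub["length"] * w).sum() / w.sum()), "histogram": hist}
    return out


def _ninemer_table(view: str, slices: Mapping[str, float]) -> NineMerTable:
    total = sum(slices.values())
    if total == 0:
        raise ValueError(f"empty 9-mer table for view {view}")
    scale = NINEMER_TABLE_SUM / total
    return NineMerTable(view, {k: v * scale for k, v in slices.items()})


def in_trans_pingpong(
    reads: Sequence[tuple[str, float]],
    exclusion_intervals: Sequence[tuple[str, int, int]] = (),
    alignments: pd.DataFrame | None = None,
) -> InTransResult:
    """In-trans ping-pong linkage from genome-mapping piRNA reads.

    ``reads`` are (sequence, abundance) pairs, already restricted to piRNA
    length. Sequences with an alignment 5' end inside any exclusion interval
    are removed first (used to blacklist tiles dominated by canonical
    ping-pong pairs, which would inflate the statistic). Three 9-mer tables
    are built — g1g9, last9 and the reverse complement of g2-g10 — each
    rescaled to sum to 1000; linkage = g1g9 . g2g10revComp and background =
    last9 . g2g10revComp.
    """
    excluded: set[str] = set()
    if exclusion_intervals and alignments is not None:
        for contig, lo, hi in exclusion_intervals:
            mask = (
                (alignments["contig"] == contig)
                & (alignments["five_prime"] >= lo)
                & (alignments["five_prime"] < hi)
            )
            excluded.update(alignments.loc[mask, "sequence"])
    g1g9: dict[str, float] = {}
    last9: dict[str, float] = {}
    g2g10rc: dict[str, float] = {}
    n_used = 0
    for seq, abundance in reads:
        if seq in excluded:
            continue
        if len(seq) < 10:
            raise ValueError("reads must be at least 10 nt for the 9-mer views")
        n_used += 1
        for table, kmer in (
            (g1g9, seq[0:9]),
            (last9, seq[-9:]),
            (g2g10rc, revcomp(seq[1:10])),
        ):
            table[kmer] = table.get(kmer, 0.0) + abundance
    if n_used == 0:
        raise ValueError("no reads left for the in-trans analysis")
    tables = {
        "g1g9": _ninemer_table("g1g9", g1g9),
        "last9": _ninemer_table("last9", last9),
        "g2g10_revcomp": _ninemer_table("g2g10_revcomp", g2g10rc),
    }
    return InTransResult(
        linkage=tables["g1g9"].dot(tables["g2g10_revcomp"]),
        background=tables["last9"].dot(tables["g2g10_revcomp"]),
        tables=tables,
    )


def pair_overlap_length(seq_a: str, seq_b: str) -> int:
    """Largest k with the first k nt of one read reverse-complementing the
    first k nt of the other (10 for a canonical ping-pong pair)."""
    for k in range(min(len(seq_a), len(seq_b)), 0, -1):
        if seq_a[:k] == revcomp(seq_b[:k]):
            return k
    return 0
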