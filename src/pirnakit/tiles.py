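"""Genome mappability, 0.5-kb tiles, cpm counting and cluster calling.

Somatic piRNA clusters are discovered by intersecting ovary and embryo
libraries: genome-unique piRNA reads are counted in uniquely-mappable
0.5-kb tiles, normalised to counts per million genome-unique piRNA mappers
(cpm), and tiles strongly enriched in the ovary are merged into cluster
calls. Uniqueness is defined at 25-mer resolution: a position is unique iff
its 25-mer occurs exactly once in the union of both genome strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._seq import revcomp

TILE_SIZE = 500
KMER_SIZE = 25
MIN_UNIQUE_FRAC = 0.85

TILE_COLUMNS = ["contig", "start", "end", "unique_frac"]


def kmer_uniqueness(genome: Mapping[str, str], k: int = KMER_SIZE) -> dict[str, np.ndarray]:
    """Per-contig boolean mask of k-mer-unique positions.

    ``mask[p]`` is True iff the k-mer starting at ``p`` (counted together
    with its reverse complement) occurs exactly once genome-wide over both
    strands. Contigs shorter than ``k`` get an empty mask.
    """
    census: dict[str, int] = {}
    for seq in genome.values():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            census[km] = census.get(km, 0) + 1
    masks: dict[str, np.ndarray] = {}
    for name, seq in genome.items():
        n = len(seq) - k + 1
        if n <= 0:
            masks[name] = np.zeros(0, dtype=bool)
            continue
        mask = np.empty(n, dtype=bool)
        for i in range(n):
            km = seq[i : i + k]
            mask[i] = census[km] + census.get(revcomp(km), 0) == 1
        masks[name] = mask
    return masks


def define_tiles(
    genome: Mapping[str, str],
    mask: Mapping[str, np.ndarray],
    size: int = TILE_SIZE,
    min_frac: float = MIN_UNIQUE_FRAC,
) -> pd.DataFrame:
    """Fixed-grid tiles kept when at least ``min_frac`` of positions are unique.

    The grid starts at position 0 of each contig; trailing partial tiles are
    discarded; the threshold is inclusive. Positions without a defined k-mer
    (contig tail) count as non-unique.
    """
    rows = []
    for name, seq in genome.items():
        m = mask.get(name, np.zeros(0, dtype=bool))
        for start in range(0, len(seq) - size + 1, size):
            window = m[start : start + size]
            frac = float(window.sum()) / size
            if frac >= min_frac:
                rows.append((name, start, start + size, frac))
    return pd.DataFrame(rows, columns=TILE_COLUMNS)


def unique_pirna_total(alignments: pd.DataFrame) -> int:
    """Total count of genome-unique piRNA mappers in a library (cpm basis)."""
    sel = alignments[alignments["is_unique"] & alignments["is_pirna"]]
    return int(sel["count"].sum())


def tile_counts(
    alignments: pd.DataFrame,
    tiles: pd.DataFrame,
    size: int = TILE_SIZE,
) -> pd.DataFrame:
    """Per-tile, per-strand cpm of genome-unique piRNA reads.

    A read is assigned to the tile containing its 5' end. cpm normalises to
    the library's total genome-unique piRNA mappers (whether or not they
    land in a kept tile); a library with none raises.
    """
    total = unique_pirna_total(alignments)
    if total == 0:
        raise ValueError("no genome-unique piRNA mappers: cpm undefined")
    sel = alignments[alignments["is_unique"] & alignments["is_pirna"]]
    out = tiles.copy()
    for strand, col in (("+", "cpm_plus"), ("-", "cpm_minus")):
        sub = sel[sel["strand"] == strand]
        grouped = (
            sub.assign(tile_start=(sub["five_prime"] // size) * size)
            .groupby(["contig", "tile_start"])["count"]
            .sum()
        )
        keys = pd.MultiIndex.from_arrays([out["contig"], out["start"]])
        counts = grouped.reindex(keys, fill_value=0).to_numpy(dtype=float)
        out[col] = counts * 1e6 / total
    out["cpm_total"] = out["cpm_plus"] + out["cpm_minus"]
    return out


def enrichment(
    ovary_tiles: pd.DataFrame,
    embryo_tiles: pd.DataFrame,
    ovary_total: int,
    embryo_total: int,
) -> pd.DataFrame:
    """Per-tile ovary/embryo fold change with a single-read pseudocount.

    fold = (ov_cpm + eps) / (em_cpm + eps) where eps is the cpm a single
    read contributes in the smaller library, giving finite folds for tiles
    that are empty in the embryo.
    """
    if not (ovary_tiles[["contig", "start"]].values == embryo_tiles[["contig", "start"]].values).all():
        raise ValueError("ovary and embryo tile sets differ")
    eps = 1e6 / min(ovary_total, embryo_total)
    out = ovary_tiles.rename(
        columns={"cpm_plus": "ov_cpm_plus", "cpm_minus": "ov_cpm_minus", "cpm_total": "ov_cpm"}
    ).copy()
    out["em_cpm_plus"] = embryo_tiles["cpm_plus"].to_numpy()
    out["em_cpm_minus"] = embryo_tiles["cpm_minus"].to_numpy()
    out["em_cpm"] = embryo_tiles["cpm_total"].to_numpy()
    out["fold"] = (out["ov_cpm"] + eps) / (out["em_cpm"] + eps)
    return out


@dataclass
class ClusterCall:
    """A merged run of enriched tiles called as a somatic-cluster candidate."""

    contig: str
    start: int
    end: int
    n_tiles: int
    ov_cpm: float
    fold: float
    strand_ratio: float  # minus-strand cpm over plus-strand cpm


def call_clusters(
    enriched: pd.DataFrame,
    fold_min: float = 10.0,
    min_ov_cpm: float = 5.0,
    max_gap_tiles: int = 2,
    min_tiles: int = 2,
    size: int = TILE_SIZE,
) -> list[ClusterCall]:
    """Merge enriched tiles into cluster calls.

    Tiles passing both thresholds are merged along a contig when separated
    by at most ``max_gap_tiles`` grid tiles; runs of fewer than ``min_tiles``
    passing tiles are discarded. The strand ratio is computed from the
    member tiles' ovary cpm.
    """
    passing = enriched[(enriched["fold"] >= fold_min) & (enriched["ov_cpm"] >= min_ov_cpm)]
    calls: list[ClusterCall] = []
    for contig, group in passing.groupby("contig", sort=True):
        group = group.sort_values("start")
        run: list[pd.Series] = []
        for _, row in group.iterrows():
            if run and (row["start"] - run[-1]["start"]) // size - 1 > max_gap_tiles:
                calls.extend(_emit(contig, run, min_tiles, size))
                run = []
            run.append(row)
        calls.extend(_emit(contig, run, min_tiles, size))
    return calls


def _emit(contig: str, run: list[pd.Series], min_tiles: int, size: int) -> list[ClusterCall]:
    if len(run) < min_tiles:
        return []
    plus = sum(r["ov_cpm_plus"] for r in run)
    minus = sum(r["ov_cpm_minus"] for r in run)
    ov = sum(r["ov_cpm"] for r in run)
    em = sum(r["em_cpm"] for r in run)
    fold = min(r["fold"] for r in run) if em == 0 else ov / max(em, 1e-300)
    return [
        ClusterCall(
            contig=contig,
            start=int(run[0]["start"]),
            end=int(run[-1]["end"]),
            n_tiles=len(run),
            ov_cpm=float(ov),
            fold=float(fold),
            strand_ratio=float(minus / plus) if plus > 0 else float("inf"),
        )
    ]


def clusters_to_frame(calls: list[ClusterCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def cluster_fraction(alignments: pd.DataFrame, clusters: list[ClusterCall]) -> float:
    """Weighted fraction of genome-mapping piRNAs whose 5' end lies in a cluster.

    Multimappers contribute their 1/n weight per placement, so a read split
    between inside and outside contributes fractionally.
    """
    pir = alignments[alignments["is_pirna"]]
    total = float((pir["weight"] * pir["count"]).sum())
    if total == 0:
        return 0.0
    inside = np.zeros(len(pir), dtype=bool)
    for c in clusters:
        inside |= (
            (pir["contig"] == c.contig)
            & (pir["five_prime"] >= c.start)
            & (pir["five_prime"] < c.end)
        ).to_numpy()
    return float((pir["weight"] * pir["count"])[inside].sum() / total)


def mask_to_bed(mask: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Export unique runs of the mappability mask as BED intervals."""
    rows = []
    for contig in sorted(mask):
        m = mask[contig]
        if m.size == 0:
            continue
        padded = np.concatenate([[False], m, [False]])
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(edges[::2], edges[1::2]):
            rows.append((contig, int(s), int(e), "unique", 0, "+"))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score", "strand"])
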