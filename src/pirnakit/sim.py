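"""Seeded simulator of ovarian-somatic piRNA libraries with ground truth.

The generator emulates the statistical structure of paired ovary/embryo
small-RNA sequencing experiments used to discover somatic piRNA clusters:

* a random genome carrying a uni-stranded somatic cluster with planted
  transposon fragments, plus a shared germline cluster that both libraries
  sample;
* somatic-cluster reads produced under one of three biogenesis mechanisms —
  Zucchini-style **phasing** (head-to-tail trails with a downstream-uridine
  cleavage bias), **ping-pong** (trigger/responder pairs whose 5' ends
  overlap by exactly 10 nt on opposite strands, with a 1U/10A bias), and
  **slicing-triggered phasing** (triggers from a distinct locus that place
  responder 5' ends on the cluster, each followed by a phased trail);
* library wrapping — 4-nt random UMIs on both sides of the insert plus a 3'
  adapter — into 4-line FASTQ records, with a per-read truth table.

Every operation is deterministic under ``SimConfig.seed``: the same config
yields byte-identical FASTA/FASTQ/TSV outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from ._seq import discrete_truncnorm_pmf, revcomp

MIN_PIRNA_LEN = 23
MAX_PIRNA_LEN = 35

MECHANISMS = ("phasing", "pingpong", "sliced_phasing")
ROLES = ("initiator", "phased_follower", "trigger", "responder", "contaminant", "germline")

TRUTH_COLUMNS = [
    "read_id", "mechanism", "role", "contig", "start", "end", "strand",
    "library", "sequence", "u_fallback",
]


class SimulationError(ValueError):
    """Raised when a simulator precondition is violated."""


@dataclass
class Fragment:
    """A transposon fragment to plant in the genome.

    ``strand='-'`` means the genome carries the reverse complement of the
    fragment's consensus sequence across ``[start, end)``.
    """

    start: int
    end: int
    strand: str = "-"
    label: str = "gypsy"


def _default_fragments() -> list[Fragment]:
    # three antisense gypsy fragments inside the default cluster span
    return [
        Fragment(10500, 11300, "-", "gypsy"),
        Fragment(12000, 12900, "-", "gypsy"),
        Fragment(13600, 14300, "-", "LINE"),
    ]


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults are the study conditions.

    Probabilities must lie in [0, 1]; read lengths are clipped to
    [23, 35] nt; the cluster must fit in the genome with at least a
    ten-fold margin.
    """

    seed: int = 0
    genome_length: int = 60_000
    contig: str = "sim1"
    cluster_interval: tuple[str, int, int] = ("sim1", 10_000, 15_000)
    transposon_fragments: list[Fragment] = field(default_factory=_default_fragments)
    mechanism: str = "phasing"
    u_bias: float = 0.85          # P(cleavage site immediately followed by U)
    phase_prob: float = 0.7       # P(next 5' end = previous 3' end + 1)
    n_reads: int = 20_000
    len_mean_plus: float = 27.4   # plus-strand mean length, nt
    len_mean_minus: float = 25.3  # minus-strand mean length, nt
    len_sd: float = 1.5
    first_u_bias: float = 0.90    # P(responder 5' base is U)
    depth_ovary: int = 20_000
    depth_embryo: int = 20_000
    somatic_fraction: float = 0.3
    contam_rate: float = 0.05
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    umi_len: int = 4
    n_trigger_anchors: int = 40   # distinct trigger/responder species (sliced mode)
    gap_window: int = 50          # nt window for 5' restarts after a broken trail
    walk_restart_prob: float = 0.3  # P(processing run detaches at a break and re-enters elsewhere)
    trigger_locus_length: int = 1_000

    def validate(self) -> None:
        for name in ("u_bias", "phase_prob", "first_u_bias", "somatic_fraction", "contam_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.mechanism not in MECHANISMS:
            raise SimulationError(f"unknown mechanism {self.mechanism!r}")
        contig, cs, ce = self.cluster_interval
        if not (0 <= cs < ce <= self.genome_length):
            raise SimulationError("cluster_interval outside the genome")
        if self.genome_length < 10 * (ce - cs):
            raise SimulationError(
                f"genome_length={self.genome_length} must be >= 10x the cluster length {ce - cs}"
            )
        frags = sorted(self.transposon_fragments, key=lambda f: f.start)
        for a, b in zip(frags, frags[1:]):
            if a.end > b.start:
                raise SimulationError(f"overlapping fragments at {a.start}-{a.end} and {b.start}-{b.end}")
        for f in frags:
            if not (0 <= f.start < f.end <= self.genome_length):
                raise SimulationError(f"fragment {f.start}-{f.end} outside the genome")
            if f.strand not in "+-":
                raise SimulationError(f"fragment strand {f.strand!r}")


@dataclass
class SimGenome:
    """Genome, annotations and companion references produced for one config."""

    config: SimConfig
    contigs: dict[str, str]
    annotations: pd.DataFrame        # BED6-style: contig start end name score strand
    cluster: tuple[str, int, int]
    germline_interval: tuple[str, int, int]
    trigger_interval: tuple[str, int, int] | None
    contaminants: dict[str, str]
    fragment_seqs: dict[str, str]    # consensus sequence per planted fragment

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.contigs, outdir / "genome.fa")
        io.write_fasta(self.contaminants, outdir / "contaminants.fa")
        io.write_bed(self.annotations, outdir / "annotations.bed")
        cluster_df = pd.DataFrame(
            [[self.cluster[0], self.cluster[1], self.cluster[2], "somatic_cluster", 0, "+"]],
            columns=io.BED6_COLUMNS,
        )
        io.write_bed(cluster_df, outdir / "cluster.bed")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def generate_genome(config: SimConfig) -> SimGenome:
    """Build the seeded genome, annotations and contaminant references.

    The somatic cluster occupies ``config.cluster_interval``; a germline
    cluster of equal size is placed in the last third of the contig; in
    ``sliced_phasing`` mode a trigger locus carrying the reverse complement
    of a cluster sub-segment is planted between the two.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contig, cs, ce = config.cluster_interval
    genome = list(_random_seq(rng, config.genome_length))

    fragment_seqs: dict[str, str] = {}
    ann_rows = []
    for i, frag in enumerate(config.transposon_fragments):
        name = f"{frag.label}_{i}"
        consensus = _random_seq(rng, frag.end - frag.start)
        fragment_seqs[name] = consensus
        placed = consensus if frag.strand == "+" else revcomp(consensus)
        genome[frag.start : frag.end] = list(placed)
        ann_rows.append([contig, frag.start, frag.end, name, 0, frag.strand])

    clen = ce - cs
    gl_start = config.genome_length - clen - 1_000
    if gl_start < ce + 1_000:
        raise SimulationError("no room for a germline cluster after the somatic cluster")
    gl_start -= gl_start % 500  # tile-grid aligned
    germline = (contig, gl_start, gl_start + clen)
    ann_rows.append([contig, gl_start, gl_start + clen, "germline_cluster", 0, "+"])

    trigger = None
    if config.mechanism == "sliced_phasing":
        tlen = min(config.trigger_locus_length, clen)
        ts = (ce + gl_start - tlen) // 2
        if ts < ce + 500 or ts + tlen > gl_start - 500:
            raise SimulationError("no room for a trigger locus")
        genome[ts : ts + tlen] = list(revcomp("".join(genome[cs : cs + tlen])))
        trigger = (contig, ts, ts + tlen)
        ann_rows.append([contig, ts, ts + tlen, "trigger_locus", 0, "+"])

    ann_rows.append([contig, cs, ce, "somatic_cluster", 0, "+"])
    annotations = pd.DataFrame(ann_rows, columns=io.BED6_COLUMNS).sort_values(
        ["contig", "start"], kind="stable", ignore_index=True
    )
    contaminants = {
        "rRNA_toy": _random_seq(rng, 2_000),
        "tRNA_toy": _random_seq(rng, 500),
        "snRNA_toy": _random_seq(rng, 300),
    }
    return SimGenome(
        config=config,
        contigs={contig: "".join(genome)},
        annotations=annotations,
        cluster=(contig, cs, ce),
        germline_interval=germline,
        trigger_interval=trigger,
        contaminants=contaminants,
        fragment_seqs=fragment_seqs,
    )


def _length_sampler(mean: float, sd: float):
    lengths, pmf = discrete_truncnorm_pmf(mean, sd, MIN_PIRNA_LEN, MAX_PIRNA_LEN)
    def draw(rng: np.random.Generator, allowed: np.ndarray | None = None) -> int:
        if allowed is None:
            return int(rng.choice(lengths, p=pmf))
        w = pmf[np.searchsorted(lengths, allowed)]
        return int(rng.choice(allowed, p=w / w.sum()))
    return draw


def _truth_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    df["u_fallback"] = df["u_fallback"].astype(bool)
    return df


def _choose_three_prime(
    rng: np.random.Generator, seq: str, pos: int, limit: int, u_bias: float, draw_len,
) -> tuple[int, bool]:
    """Pick a read length for a read starting at ``pos``.

    With probability ``u_bias`` the 3' end is chosen among lengths whose next
    genomic base is T (U in the transcript); otherwise among the rest. When
    the wanted set is empty the choice falls back to all candidates and the
    read is flagged.
    """
    cand = np.array([l for l in range(MIN_PIRNA_LEN, MAX_PIRNA_LEN + 1) if pos + l < limit])
    if cand.size == 0:
        raise SimulationError("no room for a read at the end of the transcript")
    is_u = np.array([seq[pos + l] == "T" for l in cand])
    want_u = rng.random() < u_bias
    subset = cand[is_u] if want_u else cand[~is_u]
    if subset.size == 0:
        return draw_len(rng, cand), True
    return draw_len(rng, subset), False


def simulate_phasing(
    config: SimConfig,
    genome: SimGenome,
    *,
    n_reads: int | None = None,
    rng: np.random.Generator | None = None,
    library: str = "ovary",
    id_prefix: str = "ph",
) -> pd.DataFrame:
    """Head-to-tail phased piRNA production from the plus strand of the cluster.

    Trails walk the cluster transcript: with probability ``phase_prob`` the
    next read's 5' end is the base right after the previous 3' end; on a
    break the next 5' end jumps 2..``gap_window``+1 nt downstream. 3' ends
    prefer positions immediately followed by uridine (``u_bias``).
    """
    if config.mechanism != "phasing":
        raise SimulationError("config.mechanism must be 'phasing'")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_reads if n_reads is None else n_reads
    contig, cs, ce = genome.cluster
    seq = genome.contigs[contig]
    draw_len = _length_sampler(config.len_mean_plus, config.len_sd)
    margin = MAX_PIRNA_LEN + 1

    rows: list[dict] = []
    pos = -1
    role = "initiator"
    while len(rows) < n:
        if pos < 0 or pos > ce - margin:
            pos = int(cs + rng.integers(0, ce - cs - margin))
            role = "initiator"
        length, fallback = _choose_three_prime(rng, seq, pos, ce, config.u_bias, draw_len)
        rows.append(
            dict(
                read_id=f"{id_prefix}{len(rows):06d}", mechanism="phasing", role=role,
                contig=contig, start=pos, end=pos + length, strand="+",
                library=library, sequence=seq[pos : pos + length], u_fallback=fallback,
            )
        )
        if rng.random() < config.phase_prob:
            pos, role = pos + length, "phased_follower"
        elif rng.random() < config.walk_restart_prob:
            pos = -1  # run detaches; next read re-enters the cluster uniformly
        else:
            pos = pos + length + int(rng.integers(1, config.gap_window + 1))
            role = "initiator"
    return _truth_frame(rows)


def simulate_pingpong(
    config: SimConfig,
    genome: SimGenome,
    *,
    n_reads: int | None = None,
    rng: np.random.Generator | None = None,
    library: str = "ovary",
    id_prefix: str = "pp",
) -> pd.DataFrame:
    """Trigger/responder pairs with the canonical 10-nt 5'-5' overlap.

    Responders sit on the plus strand (5' base U with probability
    ``first_u_bias``); triggers on the minus strand with their 5' end 9 nt
    downstream, so position 10 of a trigger is the complement of its
    responder's first base. ``n_reads`` counts reads, i.e. ``n_reads // 2``
    pairs are drawn.
    """
    if config.mechanism != "pingpong":
        raise SimulationError("config.mechanism must be 'pingpong'")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_reads if n_reads is None else n_reads
    contig, cs, ce = genome.cluster
    seq = genome.contigs[contig]
    lo, hi = cs + MAX_PIRNA_LEN - 9, ce - MAX_PIRNA_LEN - 1
    if hi <= lo:
        raise SimulationError("cluster too short for a 10-nt overlapped pair")
    sites = np.arange(lo, hi)
    bases = np.frombuffer(seq.encode(), dtype="S1")[sites]
    t_sites, nt_sites = sites[bases == b"T"], sites[bases != b"T"]
    if t_sites.size == 0 or nt_sites.size == 0:
        raise SimulationError("cluster lacks usable responder start sites")
    draw_plus = _length_sampler(config.len_mean_plus, config.len_sd)
    draw_minus = _length_sampler(config.len_mean_minus, config.len_sd)

    rows: list[dict] = []
    for i in range(n // 2):
        pool = t_sites if rng.random() < config.first_u_bias else nt_sites
        g = int(pool[rng.integers(0, pool.size)])
        lp, lm = draw_plus(rng), draw_minus(rng)
        rows.append(
            dict(
                read_id=f"{id_prefix}{2 * i:06d}", mechanism="pingpong", role="responder",
                contig=contig, start=g, end=g + lp, strand="+",
                library=library, sequence=seq[g : g + lp], u_fallback=False,
            )
        )
        rows.append(
            dict(
                read_id=f"{id_prefix}{2 * i + 1:06d}", mechanism="pingpong", role="trigger",
                contig=contig, start=g + 10 - lm, end=g + 10, strand="-",
                library=library, sequence=revcomp(seq[g + 10 - lm : g + 10]), u_fallback=False,
            )
        )
    return _truth_frame(rows)


def simulate_sliced_phasing(
    config: SimConfig,
    genome: SimGenome,
    *,
    n_reads: int | None = None,
    rng: np.random.Generator | None = None,
    library: str = "ovary",
    id_prefix: str = "sl",
) -> pd.DataFrame:
    """Slicing-triggered phasing: trigger piRNAs from a distinct locus.

    Each event emits a trigger read from the trigger locus, a responder on
    the cluster whose g1-g9 equals the reverse complement of the trigger's
    g2-g10, and a phased trail downstream of the responder. Events reuse a
    fixed pool of anchor sites, mimicking the small number of dominant
    trigger/responder piRNA species seen in real libraries.
    """
    if config.mechanism != "sliced_phasing":
        raise SimulationError("config.mechanism must be 'sliced_phasing'")
    if genome.trigger_interval is None:
        raise SimulationError("genome has no trigger locus complementary to the cluster")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_reads if n_reads is None else n_reads
    contig, cs, ce = genome.cluster
    _, ts, te = genome.trigger_interval
    tlen = te - ts
    seq = genome.contigs[contig]
    draw_plus = _length_sampler(config.len_mean_plus, config.len_sd)
    draw_minus = _length_sampler(config.len_mean_minus, config.len_sd)

    # responder anchors r map to trigger starts p = ts + tlen - 10 - (r - cs)
    r_lo, r_hi = cs + MAX_PIRNA_LEN - 10, cs + tlen - 10
    valid = np.arange(r_lo, r_hi)
    if valid.size < config.n_trigger_anchors:
        raise SimulationError("trigger locus too short for the requested anchor pool")
    anchors = np.sort(rng.choice(valid, size=config.n_trigger_anchors, replace=False))

    rows: list[dict] = []
    while len(rows) < n:
        r = int(anchors[rng.integers(0, anchors.size)])
        p = ts + tlen - 10 - (r - cs)
        lt = draw_minus(rng)
        rows.append(
            dict(
                read_id=f"{id_prefix}{len(rows):06d}", mechanism="sliced_phasing", role="trigger",
                contig=contig, start=p, end=p + lt, strand="+",
                library=library, sequence=seq[p : p + lt], u_fallback=False,
            )
        )
        # responder plus phased trail on the cluster
        pos, role = r, "responder"
        while len(rows) < n:
            length, fallback = _choose_three_prime(rng, seq, pos, ce, config.u_bias, draw_plus)
            rows.append(
                dict(
                    read_id=f"{id_prefix}{len(rows):06d}", mechanism="sliced_phasing", role=role,
                    contig=contig, start=pos, end=pos + length, strand="+",
                    library=library, sequence=seq[pos : pos + length], u_fallback=fallback,
                )
            )
            if rng.random() >= config.phase_prob or pos + length > ce - MAX_PIRNA_LEN - 1:
                break
            pos, role = pos + length, "phased_follower"
    return _truth_frame(rows)


_MECHANISM_SIMS = {
    "phasing": simulate_phasing,
    "pingpong": simulate_pingpong,
    "sliced_phasing": simulate_sliced_phasing,
}


def _uniform_reads(
    rng: np.random.Generator,
    genome: SimGenome,
    interval: tuple[str, int, int],
    n: int,
    config: SimConfig,
    role: str,
    library: str,
    id_prefix: str,
) -> list[dict]:
    contig, lo, hi = interval
    seq = genome.contigs[contig]
    draw_plus = _length_sampler(config.len_mean_plus, config.len_sd)
    draw_minus = _length_sampler(config.len_mean_minus, config.len_sd)
    rows = []
    for i in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        length = (draw_plus if strand == "+" else draw_minus)(rng)
        start = int(lo + rng.integers(0, hi - lo - length))
        insert = seq[start : start + length]
        rows.append(
            dict(
                read_id=f"{id_prefix}{i:06d}", mechanism="none", role=role,
                contig=contig, start=start, end=start + length, strand=strand,
                library=library, sequence=insert if strand == "+" else revcomp(insert),
                u_fallback=False,
            )
        )
    return rows


def _contaminant_reads(
    rng: np.random.Generator, genome: SimGenome, n: int, config: SimConfig,
    library: str, id_prefix: str,
) -> list[dict]:
    names = sorted(genome.contaminants)
    draw_len = _length_sampler((config.len_mean_plus + config.len_mean_minus) / 2, config.len_sd)
    rows = []
    for i in range(n):
        name = names[rng.integers(0, len(names))]
        ref = genome.contaminants[name]
        length = draw_len(rng)
        start = int(rng.integers(0, len(ref) - length))
        rows.append(
            dict(
                read_id=f"{id_prefix}{i:06d}", mechanism="none", role="contaminant",
                contig=name, start=start, end=start + length, strand="+",
                library=library, sequence=ref[start : start + length], u_fallback=False,
            )
        )
    return rows


@dataclass
class SimLibraries:
    """Ovary/embryo FASTQ records plus the combined truth table."""

    ovary: list[tuple[str, str]]   # (read_id, wrapped sequence)
    embryo: list[tuple[str, str]]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fastq(self.ovary, outdir / "ovary.fastq")
        io.write_fastq(self.embryo, outdir / "embryo.fastq")
        io.write_tsv(self.truth, outdir / "truth.tsv")


def simulate_libraries(config: SimConfig, genome: SimGenome) -> SimLibraries:
    """Compose ovary and embryo libraries and wrap inserts for FASTQ.

    Ovary = ``somatic_fraction`` mechanism-derived cluster reads + shared
    germline reads + contaminants; embryo = germline + contaminants only.
    Each insert is wrapped as UMI + insert + UMI + adapter.
    """
    config.validate()
    if config.depth_ovary <= 0 or config.depth_embryo <= 0:
        raise SimulationError("library depths must be positive")
    if config.somatic_fraction == 0:
        warnings.warn("somatic_fraction=0: the declared cluster will be undetectable")
    rng = np.random.default_rng(config.seed)

    n_som = int(round(config.somatic_fraction * config.depth_ovary))
    som_rows: list[dict] = []
    if n_som > 0:
        sim = _MECHANISM_SIMS[config.mechanism]
        som_rows = sim(config, genome, n_reads=n_som, rng=rng, library="ovary",
                       id_prefix="ov_som").to_dict("records")
    n_contam_ov = int(round(config.contam_rate * config.depth_ovary))
    n_germ_ov = config.depth_ovary - len(som_rows) - n_contam_ov
    n_contam_em = int(round(config.contam_rate * config.depth_embryo))
    n_germ_em = config.depth_embryo - n_contam_em

    rows = list(som_rows)
    rows += _uniform_reads(rng, genome, genome.germline_interval, n_germ_ov, config,
                           "germline", "ovary", "ov_gl")
    rows += _contaminant_reads(rng, genome, n_contam_ov, config, "ovary", "ov_ct")
    rows += _uniform_reads(rng, genome, genome.germline_interval, n_germ_em, config,
                           "germline", "embryo", "em_gl")
    rows += _contaminant_reads(rng, genome, n_contam_em, config, "embryo", "em_ct")
    truth = _truth_frame(rows)

    def wrap(insert: str) -> str:
        umi5 = _random_seq(rng, config.umi_len)
        umi3 = _random_seq(rng, config.umi_len)
        return umi5 + insert + umi3 + config.adapter

    ovary = [(r["read_id"], wrap(r["sequence"])) for r in rows if r["library"] == "ovary"]
    embryo = [(r["read_id"], wrap(r["sequence"])) for r in rows if r["library"] == "embryo"]
    return SimLibraries(ovary=ovary, embryo=embryo, truth=truth)


def truth_alignments(truth: pd.DataFrame, genome_mapping_only: bool = True) -> pd.DataFrame:
    """Turn a truth table into an alignment frame with unit weights.

    Useful for testing downstream statistics against the generator's own
    coordinates without running the mapper. Contaminant rows are dropped by
    default because they do not map to the genome.
    """
    df = truth.copy()
    if genome_mapping_only:
        df = df[df["role"] != "contaminant"].copy()
    df["mismatches"] = 0
    df["n_instances"] = 1
    df["weight"] = 1.0
    df["count"] = 1
    df["length"] = df["end"] - df["start"]
    df["five_prime"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    df["three_prime"] = np.where(df["strand"] == "+", df["end"] - 1, df["start"])
    df["is_unique"] = True
    df["is_pirna"] = df["length"] >= MIN_PIRNA_LEN
    return df.reset_index(drop=True)
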