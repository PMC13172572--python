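"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA via Biopython, FASTQ as 4-line records, BED6 (0-based half-open),
minimal SAM (import through pysam, export as text), and TSV tables through
pandas. All writers emit records in a deterministic order so identical
inputs give byte-identical files.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from ._seq import revcomp

BED6_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file as an ordered ``{name: uppercase sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterable[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from a 4-line-record FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip().upper()
            fh.readline()  # '+'
            fh.readline()  # qualities
            yield header.strip().lstrip("@").split()[0], seq


def write_fastq(records: Iterable[tuple[str, str]], path: str | os.PathLike, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sam(alignments: pd.DataFrame, contig_lengths: Mapping[str, int], path: str | os.PathLike) -> None:
    """Export an alignment table as minimal single-end SAM.

    One line per placement; SEQ is written in reference orientation as SAM
    requires, NM carries the mismatch count and the 1/n multimapper weight
    travels in the XW tag.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in contig_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for i, row in enumerate(alignments.itertuples(index=False)):
            flag = 16 if row.strand == "-" else 0
            seq = revcomp(row.sequence) if row.strand == "-" else row.sequence
            fh.write(
                f"read{i}\t{flag}\t{row.contig}\t{row.start + 1}\t255\t{len(row.sequence)}M"
                f"\t*\t0\t0\t{seq}\t{'I' * len(row.sequence)}"
                f"\tNM:i:{row.mismatches}\tXW:f:{row.weight:.6g}\tXC:i:{row.count}\n"
            )


def read_sam(path: str | os.PathLike) -> pd.DataFrame:
    """Import pre-computed alignments from SAM for users with real mappings.

    Multiplicity is re-derived per read name so 1/n weights do not depend on
    the upstream aligner having written them.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            seq = rec.query_sequence or ""
            if rec.is_reverse:
                seq = revcomp(seq)
            rows.append(
                {
                    "sequence": seq,
                    "contig": rec.reference_name,
                    "start": rec.reference_start,
                    "end": rec.reference_end,
                    "strand": "-" if rec.is_reverse else "+",
                    "mismatches": rec.get_tag("NM") if rec.has_tag("NM") else 0,
                    "count": rec.get_tag("XC") if rec.has_tag("XC") else 1,
                    "name": rec.query_name,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    n_inst = df.groupby("name")["name"].transform("size")
    df["n_instances"] = n_inst
    df["weight"] = 1.0 / n_inst
    return df.drop(columns="name")
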