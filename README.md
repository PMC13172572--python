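# pirnakit

Discovery of **ovarian somatic piRNA clusters** from paired ovary/embryo
small-RNA sequencing, and classification of the dominant **piRNA biogenesis
mechanism** — phasing, ping-pong, or slicing-triggered phasing — from the
linkage signatures those mechanisms leave in the data. A seeded generative
simulator produces libraries with per-read ground truth, so the whole
pipeline is testable on a laptop with no downloads.

## The science

PIWI-interacting RNAs (piRNAs, 23–35 nt) silence transposons such as the
*envelope*-carrying *gypsy* LTR retrotransposons that invade the germline
from the ovarian somatic niche. Because somatic piRNAs are not deposited in
early embryos, genomic regions much more piRNA-productive in ovaries than
in embryos mark **somatic piRNA clusters**: genome-unique piRNA reads are
counted in uniquely-mappable 0.5-kb tiles (≥85% of positions carrying a
genome-unique 25-mer), normalised to counts per million genome-unique
piRNA mappers (cpm), and tiles with ovary/embryo fold ≥ 10 are merged into
cluster calls.

Three statistics classify how the cluster's piRNAs are made:

* **Phasing** (Zucchini/MitoPLD): head-to-tail production puts uridine
  immediately after piRNA 3' ends and links 3' ends to the next 5' end.
  With a(t), b(p) the weighted 3'/5'-end abundances, the profile over
  distances d ∈ [−9, +10] is Σₜ a(t)·b(t+d); the z-score at d = +1 is the
  phasing linkage.
* **Ping-pong**: reciprocal slicing yields plus/minus pairs whose 5' ends
  overlap by exactly 10 nt, with 1U/10A nucleotide biases. The overlap
  profile is score(s) = Σᵢ a₊(i)·a₋(i+s−1), s ∈ 1..20; z at s = 10.
* **In-trans ping-pong**: trigger piRNAs from one locus slice precursors at
  another, pairing through g2–g10 complementarity. Reads are reduced to
  9-mer tables (g1–g9, last 9 nt, reverse-complemented g2–g10; each summing
  to 1000); linkage = ⟨g1g9, g2g10revComp⟩ with ⟨last9, g2g10revComp⟩ as
  background.

z-scores follow one convention throughout: deviation of the focal
frequency from the window mean, over the window's population standard
deviation (focal included; z = 0 for a flat window).

See `docs/methods.md` for models, parameter defaults and numerical choices.

## Worked example

Simulate a paired ovary/embryo experiment (phasing-mode somatic cluster at
sim1:10,000–15,000, 20,000 reads per library), run the full pipeline, and
ask what it finds:

```python
import pirnakit as pk
from pirnakit import tiles as tl
from pirnakit.reads import process_fastq

cfg = pk.SimConfig(seed=1)
genome = pk.generate_genome(cfg)
libs = pk.simulate_libraries(cfg, genome)

aln = {}
for lib, records in (("ovary", libs.ovary), ("embryo", libs.embryo)):
    reads = process_fastq(records, cfg.adapter, cfg.umi_len,
                          contaminant_refs=genome.contaminants)
    aln[lib] = pk.map_reads(reads, genome.contigs)

mask = pk.kmer_uniqueness(genome.contigs)
tiles = pk.define_tiles(genome.contigs, mask)
enr = pk.enrichment(pk.tile_counts(aln["ovary"], tiles),
                    pk.tile_counts(aln["embryo"], tiles),
                    tl.unique_pirna_total(aln["ovary"]),
                    tl.unique_pirna_total(aln["embryo"]))
calls = pk.call_clusters(enr)

c = calls[0]
print(f"cluster {c.contig}:{c.start}-{c.end}  tiles={c.n_tiles} "
      f"fold={c.fold:.0f}  strand_ratio={c.strand_ratio:.3f}")

pir = aln["ovary"][aln["ovary"]["is_pirna"]]
cluster_reads = pir[(pir.five_prime >= c.start) & (pir.five_prime < c.end)]
prof = pk.phasing_distance_profile(cluster_reads)
down = pk.end_nucleotide_profile(cluster_reads, genome.contigs,
                                 "three_prime_downstream")
print(f"phasing: mode {prof.mode:+d}, z(+1) = {prof.z:.2f}")
print(f"downstream U = {down.base_frequencies('T')[5]:.3f}")
```

Output:

```
cluster sim1:10000-15000  tiles=10 fold=381  strand_ratio=0.000
phasing: mode +1, z(+1) = 4.34
downstream U = 0.827
```

The truth cluster is recovered at exact tile boundaries with 381-fold
ovary enrichment; a strand ratio of 0 says the cluster is uni-stranded.
The 3'→5' distance profile peaks at +1 with z = 4.3 and 83% of 3' ends are
immediately followed by uridine (the configured cleavage bias is 0.85) —
the head-to-tail phasing signature, as simulated. A ping-pong-mode
simulation instead drives the 10-nt 5'–5' overlap z-score above 3 with
1U/10A biases and leaves z(+1) below 2.

The same stages are available as a CLI
(`pirnakit simulate | process | map | tiles | clusters | quantify |
signatures | report`), exchanging plain-text FASTA/FASTQ/BED/TSV/JSON
files; see `pirnakit --help`.

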