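"""Biogenesis-signature statistics: z-scores, profiles, 9-mer linkage."""

import numpy as np
import pandas as pd
import pytest

import pirnakit as pk
from pirnakit import signatures as sg
from pirnakit._seq import revcomp
from tests.test_tiles import make_alignments

PIRNA_A, PIRNA_B = sg.AEDES_PINGPONG_PAIR


class TestZScore:
    def test_flat_profile_zero(self):
        assert pk.z_score([0.2] * 10, 4) == 0.0

    def test_direct_arithmetic(self):
        freqs = np.array([0.01] * 5 + [0.9] + [0.01] * 5)
        expected = (0.9 - freqs.mean()) / freqs.std()
        assert pk.z_score(freqs, 5) == pytest.approx(expected)

    def test_permuting_nonfocal_positions_invariant(self, rng):
        freqs = rng.random(11)
        z0 = pk.z_score(freqs, 5)
        for _ in range(5):
            rest = np.delete(freqs, 5)
            rng.shuffle(rest)
            permuted = np.insert(rest, 5, freqs[5])
            assert pk.z_score(permuted, 5) == pytest.approx(z0)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            pk.z_score([0.5, 0.5], 0)


class TestEndNucleotideProfile:
    def test_all_reads_starting_with_t(self):
        genome = {"chrT": "GGGG" + "TACGTACGTACGTACGTACGTACG" + "GGGG"}
        aln = make_alignments([("chrT", 4, 28, "+", 1, 1)] * 3)
        prof = pk.end_nucleotide_profile(aln, genome, "five_prime_pos1")
        i0 = prof.positions.tolist().index(0)
        assert prof.base_frequencies("T")[i0] == 1.0

    def test_minus_strand_reads_complemented(self):
        # minus-strand read with 5' base A on the minus strand = T on plus
        genome = {"chrT": "C" * 30 + "T" + "C" * 30}
        aln = make_alignments([("chrT", 5, 31, "-", 1, 1)])
        prof = pk.end_nucleotide_profile(aln, genome, "five_prime_pos1")
        i0 = prof.positions.tolist().index(0)
        assert prof.base_frequencies("A")[i0] == 1.0

    def test_null_genome_flat_frequencies(self, rng):
        genome = {"chrT": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4000)])}
        starts = rng.integers(10, 3900, size=800)
        aln = make_alignments([("chrT", int(s), int(s) + 26, "+", 1, 1) for s in starts])
        prof = pk.end_nucleotide_profile(aln, genome, "three_prime_downstream")
        assert abs(prof.z) < 2
        assert np.allclose(prof.frequencies.sum(axis=1), 1.0)

    def test_u_bias_recovered_from_phasing_sim(self, phasing_sim):
        cfg, genome, truth = phasing_sim
        aln = pk.truth_alignments(truth[~truth["u_fallback"]])
        prof = pk.end_nucleotide_profile(aln, genome.contigs, "three_prime_downstream")
        i0 = prof.positions.tolist().index(0)
        freq = prof.base_frequencies("T")[i0]
        se3 = 3 * np.sqrt(cfg.u_bias * (1 - cfg.u_bias) / len(aln))
        assert abs(freq - cfg.u_bias) <= se3
        assert prof.z >= 3

    def test_first_u_bias_recovered_from_pingpong_sim(self, pingpong_sim):
        cfg, genome, truth = pingpong_sim
        trig = pk.truth_alignments(truth[truth["role"] == "trigger"])
        prof = pk.end_nucleotide_profile(trig, genome.contigs, "read_pos10")
        i0 = prof.positions.tolist().index(0)
        freq = prof.base_frequencies("A")[i0]
        se3 = 3 * np.sqrt(cfg.first_u_bias * (1 - cfg.first_u_bias) / len(trig))
        assert abs(freq - cfg.first_u_bias) <= se3


class TestPhasingDistanceProfile:
    def test_constructed_pair_all_mass_at_plus_one(self):
        aln = make_alignments(
            [("chrT", 100, 126, "+", 1, 1), ("chrT", 126, 152, "+", 1, 1)]
        )
        prof = pk.phasing_distance_profile(aln)
        assert prof.mode == 1

    def test_minus_strand_orientation(self):
        # on the minus strand the next 5' end is one base *left* of the 3' end
        aln = make_alignments(
            [("chrT", 200, 226, "-", 1, 1), ("chrT", 174, 200, "-", 1, 1)]
        )
        prof = pk.phasing_distance_profile(aln)
        assert prof.mode == 1

    def test_phasing_sim_recovery(self, phasing_sim):
        _, _, truth = phasing_sim
        prof = pk.phasing_distance_profile(pk.truth_alignments(truth))
        assert prof.mode == 1 and prof.z >= 3

    def test_pingpong_sim_specificity(self, pingpong_sim):
        _, _, truth = pingpong_sim
        prof = pk.phasing_distance_profile(pk.truth_alignments(truth))
        assert prof.z < 2

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            pk.phasing_distance_profile(make_alignments([]).iloc[0:0])


class TestPingpongOverlapProfile:
    def test_constructed_pair_all_mass_at_ten(self):
        prof = pk.pingpong_overlap_profile({100: 1.0}, {109: 1.0})
        assert prof.mode == 10 and prof.frequencies[9] == 1.0

    def test_min_mode_variant(self):
        prof = pk.pingpong_overlap_profile({100: 2.0}, {109: 0.5}, mode="min")
        assert prof.mode == 10 and prof.frequencies[9] == 1.0

    def test_pingpong_sim_per_tile_recovery(self, pingpong_sim):
        cfg, genome, truth = pingpong_sim
        aln = pk.truth_alignments(truth)
        mask = pk.kmer_uniqueness(genome.contigs)
        tiles = pk.define_tiles(genome.contigs, mask)
        profiles, _ = pk.tile_pingpong(aln, tiles, total_genome_mapped=len(truth))
        assert len(profiles) >= 5
        modes = [p.mode for p in profiles.values()]
        zs = [p.z for p in profiles.values()]
        assert np.mean([m == 10 for m in modes]) >= 0.9
        assert np.mean([z >= 3 for z in zs]) >= 0.9

    def test_phasing_sim_specificity(self, phasing_sim):
        _, _, truth = phasing_sim
        aln = pk.truth_alignments(truth)
        plus = aln[aln["strand"] == "+"]
        prof = pk.pingpong_overlap_profile(
            sg._end_abundance(plus, "five_prime"), {}, mode="product"
        )
        assert prof.z < 2  # no minus strand -> empty profile, z = 0

    def test_coverage_thresholds_skip_tiles(self, pingpong_sim):
        _, genome, truth = pingpong_sim
        aln = pk.truth_alignments(truth)
        mask = pk.kmer_uniqueness(genome.contigs)
        tiles = pk.define_tiles(genome.contigs, mask)
        profiles, skipped = pk.tile_pingpong(aln, tiles, total_genome_mapped=len(truth))
        assert len(profiles) + len(skipped) == len(tiles)
        # tiles outside the cluster have no coverage and must be skipped
        outside = [key for key in skipped if not 10_000 <= key[1] < 15_000]
        assert len(outside) == len(tiles) - 10


class TestStrandSizeStats:
    def test_uniform_lengths(self):
        aln = make_alignments([("chrT", 0, 25, "+", 1, 1)] * 4)
        assert pk.strand_size_stats(aln)["+"]["mean"] == 25.0

    def test_weighted_mean(self):
        aln = make_alignments([("chrT", 0, 24, "+", 1, 1), ("chrT", 50, 76, "+", 1, 3)])
        assert pk.strand_size_stats(aln)["+"]["mean"] == pytest.approx(25.5)

    def test_empty_strand_is_nan(self):
        aln = make_alignments([("chrT", 0, 25, "+", 1, 1)])
        assert np.isnan(pk.strand_size_stats(aln)["-"]["mean"])


class TestInTransPingpong:
    def test_worked_example_canonical_pair(self):
        result = pk.in_trans_pingpong([(PIRNA_A, 1.0), (PIRNA_B, 1.0)])
        g1g9 = result.tables["g1g9"].frequencies
        assert g1g9 == {PIRNA_A[:9]: 500.0, PIRNA_B[:9]: 500.0}
        rc = result.tables["g2g10_revcomp"].frequencies
        assert rc == {revcomp(PIRNA_A[1:10]): 500.0, revcomp(PIRNA_B[1:10]): 500.0}
        # the two reads are each other's ping-pong partners in sequence space
        assert rc == {PIRNA_B[:9]: 500.0, PIRNA_A[:9]: 500.0}
        assert result.linkage == pytest.approx(500_000.0)
        last9 = result.tables["last9"].frequencies
        assert last9 == {PIRNA_A[-9:]: 500.0, PIRNA_B[-9:]: 500.0}
        assert result.background == 0.0
        assert result.ratio == float("inf")

    def test_single_read_no_linkage(self):
        result = pk.in_trans_pingpong([(PIRNA_A, 1.0)])
        assert result.linkage == 0.0

    def test_tables_sum_to_one_thousand(self, sliced_sim):
        _, _, truth = sliced_sim
        pir = truth[(truth["end"] - truth["start"]) >= 23]
        result = pk.in_trans_pingpong([(s, 1.0) for s in pir["sequence"]])
        for table in result.tables.values():
            assert sum(table.frequencies.values()) == pytest.approx(1000.0, abs=1e-6)

    def test_random_reads_ratio_near_one(self, rng):
        reads = [
            ("".join(np.array(list("ACGT"))[rng.integers(0, 4, 26)]), 1.0)
            for _ in range(1000)
        ]
        result = pk.in_trans_pingpong(reads)
        if result.background > 0:
            assert 0.5 <= result.ratio <= 2.0

    def test_exclusion_intervals_remove_reads(self):
        aln = make_alignments([("chrT", 100, 128, "+", 1, 1)])
        aln.loc[0, "sequence"] = PIRNA_A
        reads = [(PIRNA_A, 1.0), (PIRNA_B, 1.0)]
        result = pk.in_trans_pingpong(reads, [("chrT", 0, 500)], aln)
        assert PIRNA_A[:9] not in result.tables["g1g9"].frequencies
        assert result.linkage == 0.0

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            pk.in_trans_pingpong([])


class TestPairOverlapLength:
    def test_canonical_pair_is_ten(self):
        assert pk.pair_overlap_length(PIRNA_A, PIRNA_B) == 10

    def test_full_reverse_complement(self):
        a = "ACGTTGCAAGGT"
        assert pk.pair_overlap_length(a, revcomp(a)) == len(a)

    def test_a_never_pairs_with_a(self):
        assert pk.pair_overlap_length("AAAAACGTACGTACGT", "AAAAACGTACGTACGT") == 0

    def test_symmetric(self, rng):
        for _ in range(20):
            a = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 24)])
            b = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 28)])
            assert pk.pair_overlap_length(a, b) == pk.pair_overlap_length(b, a)


class TestMechanismClassification:
    """The three statistics jointly identify the generating mechanism.

    Over a sweep of seeds, phasing-mode data must show the +1 linkage but no
    ping-pong or in-trans signal; ping-pong data the 10-nt overlap and
    1U/10A biases but no +1 linkage; slicing-triggered data both the +1
    linkage and a strong in-trans ratio.
    """

    N_SEEDS = 20
    N_READS = 20_000

    def _overlap_z(self, aln):
        plus = aln[aln["strand"] == "+"]
        minus = aln[aln["strand"] == "-"]
        return pk.pingpong_overlap_profile(
            sg._end_abundance(plus, "five_prime") if len(plus) else {},
            sg._end_abundance(minus, "five_prime") if len(minus) else {},
        ).z

    def _intrans_ratio(self, truth):
        pir = truth[(truth["end"] - truth["start"]) >= 23]
        return pk.in_trans_pingpong([(s, 1.0) for s in pir["sequence"]]).ratio

    def test_phasing_mode(self):
        ok = 0
        for seed in range(self.N_SEEDS):
            cfg = pk.SimConfig(seed=100 + seed, mechanism="phasing")
            genome = pk.generate_genome(cfg)
            truth = pk.simulate_phasing(cfg, genome, n_reads=self.N_READS)
            aln = pk.truth_alignments(truth)
            ratio = self._intrans_ratio(truth)
            ok += (
                pk.phasing_distance_profile(aln).z >= 3
                and self._overlap_z(aln) < 2
                and (np.isnan(ratio) or ratio < 2)
            )
        assert ok >= 0.95 * self.N_SEEDS

    def test_pingpong_mode(self):
        ok = 0
        for seed in range(self.N_SEEDS):
            cfg = pk.SimConfig(seed=200 + seed, mechanism="pingpong")
            genome = pk.generate_genome(cfg)
            truth = pk.simulate_pingpong(cfg, genome, n_reads=self.N_READS)
            aln = pk.truth_alignments(truth)
            resp = truth[truth["role"] == "responder"]
            trig = truth[truth["role"] == "trigger"]
            u1 = (resp["sequence"].str[0] == "T").mean()
            a10 = (trig["sequence"].str[9] == "A").mean()
            se3 = 3 * np.sqrt(cfg.first_u_bias * (1 - cfg.first_u_bias) / len(resp))
            ok += (
                self._overlap_z(aln) >= 3
                and abs(u1 - cfg.first_u_bias) <= se3
                and abs(a10 - cfg.first_u_bias) <= se3
                and pk.phasing_distance_profile(aln).z < 2
            )
        assert ok >= 0.95 * self.N_SEEDS

    def test_sliced_phasing_mode(self):
        ok = 0
        for seed in range(self.N_SEEDS):
            cfg = pk.SimConfig(seed=300 + seed, mechanism="sliced_phasing")
            genome = pk.generate_genome(cfg)
            truth = pk.simulate_sliced_phasing(cfg, genome, n_reads=self.N_READS)
            cluster_reads = truth[truth["role"] != "trigger"]
            aln = pk.truth_alignments(cluster_reads)
            ok += (
                pk.phasing_distance_profile(aln).z >= 3
                and self._intrans_ratio(truth) >= 5
            )
        assert ok >= 0.95 * self.N_SEEDS


class TestShuffleNull:
    def test_position_shuffle_kills_all_z_scores(self, phasing_sim):
        """Permuting read positions within the cluster destroys every linkage."""
        cfg, genome, truth = phasing_sim
        _, cs, ce = cfg.cluster_interval
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            shuffled = truth.copy().head(5000)
            lengths = (shuffled["end"] - shuffled["start"]).to_numpy()
            starts = rng.integers(cs, ce - 36, size=len(shuffled))
            shuffled["start"] = starts
            shuffled["end"] = starts + lengths
            aln = pk.truth_alignments(shuffled)
            z_phase = pk.phasing_distance_profile(aln).z
            plus = aln[aln["strand"] == "+"]
            z_pp = pk.pingpong_overlap_profile(
                sg._end_abundance(plus, "five_prime"),
                sg._end_abundance(plus, "five_prime"),
            ).z
            if abs(z_phase) < 2 and abs(z_pp) < 2:
                ok += 1
        assert ok >= 0.95 * n_seeds
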