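import math

import numpy as np
import pysam
import pytest

from hapodds.evaluator import (
    HypothesisLikelihoodTable,
    collect_reads,
    evaluate_variants,
    marginalize_variant,
    score_cluster,
)
from hapodds.hypotheses import (
    GenomeHypothesis,
    VariantCluster,
    VariantRecord,
    Zygosity,
    build_hypotheses,
)
from hapodds.io import load_candidates, load_reference
from hapodds.probability import ParalogParams, ReadObservation, read_segment_log_prob
from hapodds.simulate import (
    SimulationConfig,
    build_diploid_genome,
    read_labels,
    simulate_reads,
    write_alignments,
    write_fasta,
)


def make_table(entries, cluster_id=0, n_reads=1):
    """entries: (included_variants, zygosity, prior, logL) tuples."""
    hyps, lls = [], []
    for included, zyg, prior, ll in entries:
        h = GenomeHypothesis(tuple(included), zyg)
        h.prior = prior
        hyps.append(h)
        lls.append(ll)
    return HypothesisLikelihoodTable(cluster_id, hyps, np.array(lls), n_reads)


class TestMarginalize:
    def test_hand_worked_single_variant(self):
        """One read: ref-window likelihood 0.01, alt-window 0.99.

        numerator 0.25*(a+b)/2 + 0.25*b, denominator 0.5*a -> odds 74.5.
        """
        v = VariantRecord("c", 10, "A", "C")
        a, b = 0.01, 0.99
        table = make_table(
            [
                ((), Zygosity.REFERENCE, 0.5, math.log(a)),
                ((v,), Zygosity.HETEROZYGOUS, 0.25, math.log((a + b) / 2)),
                ((v,), Zygosity.HOMOZYGOUS, 0.25, math.log(b)),
            ]
        )
        scored = marginalize_variant(table, v)
        assert math.exp(scored.log_odds) == pytest.approx(74.5, rel=1e-10)
        assert scored.posterior == pytest.approx(74.5 / 75.5, rel=1e-10)

    def test_uninformative_reads_give_prior_odds(self):
        """Equal likelihoods cancel: the odds reduce to the prior ratio."""
        v = VariantRecord("c", 10, "A", "C")
        table = make_table(
            [
                ((), Zygosity.REFERENCE, 0.5, -7.0),
                ((v,), Zygosity.HETEROZYGOUS, 0.25, -7.0),
                ((v,), Zygosity.HOMOZYGOUS, 0.25, -7.0),
            ]
        )
        scored = marginalize_variant(table, v)
        assert scored.log_odds == pytest.approx(math.log(0.5 / 0.5), abs=1e-12)

    def test_two_variant_partition_sizes(self):
        """k=2: G_v has 4 hypotheses, G_u has 3 (ref + other-only pair)."""
        v = VariantRecord("c", 10, "A", "C")
        w = VariantRecord("c", 15, "T", "G")
        cluster = VariantCluster([v, w])
        ref = "ACGT" * 20
        ref = ref[:9] + "A" + ref[10:14] + "T" + ref[15:]
        hyps = build_hypotheses(ref, cluster, read_length=4)
        in_v = [h for h in hyps if h.contains(v)]
        out_v = [h for h in hyps if not h.contains(v)]
        assert len(in_v) == 4
        assert len(out_v) == 3

    def test_variant_not_in_table_flagged(self):
        v = VariantRecord("c", 10, "A", "C")
        other = VariantRecord("c", 12, "G", "T")
        table = make_table(
            [
                ((), Zygosity.REFERENCE, 0.5, -1.0),
                ((other,), Zygosity.HETEROZYGOUS, 0.25, -1.0),
                ((other,), Zygosity.HOMOZYGOUS, 0.25, -1.0),
            ]
        )
        scored = marginalize_variant(table, v)
        assert "not_evaluated" in scored.flags
        assert math.isnan(scored.log_odds)

    def test_posterior_sign_consistency(self):
        v = VariantRecord("c", 10, "A", "C")
        for ll_alt, expect_positive in [(-1.0, True), (-20.0, False)]:
            table = make_table(
                [
                    ((), Zygosity.REFERENCE, 0.5, -5.0),
                    ((v,), Zygosity.HETEROZYGOUS, 0.25, ll_alt),
                    ((v,), Zygosity.HOMOZYGOUS, 0.25, ll_alt),
                ]
            )
            s = marginalize_variant(table, v)
            assert (s.log_odds > 0) == expect_positive
            assert (s.posterior > 0.5) == expect_positive
            assert 0.0 <= s.posterior <= 1.0


class TestScoreCluster:
    def _hyps(self, ref, v, read_length):
        return build_hypotheses(ref, VariantCluster([v]), read_length=read_length)

    def test_single_read_single_hypothesis_reduces_to_kernel(self):
        ref = "ACGTACGTACGTACGTACGTACGT"
        v = VariantRecord("c", 12, ref[11], "A" if ref[11] != "A" else "C")
        hyps = self._hyps(ref, v, read_length=6)
        refh = next(h for h in hyps if h.is_reference)
        window = refh.haplotype_windows[0]
        read = ReadObservation("r1", window[3:9], np.full(6, 0.01))
        table = score_cluster([read], [refh], ParalogParams(h=0.0))
        from scipy.special import logsumexp

        expected = logsumexp(
            [read_segment_log_prob(read, window[s : s + 6])
             for s in range(len(window) - 5)]
        )
        assert table.log_likelihoods[0] == pytest.approx(float(expected), rel=1e-12)

    @pytest.mark.parametrize("truth", ["reference", "hom"])
    def test_generating_hypothesis_is_maximal(self, truth, rng):
        """Reads drawn from a genome make that genome's hypothesis win."""
        wins = 0
        trials = 20
        for t in range(trials):
            local = np.random.default_rng(1000 + t)
            ref = "".join("ACGT"[i] for i in local.integers(0, 4, size=400))
            pos = 200
            alt = "ACGT"[("ACGT".index(ref[pos]) + 1) % 4]
            v = VariantRecord("c", pos + 1, ref[pos], alt)
            source = ref if truth == "reference" else ref[:pos] + alt + ref[pos + 1 :]
            reads = []
            for i in range(30):
                start = int(local.integers(pos - 80, pos - 10))
                seq = list(source[start : start + 90])
                for j in range(len(seq)):  # 1% sequencing error
                    if local.random() < 0.01:
                        seq[j] = "ACGT"[("ACGT".index(seq[j]) + int(local.integers(1, 4))) % 4]
                reads.append(ReadObservation(f"r{i}", "".join(seq), np.full(90, 0.01)))
            hyps = self._hyps(ref, v, read_length=90)
            table = score_cluster(reads, hyps, ParalogParams(h=0.0))
            best = table.hypotheses[int(np.argmax(table.log_likelihoods))]
            if truth == "reference" and best.is_reference:
                wins += 1
            elif truth == "hom" and best.zygosity is Zygosity.HOMOZYGOUS:
                wins += 1
        assert wins >= trials - 1

    def test_duplicating_supporting_read_never_decreases_odds(self, rng):
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        pos = 150
        alt = "ACGT"[("ACGT".index(ref[pos]) + 1) % 4]
        v = VariantRecord("c", pos + 1, ref[pos], alt)
        hyps = build_hypotheses(ref, VariantCluster([v]), read_length=40)
        alt_seq = ref[:pos] + alt + ref[pos + 1 :]
        support = ReadObservation("s", alt_seq[130:170], np.full(40, 0.01))
        reads = [ReadObservation("b", ref[120:160], np.full(40, 0.01))]
        prev = -math.inf
        for n_support in range(4):
            batch = reads + [
                ReadObservation(f"s{i}", support.called_seq, support.error_probs)
                for i in range(n_support)
            ]
            table = score_cluster(batch, hyps, ParalogParams(h=0.0))
            lo = marginalize_variant(table, v).log_odds
            assert lo >= prev
            prev = lo


class TestCollectReads:
    def test_simulated_window_counts_match_bookkeeping(self, tmp_path):
        """All simulated reads overlapping a 1-kb span are collected."""
        config = SimulationConfig(contig_length=5000, seed=5, n_snps=0,
                                  n_insertions=0, n_deletions=0, n_decoys=0)
        genome = build_diploid_genome(config)
        reads = simulate_reads(genome)
        bam = tmp_path / "r.bam"
        write_alignments(bam, config.contig_name, config.contig_length, reads)
        span = (2000, 3000)
        expected = sum(1 for r in reads if r.pos < span[1] and r.pos + len(r.seq) > span[0])
        got, flags = collect_reads(str(bam), config.contig_name, span)
        assert len(got) == expected
        # 30x over 1 kb with 100-bp reads: about (1000 + 99) / 100 * 30 reads
        assert 0.7 * 300 <= len(got) <= 1.4 * 330
        assert flags == []

    def test_phred_conversion(self, tmp_path):
        config = SimulationConfig(contig_length=3000, seed=5, n_snps=0,
                                  n_insertions=0, n_deletions=0, n_decoys=0,
                                  base_quality=20.0, coverage=5)
        genome = build_diploid_genome(config)
        bam = tmp_path / "r.bam"
        write_alignments(bam, config.contig_name, config.contig_length,
                         simulate_reads(genome))
        got, _ = collect_reads(str(bam), config.contig_name, (1000, 1100))
        assert got
        assert np.allclose(got[0].error_probs, 0.01)

    def test_read_outside_span_excluded(self, tmp_path):
        config = SimulationConfig(contig_length=3000, seed=5, n_snps=0,
                                  n_insertions=0, n_deletions=0, n_decoys=0, coverage=5)
        genome = build_diploid_genome(config)
        reads = simulate_reads(genome)
        bam = tmp_path / "r.bam"
        write_alignments(bam, config.contig_name, config.contig_length, reads)
        got, _ = collect_reads(str(bam), config.contig_name, (2500, 2600))
        for r in got:
            pos = r.locations[0].pos
            assert pos < 2600 and pos + len(r) > 2500

    def test_missing_index_raises(self, tmp_path):
        config = SimulationConfig(contig_length=2000, seed=5, n_snps=0,
                                  n_insertions=0, n_deletions=0, n_decoys=0, coverage=2)
        genome = build_diploid_genome(config)
        bam = tmp_path / "r.bam"
        write_alignments(bam, config.contig_name, config.contig_length,
                         simulate_reads(genome))
        (tmp_path / "r.bam.bai").unlink()
        with pytest.raises(ValueError):
            collect_reads(str(bam), config.contig_name, (500, 600))

    def test_high_depth_flag(self, tmp_path):
        config = SimulationConfig(contig_length=2000, seed=5, n_snps=0,
                                  n_insertions=0, n_deletions=0, n_decoys=0, coverage=30)
        genome = build_diploid_genome(config)
        bam = tmp_path / "r.bam"
        write_alignments(bam, config.contig_name, config.contig_length,
                         simulate_reads(genome))
        got, flags = collect_reads(str(bam), config.contig_name, (0, 2000), max_reads=10)
        assert len(got) == 10
        assert "high_depth" in flags


class TestEvaluateVariants:
    def test_planted_and_decoy_separation(self, small_sim):
        config, paths = small_sim
        ref = load_reference(paths["reference"])
        cands = load_candidates(paths["candidates_vcf"], ref)
        labels = read_labels(paths["labels"])
        scored = evaluate_variants(ref, cands, str(paths["alignments"]))
        truth_lo = [s.log_odds for s in scored if labels[s.variant.key()] == "truth"]
        decoy_lo = [s.log_odds for s in scored if labels[s.variant.key()] == "decoy"]
        assert len(truth_lo) == 16 and len(decoy_lo) == 15
        assert sum(lo > 0 for lo in truth_lo) / len(truth_lo) >= 0.95
        assert sum(lo < 0 for lo in decoy_lo) / len(decoy_lo) >= 0.95

    def test_no_data_cluster_flagged(self, small_sim, tmp_path):
        config, paths = small_sim
        ref = load_reference(paths["reference"])
        # an empty BAM: no reads anywhere
        empty = tmp_path / "empty.bam"
        write_alignments(empty, config.contig_name, config.contig_length, [])
        v = VariantRecord(config.contig_name, 1000,
                          ref[config.contig_name][999], "A"
                          if ref[config.contig_name][999] != "A" else "C")
        scored = evaluate_variants(ref, [v], str(empty))
        assert scored[0].flags == ["no_data"]
        assert scored[0].log_odds == 0.0
        assert scored[0].posterior == 0.5

    def test_bit_identical_reruns(self, small_sim):
        config, paths = small_sim
        ref = load_reference(paths["reference"])
        cands = load_candidates(paths["candidates_vcf"], ref)
        a = evaluate_variants(ref, cands, str(paths["alignments"]))
        b = evaluate_variants(ref, cands, str(paths["alignments"]))
        assert [s.log_odds for s in a] == [s.log_odds for s in b]
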