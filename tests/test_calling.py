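"""Mutation calling, masks, colony filter and frequency arithmetic."""

import math

import numpy as np
import pytest

from duplexprof import (
    apply_known_variant_mask,
    colony_dedup_filter,
    compute_spectrum,
    consensus_pass,
    detect_mutations,
    simulate_duplex_experiment,
    total_bs_frequency,
)
from duplexprof.calling import (
    AGAR,
    BaseCountTable,
    CallingDataError,
    ComputationError,
    MutationCall,
    SUSPENSION,
)
from duplexprof.consensus import DsDCSRead
from duplexprof.simulate import ReferenceGenome, SimulationConfig


def dsdcs_for(genome, start, end, left=None, right=None, contig="chr1", rl=10):
    seq = genome.contigs[contig]
    return DsDCSRead(
        (contig, start, end),
        left if left is not None else seq[start : start + rl],
        right if right is not None else seq[end - rl : end],
        1,
        1,
    )


def call_at(pos, ref="G", alt="A", sample="s", mode=SUSPENSION):
    return MutationCall(contig="chr1", position=pos, ref_base=ref, alt_base=alt,
                        sample_id=sample, culture_mode=mode)


class TestDetectMutations:
    def test_null_reads_give_no_calls_and_full_denominator(self, medium_genome):
        reads = [dsdcs_for(medium_genome, 100, 160), dsdcs_for(medium_genome, 300, 380)]
        calls, table = detect_mutations(reads, medium_genome)
        assert calls == []
        seq = medium_genome.contigs["chr1"]
        covered = seq[100:110] + seq[150:160] + seq[300:310] + seq[370:380]
        assert table.gc_read_bases == sum(b in "GC" for b in covered)
        assert table.at_read_bases == sum(b in "AT" for b in covered)

    def test_single_substitution_yields_one_classed_call(self, medium_genome):
        seq = medium_genome.contigs["chr1"]
        start = seq.index("G", 500)
        left = "A" + seq[start + 1 : start + 10] if seq[start] == "G" else None
        read = dsdcs_for(medium_genome, start, start + 60, left=left)
        calls, _ = detect_mutations([read], medium_genome)
        assert len(calls) == 1
        assert (calls[0].ref_base, calls[0].alt_base) == ("G", "A")
        assert calls[0].bs_class == "G:C>A:T"
        assert calls[0].position == start

    def test_n_bases_contribute_nothing(self, medium_genome):
        seq = medium_genome.contigs["chr1"]
        left = "N" + seq[101:110]
        read = dsdcs_for(medium_genome, 100, 160, left=left)
        calls, table = detect_mutations([read], medium_genome)
        assert calls == []
        covered = seq[101:110] + seq[150:160]
        assert table.total == len(covered)

    def test_masked_positions_excluded_from_calls_and_denominator(self, medium_genome):
        genome = ReferenceGenome(
            medium_genome.contigs, known_variant_positions={("chr1", 105)}
        )
        seq = genome.contigs["chr1"]
        alt = "A" if seq[105] != "A" else "C"
        left = seq[100:105] + alt + seq[106:110]
        read = dsdcs_for(genome, 100, 160, left=left)
        calls, table = detect_mutations([read], genome)
        assert calls == []
        assert table.total == 19  # 20 covered minus the masked site

    def test_matches_brute_force_comparator(self, medium_genome, rng):
        """Batch detection equals a naive per-position diff oracle."""
        config = SimulationConfig(
            n_fragments=40, strand_error_rate=0.01, mutation_frequency=1e-3, seed=41
        )
        pairs, _ = simulate_duplex_experiment(medium_genome, config)
        reads, _ = consensus_pass(pairs)
        calls, table = detect_mutations(reads, medium_genome)

        seq = medium_genome.contigs["chr1"]
        naive = []
        covered = 0
        for r in reads:
            right_start = max(
                r.fragment_start + len(r.consensus_left),
                r.fragment_end - len(r.consensus_right),
            )
            windows = [
                (r.fragment_start, r.consensus_left),
                (right_start,
                 r.consensus_right[right_start - (r.fragment_end - len(r.consensus_right)):]),
            ]
            mismatches = [
                (s + i, w[i])
                for s, w in windows
                for i in range(len(w))
                if w[i] != "N" and w[i] != seq[s + i]
            ]
            if len(mismatches) > 5:
                continue
            naive.extend(mismatches)
            covered += sum(
                1 for s, w in windows for i in range(len(w)) if w[i] != "N"
            )
        assert sorted((c.position, c.alt_base) for c in calls) == sorted(naive)
        assert table.total == covered

    def test_misassembled_read_discarded(self, medium_genome):
        seq = medium_genome.contigs["chr1"]
        garbled = "".join("A" if b != "A" else "C" for b in seq[100:110])
        read = dsdcs_for(medium_genome, 100, 160, left=garbled)
        calls, table = detect_mutations([read], medium_genome)
        assert calls == []
        assert table.total == 0
        assert table.n_reads_discarded == 1

    def test_out_of_contig_read_raises(self, medium_genome):
        read = DsDCSRead(("chr1", 49_990, 50_060), "A" * 10, "A" * 10, 1, 1)
        with pytest.raises(CallingDataError):
            detect_mutations([read], medium_genome)
        with pytest.raises(CallingDataError):
            detect_mutations([DsDCSRead(("nope", 0, 20), "A" * 10, "A" * 10, 1, 1)],
                             medium_genome)


class TestMaskAndColonyFilter:
    def test_mask_removes_only_masked(self):
        calls = [call_at(10), call_at(20), call_at(30)]
        out = apply_known_variant_mask(calls, {("chr1", 20)})
        assert [c.position for c in out] == [10, 30]
        assert apply_known_variant_mask(calls, set()) == calls

    def test_agar_triplicate_removed_entirely(self):
        calls = [call_at(50, "G", "T", mode=AGAR) for _ in range(3)]
        assert colony_dedup_filter(calls) == []

    def test_agar_duplicate_kept(self):
        calls = [call_at(50, "G", "T", mode=AGAR) for _ in range(2)]
        assert len(colony_dedup_filter(calls)) == 2

    def test_suspension_unaffected(self):
        calls = [call_at(50, "G", "T", mode=SUSPENSION) for _ in range(5)]
        assert len(colony_dedup_filter(calls)) == 5

    def test_filter_is_per_sample(self):
        calls = [call_at(50, "G", "T", sample=f"s{i % 2}", mode=AGAR) for i in range(4)]
        # two occurrences per sample: below the 3x threshold in each
        assert len(colony_dedup_filter(calls)) == 4

    def test_mask_and_colony_filter_commute(self):
        calls = (
            [call_at(50, "G", "T", mode=AGAR) for _ in range(3)]
            + [call_at(60, "C", "A", mode=AGAR)]
            + [call_at(70, "A", "G", mode=AGAR) for _ in range(4)]
        )
        mask = {("chr1", 60), ("chr1", 70)}
        a = colony_dedup_filter(apply_known_variant_mask(calls, mask))
        b = apply_known_variant_mask(colony_dedup_filter(calls), mask)
        key = lambda c: (c.position, c.ref_base, c.alt_base)
        assert sorted(map(key, a)) == sorted(map(key, b))


class TestFrequencies:
    def test_class_frequency_arithmetic(self):
        calls = [call_at(i, "G", "A") for i in range(3)]
        table = BaseCountTable(gc_read_bases=1_500_000, at_read_bases=1_000_000)
        spec = compute_spectrum(calls, table)
        assert spec.frequencies["G:C>A:T"] == pytest.approx(2.0)
        assert sum(v for k, v in spec.frequencies.items() if k != "G:C>A:T") == 0

    def test_no_calls_all_zero(self):
        spec = compute_spectrum([], BaseCountTable(10, 10))
        assert all(v == 0.0 for v in spec.frequencies.values())
        assert spec.total_bs_frequency == 0.0

    def test_zero_denominator_with_calls_is_error(self):
        with pytest.raises(ComputationError):
            compute_spectrum([call_at(1, "G", "A")], BaseCountTable(0, 100))
        with pytest.raises(ComputationError):
            total_bs_frequency([call_at(1, "G", "A")], BaseCountTable(0, 0))

    def test_total_bs_frequency_arithmetic_and_identity(self):
        calls = [call_at(i, "G", "A") for i in range(4)] + [
            call_at(i, "A", "T") for i in range(2)
        ]
        table = BaseCountTable(gc_read_bases=1_200_000, at_read_bases=800_000)
        total = total_bs_frequency(calls, table)
        assert total == pytest.approx(3.0)
        spec = compute_spectrum(calls, table)
        recombined = (
            sum(spec.class_counts[c] for c in spec.class_counts) / table.total * 1e6
        )
        assert total == pytest.approx(recombined)
        assert sum(spec.class_counts.values()) == len(calls)

    def test_simulation_recovery_within_poisson_bound(self, medium_genome):
        """End-to-end frequency at injected 1e-5 pure G:C>A:T is unbiased."""
        config = SimulationConfig(
            n_fragments=20_000,
            mutation_frequency=1e-5,
            mutation_spectrum={"G:C>A:T": 1.0},
            seed=42,
        )
        pairs, _ = simulate_duplex_experiment(medium_genome, config)
        reads, _ = consensus_pass(pairs)
        calls, table = detect_mutations(reads, medium_genome)
        k = sum(1 for c in calls if c.bs_class == "G:C>A:T")
        lam = 1e-5 * table.gc_read_bases
        assert abs(k - lam) <= 3 * math.sqrt(lam)

    def test_monotone_in_injected_frequency(self, medium_genome):
        """Estimated total BS frequency is non-decreasing in the true rate."""
        totals, sds = [], []
        for i, mf in enumerate([0.0, 2e-5, 5e-5, 1e-4, 2e-4]):
            config = SimulationConfig(n_fragments=8_000, mutation_frequency=mf, seed=50)
            pairs, _ = simulate_duplex_experiment(medium_genome, config)
            reads, _ = consensus_pass(pairs)
            calls, table = detect_mutations(reads, medium_genome)
            totals.append(total_bs_frequency(calls, table))
            sds.append(1e6 * math.sqrt(max(len(calls), 1)) / table.total)
        for lo, hi, s_lo, s_hi in zip(totals, totals[1:], sds, sds[1:]):
            assert hi >= lo - 3 * math.hypot(s_lo, s_hi)
        assert totals[-1] > totals[0]
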