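"""Duplex consensus: grouping, voting rules, rejection, error suppression."""

import random
from collections import defaultdict

import pytest

from duplexprof import consensus_pass, group_by_position, simulate_duplex_experiment
from duplexprof.consensus import (
    AlignedReadPair,
    ConsensusDataError,
    F1R2,
    F2R1,
    PositionGroup,
    build_dsdcs,
)
from duplexprof.core import revcomp, seq_to_array
from duplexprof.simulate import SimulationConfig


def make_pair(seq, start=100, orientation=F1R2, contig="c1", rl=None):
    """Pair whose mates exactly tile a fragment of sequence ``seq``."""
    rl = rl if rl is not None else len(seq) // 2
    left, right = seq[:rl], seq[-rl:]
    end = start + len(seq)
    if orientation == F1R2:
        return AlignedReadPair(contig, start, end, F1R2, left, revcomp(right))
    return AlignedReadPair(contig, start, end, F2R1, revcomp(right), left)


FRAG = "ACGTACGTAAGGCCTTACGT"  # 20 bp; windows of 10


class TestGroupByPosition:
    def test_empty(self):
        assert group_by_position([]) == []

    def test_against_brute_force_oracle(self, rng):
        keys = [("c1", 100, 450), ("c1", 100, 450), ("c1", 101, 450),
                ("c2", 100, 450), ("c1", 100, 451)]
        pairs = [
            AlignedReadPair(c, s, e, F1R2, "AAAA", "TTTT") for c, s, e in keys
        ]
        groups = group_by_position(pairs)
        oracle = defaultdict(int)
        for c, s, e in keys:
            oracle[(c, s, e)] += 1
        assert {g.key: g.size for g in groups} == dict(oracle)
        assert sorted(g.size for g in groups) == [1, 1, 1, 2]

    def test_opposite_orientations_one_group_two_subgroups(self):
        a = make_pair(FRAG, orientation=F1R2)
        b = make_pair(FRAG, orientation=F2R1)
        groups = group_by_position([a, b])
        assert len(groups) == 1
        assert len(groups[0].subgroup_f1r2) == 1
        assert len(groups[0].subgroup_f2r1) == 1

    def test_order_independent(self, clean_run):
        pairs, _, _ = clean_run
        shuffled = list(pairs)
        random.Random(99).shuffle(shuffled)
        a = [(g.key, g.size) for g in group_by_position(pairs)]
        b = [(g.key, g.size) for g in group_by_position(shuffled)]
        assert a == b


class TestBuildDsdcs:
    def test_single_orientation_rejected(self):
        group = group_by_position([make_pair(FRAG), make_pair(FRAG)])[0]
        assert build_dsdcs(group) is None

    def test_unanimous_pair_gives_identity_consensus(self):
        group = group_by_position(
            [make_pair(FRAG, orientation=F1R2), make_pair(FRAG, orientation=F2R1)]
        )[0]
        read = build_dsdcs(group)
        assert read is not None
        assert read.consensus_left == FRAG[:10]
        assert read.consensus_right == FRAG[-10:]
        assert (read.depth_f1r2, read.depth_f2r1) == (1, 1)

    def test_strand_disagreement_masks_single_position(self):
        # F2R1 copy carries G instead of A at fragment offset 0
        altered = "G" + FRAG[1:]
        group = group_by_position(
            [make_pair(FRAG, orientation=F1R2), make_pair(altered, orientation=F2R1)]
        )[0]
        read = build_dsdcs(group)
        assert read.consensus_left == "N" + FRAG[1:10]
        assert read.consensus_right == FRAG[-10:]

    def test_within_strand_ambiguity_masks(self):
        altered = "G" + FRAG[1:]
        group = group_by_position(
            [
                make_pair(FRAG, orientation=F1R2),
                make_pair(altered, orientation=F1R2),
                make_pair(FRAG, orientation=F2R1),
            ]
        )[0]
        read = build_dsdcs(group)  # unanimity broken in F1R2 at offset 0
        assert read.consensus_left[0] == "N"
        assert read.consensus_left[1:] == FRAG[1:10]

    def test_majority_fraction_resolves_ambiguity(self):
        altered = "G" + FRAG[1:]
        group = group_by_position(
            [
                make_pair(FRAG, orientation=F1R2),
                make_pair(FRAG, orientation=F1R2),
                make_pair(altered, orientation=F1R2),
                make_pair(FRAG, orientation=F2R1),
            ]
        )[0]
        read = build_dsdcs(group, consensus_fraction=0.6)
        assert read.consensus_left == FRAG[:10]

    def test_min_per_strand_threshold(self):
        group = group_by_position(
            [make_pair(FRAG, orientation=F1R2), make_pair(FRAG, orientation=F2R1)]
        )[0]
        assert build_dsdcs(group, min_per_strand=2) is None

    def test_unequal_lengths_raise_naming_key(self):
        good = make_pair(FRAG, orientation=F1R2)
        bad = AlignedReadPair("c1", 100, 120, F1R2, "ACGTACGTA", "ACGTACGTAC")
        group = PositionGroup(good.key, [good, bad], [make_pair(FRAG, orientation=F2R1)])
        with pytest.raises(ConsensusDataError, match=r"c1.*100.*120"):
            build_dsdcs(group)


class TestConsensusPass:
    def test_all_single_orientation_rejected(self):
        pairs = [make_pair(FRAG, start=s, orientation=F1R2) for s in range(0, 500, 25)]
        reads, stats = consensus_pass(pairs)
        assert reads == []
        assert stats.n_rejected_single_orientation == stats.n_groups == len(pairs)

    def test_yield_matches_family_census(self, medium_genome):
        """dsDCS count equals the number of dual-orientation coordinate groups."""
        config = SimulationConfig(n_fragments=600, seed=31)
        pairs, truth = simulate_duplex_experiment(medium_genome, config)
        reads, stats = consensus_pass(pairs)
        by_key = defaultdict(lambda: [0, 0])
        for f in truth.families:
            by_key[(f.contig, f.start, f.end)][0] += f.n_f1r2
            by_key[(f.contig, f.start, f.end)][1] += f.n_f2r1
        expected = sum(1 for a, b in by_key.values() if a >= 1 and b >= 1)
        assert stats.n_dsdcs == len(reads) == expected
        assert stats.n_dsdcs + stats.n_rejected_single_orientation == stats.n_groups

    def test_permutation_invariance(self, clean_run):
        pairs, _, _ = clean_run
        shuffled = list(pairs)
        random.Random(7).shuffle(shuffled)
        a, _ = consensus_pass(pairs)
        b, _ = consensus_pass(shuffled)
        assert [(r.key, r.consensus_left, r.consensus_right) for r in a] == [
            (r.key, r.consensus_left, r.consensus_right) for r in b
        ]

    def test_idempotence(self, medium_genome):
        config = SimulationConfig(n_fragments=300, strand_error_rate=5e-3, seed=32)
        pairs, _ = simulate_duplex_experiment(medium_genome, config)
        first, _ = consensus_pass(pairs)
        rl = config.read_length
        as_pairs = []
        for r in first:
            as_pairs.append(
                AlignedReadPair(r.contig, r.fragment_start, r.fragment_end, F1R2,
                                r.consensus_left, revcomp(r.consensus_right))
            )
            as_pairs.append(
                AlignedReadPair(r.contig, r.fragment_start, r.fragment_end, F2R1,
                                revcomp(r.consensus_right), r.consensus_left)
            )
        second, _ = consensus_pass(as_pairs)
        assert [(r.key, r.consensus_left, r.consensus_right) for r in second] == [
            (r.key, r.consensus_left, r.consensus_right) for r in first
        ]

    def test_error_suppression_hundredfold(self, medium_genome):
        """dsDCS substitution rate is >=100x below the raw read rate."""
        config = SimulationConfig(n_fragments=30_000, strand_error_rate=1e-3, seed=33)
        pairs, _ = simulate_duplex_experiment(medium_genome, config)
        seq = medium_genome.contigs["chr1"]

        raw_bases = raw_errors = 0
        for p in pairs[:20_000]:
            left, right = p.forward_windows()
            for s, w in ((p.fragment_start, left), (p.fragment_end - len(right), right)):
                ref = seq[s : s + len(w)]
                raw_bases += len(w)
                if w != ref:
                    raw_errors += sum(a != b for a, b in zip(w, ref))
        raw_rate = raw_errors / raw_bases
        assert 0.5e-3 < raw_rate < 2e-3

        reads, _ = consensus_pass(pairs)
        cons_bases = cons_errors = 0
        for r in reads:
            for s, w in (
                (r.fragment_start, r.consensus_left),
                (r.fragment_end - len(r.consensus_right), r.consensus_right),
            ):
                ref = seq[s : s + len(w)]
                cons_bases += sum(c != "N" for c in w)
                cons_errors += sum(a != b for a, b in zip(w, ref) if a != "N")
        assert cons_bases > 1_000_000
        cons_rate = cons_errors / cons_bases
        assert cons_rate <= raw_rate / 100

    def test_injected_duplex_mutation_survives(self, medium_genome):
        """A both-strand mutation always reaches the consensus under unanimity."""
        config = SimulationConfig(
            n_fragments=2_000, mutation_frequency=2e-4, seed=34
        )
        pairs, truth = simulate_duplex_experiment(medium_genome, config)
        reads, _ = consensus_pass(pairs)
        by_key = {r.key: r for r in reads}
        fam = {f.fragment_id: f for f in truth.families}
        survived = total = 0
        for m in truth.injected_mutations:
            for fid in m.fragment_ids:
                f = fam[fid]
                r = by_key.get((f.contig, f.start, f.end))
                if r is None:  # family not dual-orientation (or merged group)
                    continue
                off = m.position - f.start
                base = None
                if off < len(r.consensus_left):
                    base = r.consensus_left[off]
                off_r = m.position - (f.end - len(r.consensus_right))
                if 0 <= off_r < len(r.consensus_right):
                    base = r.consensus_right[off_r]
                if base is not None:
                    total += 1
                    survived += base == m.alt
        assert total > 0
        # coordinate-collision groups can mask a site as N; all isolated carriers survive
        assert survived / total > 0.95
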