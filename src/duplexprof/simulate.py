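"""Synthetic duplex-sequencing experiments with known ground truth.

The generator emulates the statistical structure of a duplex-sequencing
library made from mutagen-exposed bacterial DNA:

* a reference genome (random composition at a chosen GC fraction; real use
  would substitute the organism's FASTA);
* a population of ~350 bp fragments, each independently carrying rare
  mutations (per-base Bernoulli at ``mutation_frequency``, substitution
  drawn from a 6- or 96-dimensional spectrum);
* PCR duplicate families observed in both strand orientations, with
  per-orientation family sizes following a geometric law (singleton-heavy,
  like real libraries), so that single-orientation families exist and
  exercise the duplex rejection path;
* strand-specific substitution errors applied independently to every
  single-strand copy at a rate far above the true mutation frequency, plus
  optional "duplex" errors written into both strands of a fragment.

Every injected mutation is recorded in a :class:`GroundTruth` object so
downstream recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .consensus import F1R2, F2R1, AlignedReadPair
from .core import (
    BASES,
    BIN_INDEX,
    CLASS_OF_SUBSTITUTION,
    SIGNATURE_BINS,
    SIX_CLASSES,
    revcomp,
    seq_to_array,
)


class SimulationConfigError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class ReferenceGenome:
    """Reference sequence plus strain-specific known-variant positions.

    ``known_variant_positions`` are sites where the sequenced strain is
    known to differ from the reference (they must be masked out of mutation
    analysis, or they would dominate the counts).
    """

    contigs: dict[str, str]
    known_variant_positions: set[tuple[str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if set(seq) - set(BASES):
                raise ValueError(f"contig {name!r} contains non-ACGT bases")
        for contig, pos in self.known_variant_positions:
            if contig not in self.contigs or not 0 <= pos < len(self.contigs[contig]):
                raise ValueError(f"known-variant position ({contig}, {pos}) outside genome")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def generate_genome(
    length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    contig_name: str = "chr1",
) -> ReferenceGenome:
    """Random single-contig genome with the requested GC content.

    Each base is drawn independently: G or C with probability
    ``gc_fraction`` (split evenly), A or T otherwise. Deterministic per
    seed.
    """
    if length < 3:
        raise ValueError(f"genome length must be >= 3, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    half = gc_fraction / 2.0
    probs = [(1.0 - gc_fraction) / 2.0, half, half, (1.0 - gc_fraction) / 2.0]
    arr = rng.choice(np.frombuffer(b"AGCT", dtype=np.uint8), size=length, p=probs)
    return ReferenceGenome({contig_name: arr.tobytes().decode("ascii")})


# strain "known variants" are planted as transitions at the flagged sites
_KNOWN_ALT = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic duplex experiment.

    ``mutation_spectrum`` maps either the six collapsed classes
    (``"G:C>A:T"`` …) or the 96 trinucleotide bins (``"A[C>T]G"`` …) to
    probabilities summing to 1. A fragment base mutates with probability
    ``mutation_frequency``; the substitution is drawn from the spectrum
    restricted to entries compatible with that base (renormalised), and a
    base with no compatible spectrum mass never mutates — so a pure-G:C
    spectrum at frequency *f* injects at *f* per G:C base.
    """

    n_fragments: int
    fragment_length_mean: float = 350.0
    fragment_length_sd: float = 30.0
    read_length: int = 100
    family_size_mean: float = 2.0
    strand_error_rate: float = 0.0
    duplex_error_rate: float = 0.0
    mutation_frequency: float = 0.0
    mutation_spectrum: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments < 1:
            raise SimulationConfigError("n_fragments must be >= 1")
        if self.read_length < 1:
            raise SimulationConfigError("read_length must be >= 1")
        if self.fragment_length_mean < self.read_length:
            raise SimulationConfigError(
                "fragment_length_mean must be >= read_length "
                f"({self.fragment_length_mean} < {self.read_length})"
            )
        for name in ("strand_error_rate", "duplex_error_rate", "mutation_frequency"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {rate}")
        if self.family_size_mean <= 0:
            raise SimulationConfigError("family_size_mean must be > 0")
        if self.mutation_spectrum is not None:
            keys = set(self.mutation_spectrum)
            if not (keys <= set(SIX_CLASSES) or keys <= set(SIGNATURE_BINS)):
                raise SimulationConfigError(
                    "mutation_spectrum keys must all be six-class names or all 96-bin keys"
                )
            if any(v < 0 for v in self.mutation_spectrum.values()):
                raise SimulationConfigError("mutation_spectrum entries must be >= 0")
            total = float(sum(self.mutation_spectrum.values()))
            if abs(total - 1.0) > 1e-9:
                raise SimulationConfigError(
                    f"mutation_spectrum must sum to 1 (got {total!r})"
                )
        elif self.mutation_frequency > 0:
            # uniform over the six classes by default
            self.mutation_spectrum = {c: 1.0 / 6.0 for c in SIX_CLASSES}

    @property
    def is_96dim(self) -> bool:
        return self.mutation_spectrum is not None and any(
            "[" in k for k in self.mutation_spectrum
        )


@dataclass(slots=True)
class InjectedMutation:
    contig: str
    position: int
    ref: str
    alt: str
    fragment_ids: list[int]


@dataclass(slots=True)
class FamilyRecord:
    fragment_id: int
    contig: str
    start: int
    end: int
    n_f1r2: int
    n_f2r1: int


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    injected_mutations: list[InjectedMutation] = field(default_factory=list)
    duplex_errors: list[InjectedMutation] = field(default_factory=list)
    families: list[FamilyRecord] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        """Injected mutated sites per collapsed class."""
        counts = dict.fromkeys(SIX_CLASSES, 0)
        for m in self.injected_mutations:
            counts[CLASS_OF_SUBSTITUTION[(m.ref, m.alt)]] += 1
        return counts

    @property
    def n_dual_orientation_families(self) -> int:
        return sum(1 for f in self.families if f.n_f1r2 >= 1 and f.n_f2r1 >= 1)


# alt implied by (ref base, collapsed class)
_ALT_OF = {
    (ref, cls): alt for (ref, alt), cls in CLASS_OF_SUBSTITUTION.items()
}

_PUR_TO_PYR = str.maketrans("AG", "TC")


def _compatible_alt_sampler(config: SimulationConfig, genome: ReferenceGenome):
    """Return f(contig_seq, pos, ref, rng) -> alt or None per the spectrum."""
    spectrum = config.mutation_spectrum
    assert spectrum is not None
    if not config.is_96dim:
        by_pair: dict[str, tuple[list[str], np.ndarray]] = {}
        for pair, classes in (("GC", SIX_CLASSES[:3]), ("AT", SIX_CLASSES[3:])):
            w = np.array([spectrum.get(c, 0.0) for c in classes])
            total = w.sum()
            by_pair[pair] = (list(classes), w / total if total > 0 else w)

        def sample6(seq: str, pos: int, ref: str, rng) -> str | None:
            pair = "GC" if ref in "GC" else "AT"
            classes, w = by_pair[pair]
            if w.sum() == 0:
                return None
            cls = classes[rng.choice(len(classes), p=w)]
            return _ALT_OF[(ref, cls)]

        return sample6

    def sample96(seq: str, pos: int, ref: str, rng) -> str | None:
        if pos == 0 or pos == len(seq) - 1:
            return None
        five, three = seq[pos - 1], seq[pos + 1]
        if ref in "CT":
            centre = ref
        else:  # purine: bin on the reverse complement
            centre = ref.translate(_PUR_TO_PYR)
            five, three = revcomp(three), revcomp(five)
        keys = [f"{five}[{centre}>{b}]{three}" for b in BASES if b != centre]
        w = np.array([spectrum.get(k, 0.0) for k in keys])
        total = w.sum()
        if total == 0:
            return None
        key = keys[rng.choice(3, p=w / total)]
        pyr_alt = key[4]
        return pyr_alt if ref in "CT" else revcomp(pyr_alt)

    return sample96


def _apply_subs(seq: str, subs: Sequence[tuple[int, str]]) -> str:
    chars = list(seq)
    for off, alt in subs:
        chars[off] = alt
    return "".join(chars)


def simulate_duplex_experiment(
    genome: ReferenceGenome, config: SimulationConfig
) -> tuple[list[AlignedReadPair], GroundTruth]:
    """Simulate a duplex library and return (read pairs, ground truth).

    Fragments are placed uniformly on the genome with Gaussian lengths
    (clipped to at least ``read_length``); per-orientation duplicate counts
    are geometric on {0, 1, 2, ...} with mean ``family_size_mean``,
    zero-truncated at the family level (a fragment with no copy at all is
    unobserved and omitted). Injected mutations sit on **both** strands of
    their carrier fragment; strand errors are drawn independently for every
    single-strand copy; duplex errors are written into the fragment itself.
    Deterministic per ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    qual = "F" * rl  # constant Q37

    contig_names = sorted(genome.contigs)
    contig_lengths = np.array([len(genome.contigs[c]) for c in contig_names])
    if (contig_lengths < config.read_length).any():
        raise SimulationConfigError("every contig must be at least read_length long")

    known_by_contig: dict[str, list[int]] = {c: [] for c in contig_names}
    for contig, pos in genome.known_variant_positions:
        known_by_contig[contig].append(pos)
    for positions in known_by_contig.values():
        positions.sort()

    # fragment placement
    n = config.n_fragments
    contig_idx = rng.choice(
        len(contig_names), size=n, p=contig_lengths / contig_lengths.sum()
    )
    lengths = np.rint(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=n)
    ).astype(np.int64)
    lengths = np.clip(lengths, rl, contig_lengths[contig_idx])
    starts = np.floor(
        rng.random(n) * (contig_lengths[contig_idx] - lengths + 1)
    ).astype(np.int64)

    # family sizes: geometric on {0,1,...}, truncated so each family has >= 1 copy
    p_geom = 1.0 / (config.family_size_mean + 1.0)
    n_f1r2 = rng.geometric(p_geom, size=n) - 1
    n_f2r1 = rng.geometric(p_geom, size=n) - 1
    observed = (n_f1r2 + n_f2r1) > 0

    # per-fragment injected mutation counts
    if config.mutation_frequency > 0:
        n_mut = rng.binomial(lengths, config.mutation_frequency)
    else:
        n_mut = np.zeros(n, dtype=np.int64)
    sample_alt = (
        _compatible_alt_sampler(config, genome) if config.mutation_frequency > 0 else None
    )

    if config.duplex_error_rate > 0:
        n_dup = rng.binomial(lengths, config.duplex_error_rate)
    else:
        n_dup = np.zeros(n, dtype=np.int64)

    # strand-error counts for every copy, drawn up front
    total_copies = int(n_f1r2[observed].sum() + n_f2r1[observed].sum())
    if config.strand_error_rate > 0:
        err_counts = rng.binomial(2 * rl, config.strand_error_rate, size=total_copies)
    else:
        err_counts = np.zeros(total_copies, dtype=np.int64)

    pairs: list[AlignedReadPair] = []
    truth = GroundTruth()
    site_index: dict[tuple[str, int, str, str], InjectedMutation] = {}
    copy_cursor = 0

    base_codes = seq_to_array(BASES)

    for frag_id in np.nonzero(observed)[0]:
        contig = contig_names[contig_idx[frag_id]]
        seq = genome.contigs[contig]
        start = int(starts[frag_id])
        end = start + int(lengths[frag_id])
        frag = seq[start:end]

        subs: list[tuple[int, str]] = []
        # strain known variants present in every fragment
        for pos in known_by_contig[contig]:
            if start <= pos < end:
                subs.append((pos - start, _KNOWN_ALT[seq[pos]]))

        # true mutations (both strands of this fragment)
        for _ in range(int(n_mut[frag_id])):
            off = int(rng.integers(0, end - start))
            ref = frag[off]
            alt = sample_alt(seq, start + off, ref, rng)  # type: ignore[misc]
            if alt is None:
                continue
            subs.append((off, alt))
            site = (contig, start + off, ref, alt)
            rec = site_index.get(site)
            if rec is None:
                rec = InjectedMutation(contig, start + off, ref, alt, [])
                site_index[site] = rec
                truth.injected_mutations.append(rec)
            rec.fragment_ids.append(int(frag_id))

        # duplex errors: damage seen on both strands, not true mutations
        for _ in range(int(n_dup[frag_id])):
            off = int(rng.integers(0, end - start))
            ref = frag[off]
            alt = BASES[(BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            subs.append((off, alt))
            truth.duplex_errors.append(
                InjectedMutation(contig, start + off, ref, alt, [int(frag_id)])
            )

        if subs:
            frag = _apply_subs(frag, subs)

        left = frag[:rl]
        right_fwd = frag[-rl:]
        clean = {
            F1R2: (left, revcomp(right_fwd)),
            F2R1: (revcomp(right_fwd), left),
        }

        k1, k2 = int(n_f1r2[frag_id]), int(n_f2r1[frag_id])
        truth.families.append(FamilyRecord(int(frag_id), contig, start, end, k1, k2))

        for orientation, count in ((F1R2, k1), (F2R1, k2)):
            for _ in range(count):
                n_err = int(err_counts[copy_cursor])
                copy_cursor += 1
                if n_err == 0:
                    m1, m2 = clean[orientation]
                else:
                    # apply errors in the forward frame: [0, rl) left window,
                    # [rl, 2rl) right window
                    lw = seq_to_array(left).copy()
                    rw = seq_to_array(right_fwd).copy()
                    err_pos = rng.integers(0, 2 * rl, size=n_err)
                    shift = rng.integers(1, 4, size=n_err)
                    for pos, sh in zip(err_pos, shift):
                        win = lw if pos < rl else rw
                        off = int(pos) if pos < rl else int(pos) - rl
                        cur = int(np.searchsorted(base_codes, win[off]))
                        win[off] = base_codes[(cur + int(sh)) % 4]
                    lw_s = lw.tobytes().decode("ascii")
                    rw_s = rw.tobytes().decode("ascii")
                    if orientation == F1R2:
                        m1, m2 = lw_s, revcomp(rw_s)
                    else:
                        m1, m2 = revcomp(rw_s), lw_s
                pairs.append(
                    AlignedReadPair(contig, start, end, orientation, m1, m2, qual, qual)
                )

    return pairs, truth


def sample_calls_from_signature(
    genome: ReferenceGenome,
    spectrum96: Mapping[str, float],
    n_calls: int,
    seed: int = 0,
):
    """Draw mutation calls directly from a 96-dimensional spectrum.

    Bins are sampled from ``spectrum96`` and positions uniformly from
    genome sites matching each bin's trinucleotide context (on either
    strand), so the count proportions of the returned calls converge to
    the generator spectrum. Used for signature-recovery oracles; bypasses
    the read-level simulation.
    """
    from .calling import MutationCall  # deferred: calling imports nothing from here

    weights = np.array([spectrum96.get(k, 0.0) for k in SIGNATURE_BINS], dtype=float)
    if weights.min() < 0 or abs(weights.sum() - 1.0) > 1e-9:
        raise SimulationConfigError("spectrum96 must be non-negative and sum to 1")

    # index genome positions by pyrimidine-centred trinucleotide context
    positions_by_context: dict[str, list[tuple[str, int, str]]] = {}
    for contig in sorted(genome.contigs):
        seq = genome.contigs[contig]
        for pos in range(1, len(seq) - 1):
            ref = seq[pos]
            if ref in "CT":
                ctx = seq[pos - 1 : pos + 2]
            else:
                ctx = revcomp(seq[pos - 1 : pos + 2])
            positions_by_context.setdefault(ctx, []).append((contig, pos, ref))

    rng = np.random.default_rng(seed)
    bin_draws = rng.multinomial(n_calls, weights)
    calls = []
    for bin_idx in np.nonzero(bin_draws)[0]:
        key = SIGNATURE_BINS[bin_idx]
        ctx = f"{key[0]}{key[2]}{key[6]}"
        pyr_alt = key[4]
        sites = positions_by_context.get(ctx)
        if not sites:
            raise SimulationConfigError(
                f"genome has no site with trinucleotide context {ctx}"
            )
        for pick in rng.integers(0, len(sites), size=int(bin_draws[bin_idx])):
            contig, pos, ref = sites[int(pick)]
            alt = pyr_alt if ref in "CT" else revcomp(pyr_alt)
            seq = genome.contigs[contig]
            calls.append(
                MutationCall(
                    contig=contig,
                    position=pos,
                    ref_base=ref,
                    alt_base=alt,
                    context5=seq[pos - 1],
                    context3=seq[pos + 1],
                )
            )
    order = rng.permutation(len(calls))
    return [calls[i] for i in order]
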