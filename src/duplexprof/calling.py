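"""Rare base-substitution calling from duplex consensus reads.

Every non-N consensus base that differs from the reference at an unmasked
position becomes one :class:`MutationCall`; every non-N consensus base at
an unmasked position — variant or not — enters the denominator, split into
bases covering reference G:C versus A:T positions. Class frequencies are
reported per 10^6 read bases of the matching pair (a G:C>A:T count divides
by the G:C denominator), and the total BS frequency divides all calls by
the combined denominator. Known-variant positions of the sequenced strain
contribute neither calls nor denominator.

Two sample-level filters mirror standard practice for clonal libraries:
an external known-variant mask, and a colony de-duplication filter that,
for agar-grown samples only, removes every occurrence of a substitution
observed three or more times at one position (treated as descendants of a
single event in one colony).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .consensus import DsDCSRead
from .core import CLASS_OF_SUBSTITUTION, SIX_CLASSES, seq_to_array
from .simulate import ReferenceGenome

SUSPENSION = "suspension"
AGAR = "agar"

_N = ord("N")

# base byte -> 0..3 index (A,C,G,T); 255 elsewhere
_BASE_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i


class CallingDataError(ValueError):
    """Raised for reads or positions inconsistent with the reference."""


class ComputationError(ValueError):
    """Raised for frequency computations with invalid denominators."""


@dataclass(slots=True)
class MutationCall:
    """One base substitution on the forward reference strand."""

    contig: str
    position: int
    ref_base: str
    alt_base: str
    context5: str = ""
    context3: str = ""
    sample_id: str = ""
    dose_label: str = ""
    culture_mode: str = SUSPENSION

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        if self.ref_base not in "ACGT" or self.alt_base not in "ACGT":
            raise ValueError("ref_base and alt_base must be in {A,C,G,T}")

    @property
    def bs_class(self) -> str:
        return CLASS_OF_SUBSTITUTION[(self.ref_base, self.alt_base)]


@dataclass
class BaseCountTable:
    """Denominators of the frequency estimates.

    ``trinuc_coverage`` holds covered unmasked bases per pyrimidine-centred
    trinucleotide context (32 entries, :data:`duplexprof.core.TRINUC_CONTEXTS`
    order) for signature opportunity weighting; contig-edge positions lack a
    context and count only in the gc/at totals.
    """

    gc_read_bases: int = 0
    at_read_bases: int = 0
    trinuc_coverage: np.ndarray = field(
        default_factory=lambda: np.zeros(32, dtype=np.int64)
    )
    n_reads_discarded: int = 0

    @property
    def total(self) -> int:
        return self.gc_read_bases + self.at_read_bases


def _contig_trinuc_codes(idx: np.ndarray) -> np.ndarray:
    """Per-position pyrimidine-centred trinucleotide code (0..31; -1 at edges)."""
    L = idx.size
    codes = np.full(L, -1, dtype=np.int16)
    if L < 3:
        return codes
    centre = idx[1:-1].astype(np.int16)
    five = idx[:-2].astype(np.int16)
    three = idx[2:].astype(np.int16)
    inner = np.full(L - 2, -1, dtype=np.int16)
    is_c = centre == 1
    is_t = centre == 3
    is_g = centre == 2
    is_a = centre == 0
    inner[is_c] = five[is_c] * 4 + three[is_c]
    inner[is_t] = 16 + five[is_t] * 4 + three[is_t]
    inner[is_g] = (3 - three[is_g]) * 4 + (3 - five[is_g])
    inner[is_a] = 16 + (3 - three[is_a]) * 4 + (3 - five[is_a])
    codes[1:-1] = inner
    return codes


class _ContigIndex:
    """Cached numpy views of one contig used by the caller."""

    def __init__(self, seq: str, masked: Iterable[int]):
        self.seq = seq
        self.arr = seq_to_array(seq)
        self.idx = _BASE_IDX[self.arr]
        self.is_gc = (self.idx == 1) | (self.idx == 2)
        self.unmasked = np.ones(len(seq), dtype=bool)
        masked = list(masked)
        if masked:
            self.unmasked[np.asarray(masked, dtype=np.int64)] = False
        self.trinuc = _contig_trinuc_codes(self.idx)
        self.cov_diff = np.zeros(len(seq) + 1, dtype=np.int64)
        self.excluded: list[int] = []  # N-base positions, coverage-weighted


def detect_mutations(
    dsdcs: Sequence[DsDCSRead],
    genome: ReferenceGenome,
    sample_id: str = "",
    dose_label: str = "",
    culture_mode: str = SUSPENSION,
    extra_mask: Iterable[tuple[str, int]] = (),
    max_mismatches_per_read: int = 5,
) -> tuple[list[MutationCall], BaseCountTable]:
    """Call substitutions and count denominators over duplex consensus reads.

    A dsDCS read with more than ``max_mismatches_per_read`` mismatches to
    the reference is discarded as misassembled (counted in the returned
    table). Masked positions — the genome's known-variant positions plus
    ``extra_mask`` — contribute neither calls nor denominator, and N bases
    contribute nothing.
    """
    masked_by_contig: dict[str, set[int]] = {}
    for contig, pos in list(genome.known_variant_positions) + list(extra_mask):
        masked_by_contig.setdefault(contig, set()).add(pos)

    index: dict[str, _ContigIndex] = {}
    calls: list[MutationCall] = []
    table = BaseCountTable()

    for read in dsdcs:
        contig = read.contig
        ci = index.get(contig)
        if ci is None:
            if contig not in genome.contigs:
                raise CallingDataError(f"read on unknown contig {contig!r}")
            ci = index[contig] = _ContigIndex(
                genome.contigs[contig], masked_by_contig.get(contig, ())
            )
        L = len(ci.seq)
        if read.fragment_start < 0 or read.fragment_end > L:
            raise CallingDataError(
                f"read {read.key} outside contig of length {L}"
            )
        left_len = len(read.consensus_left)
        right_len = len(read.consensus_right)
        # clip the right window where it overlaps the left one
        right_start = max(read.fragment_start + left_len, read.fragment_end - right_len)
        windows = [
            (read.fragment_start, read.consensus_left),
            (right_start, read.consensus_right[right_start - (read.fragment_end - right_len):]),
        ]

        pending_cov: list[tuple[int, int]] = []
        pending_excl: list[int] = []
        pending_calls: list[tuple[int, str]] = []
        n_mismatch = 0
        for start, cons in windows:
            if not cons:
                continue
            stop = start + len(cons)
            pending_cov.append((start, stop))
            if cons == ci.seq[start:stop]:
                continue
            arr = seq_to_array(cons)
            ref = ci.arr[start:stop]
            is_n = arr == _N
            mism = (arr != ref) & ~is_n
            pending_excl.extend((start + np.nonzero(is_n)[0]).tolist())
            for off in np.nonzero(mism)[0]:
                pending_calls.append((start + int(off), chr(arr[off])))
            n_mismatch += int(mism.sum())

        if n_mismatch > max_mismatches_per_read:
            table.n_reads_discarded += 1
            continue
        for start, stop in pending_cov:
            ci.cov_diff[start] += 1
            ci.cov_diff[stop] -= 1
        ci.excluded.extend(pending_excl)
        for pos, alt in pending_calls:
            if ci.unmasked[pos]:
                calls.append(
                    MutationCall(
                        contig=contig,
                        position=pos,
                        ref_base=ci.seq[pos],
                        alt_base=alt,
                        context5=ci.seq[pos - 1] if pos > 0 else "",
                        context3=ci.seq[pos + 1] if pos < L - 1 else "",
                        sample_id=sample_id,
                        dose_label=dose_label,
                        culture_mode=culture_mode,
                    )
                )

    for ci in index.values():
        cov = np.cumsum(ci.cov_diff[:-1])
        if ci.excluded:
            pos, cnt = np.unique(np.asarray(ci.excluded, dtype=np.int64), return_counts=True)
            cov[pos] -= cnt
        cov[~ci.unmasked] = 0
        table.gc_read_bases += int(cov[ci.is_gc].sum())
        table.at_read_bases += int(cov[~ci.is_gc].sum())
        inner = ci.trinuc >= 0
        table.trinuc_coverage += np.bincount(
            ci.trinuc[inner], weights=cov[inner], minlength=32
        ).astype(np.int64)

    return calls, table


def apply_known_variant_mask(
    calls: Iterable[MutationCall], mask: Iterable[tuple[str, int]]
) -> list[MutationCall]:
    """Drop calls at known-variant positions; empty mask is the identity."""
    mask = set(mask)
    return [c for c in calls if (c.contig, c.position) not in mask]


def colony_dedup_filter(calls: Iterable[MutationCall]) -> list[MutationCall]:
    """Remove clonal colony duplicates from agar-grown samples.

    Within each agar sample, if one (position, ref, alt) substitution
    occurs three or more times, *all* its occurrences are removed — such
    recurrences are taken to be cells of one colony sharing a single
    mutation, not independent events. Suspension samples pass unchanged.
    """
    calls = list(calls)
    counts: Counter = Counter(
        (c.sample_id, c.contig, c.position, c.ref_base, c.alt_base)
        for c in calls
        if c.culture_mode == AGAR
    )
    clonal = {k for k, v in counts.items() if v >= 3}
    return [
        c
        for c in calls
        if c.culture_mode != AGAR
        or (c.sample_id, c.contig, c.position, c.ref_base, c.alt_base) not in clonal
    ]


@dataclass
class SampleSpectrum:
    """Six-class BS frequencies (per 10^6 bases of the matching pair) for one sample."""

    sample_id: str
    dose_label: str
    frequencies: dict[str, float]
    class_counts: dict[str, int]
    gc_read_bases: int
    at_read_bases: int
    culture_mode: str = SUSPENSION

    @property
    def total_bs_frequency(self) -> float:
        total_calls = sum(self.class_counts.values())
        return 1e6 * total_calls / (self.gc_read_bases + self.at_read_bases)


def compute_spectrum(
    calls: Iterable[MutationCall],
    counts: BaseCountTable,
    sample_id: str = "",
    dose_label: str = "",
    culture_mode: str = SUSPENSION,
) -> SampleSpectrum:
    """Collapse calls into the six-class spectrum, per 10^6 matching bases."""
    class_counts = dict.fromkeys(SIX_CLASSES, 0)
    for call in calls:
        class_counts[call.bs_class] += 1
    frequencies: dict[str, float] = {}
    for cls in SIX_CLASSES:
        denom = counts.gc_read_bases if cls.startswith("G:C") else counts.at_read_bases
        k = class_counts[cls]
        if denom == 0:
            if k > 0:
                raise ComputationError(
                    f"{k} {cls} calls but zero read bases in the matching denominator"
                )
            frequencies[cls] = 0.0
        else:
            frequencies[cls] = 1e6 * k / denom
    return SampleSpectrum(
        sample_id=sample_id,
        dose_label=dose_label,
        frequencies=frequencies,
        class_counts=class_counts,
        gc_read_bases=counts.gc_read_bases,
        at_read_bases=counts.at_read_bases,
        culture_mode=culture_mode,
    )


def total_bs_frequency(calls: Iterable[MutationCall], counts: BaseCountTable) -> float:
    """All calls per 10^6 read bases (G:C and A:T denominators combined)."""
    if counts.total == 0:
        raise ComputationError("zero total read base count")
    return 1e6 * sum(1 for _ in calls) / counts.total


@dataclass
class SpectrumSet:
    """Replicate spectra, convertible to a tidy table."""

    spectra: list[SampleSpectrum] = field(default_factory=list)

    def append(self, spectrum: SampleSpectrum) -> None:
        self.spectra.append(spectrum)

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.spectra:
            row = {
                "sample_id": s.sample_id,
                "dose_label": s.dose_label,
                "culture_mode": s.culture_mode,
                "gc_read_bases": s.gc_read_bases,
                "at_read_bases": s.at_read_bases,
                **s.frequencies,
                "total_bs_frequency": s.total_bs_frequency,
            }
            rows.append(row)
        return pd.DataFrame(rows)
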