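"""Double-strand consensus (dsDCS) construction from paired-end read families.

Read pairs sharing one fragment placement — the exact ``(contig, start,
end)`` triple — form a *position group*, split by orientation into an F1R2
and an F2R1 subgroup (the two strands of the original fragment). Only
groups populated in **both** orientations yield a double-strand consensus:
each strand votes internally, and the duplex base is kept only where the
two strand consensuses agree. Disagreement at a base, or ambiguity within
a strand, is masked as ``N``; masked bases are invisible downstream (they
enter neither mutation calls nor frequency denominators). Coincident
opposite-strand errors are therefore the only error mode that survives,
which is what buys the ~e² error suppression of duplex sequencing.

Coordinates are 0-based half-open on the forward reference strand.
Consensus sequences are reported in the forward reference frame as a left
window (first-in-fragment ``read_length`` bases) and a right window (last
``read_length`` bases).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import array_to_seq, revcomp, seq_to_array

F1R2 = "F1R2"
F2R1 = "F2R1"

_N = ord("N")


class ConsensusDataError(ValueError):
    """Raised for malformed read groups (e.g. unequal read lengths)."""


@dataclass(slots=True)
class AlignedReadPair:
    """One sequenced copy of a DNA fragment.

    ``mate1_seq``/``mate2_seq`` hold the bases **as sequenced** (mate 2 of an
    F1R2 pair reads the reverse strand, so it is the reverse complement of
    the fragment's right end). ``orientation`` is F1R2 when mate 1 maps
    forward, F2R1 when mate 1 maps reverse — the two orientations tag the
    two strands of the source fragment.
    """

    contig: str
    fragment_start: int
    fragment_end: int
    orientation: str
    mate1_seq: str
    mate2_seq: str
    mate1_qual: str = ""
    mate2_qual: str = ""

    def __post_init__(self) -> None:
        if self.fragment_start >= self.fragment_end:
            raise ValueError("fragment_start must be < fragment_end")
        if self.orientation not in (F1R2, F2R1):
            raise ValueError(f"orientation must be F1R2 or F2R1, got {self.orientation!r}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.fragment_start, self.fragment_end)

    def forward_windows(self) -> tuple[str, str]:
        """(left, right) windows on the forward reference strand.

        Left covers ``[start, start+len)``, right covers ``[end-len, end)``.
        """
        if self.orientation == F1R2:
            return self.mate1_seq, revcomp(self.mate2_seq)
        return self.mate2_seq, revcomp(self.mate1_seq)


@dataclass(slots=True)
class PositionGroup:
    """All read pairs sharing one fragment placement, split by orientation."""

    key: tuple[str, int, int]
    subgroup_f1r2: list[AlignedReadPair] = field(default_factory=list)
    subgroup_f2r1: list[AlignedReadPair] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.subgroup_f1r2) + len(self.subgroup_f2r1)


@dataclass(slots=True)
class DsDCSRead:
    """Double-strand consensus for one fragment placement.

    ``consensus_left``/``consensus_right`` are forward-strand windows over
    {A,C,G,T,N}; N marks within-strand ambiguity or between-strand
    disagreement.
    """

    key: tuple[str, int, int]
    consensus_left: str
    consensus_right: str
    depth_f1r2: int
    depth_f2r1: int

    @property
    def contig(self) -> str:
        return self.key[0]

    @property
    def fragment_start(self) -> int:
        return self.key[1]

    @property
    def fragment_end(self) -> int:
        return self.key[2]


@dataclass(slots=True)
class PassStats:
    """Bookkeeping for one consensus pass."""

    n_input_pairs: int = 0
    n_groups: int = 0
    n_rejected_single_orientation: int = 0
    n_dsdcs: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input_pairs": self.n_input_pairs,
            "groups": self.n_groups,
            "rejected_single_orientation": self.n_rejected_single_orientation,
            "dsdcs_yielded": self.n_dsdcs,
        }


def group_by_position(pairs: Iterable[AlignedReadPair]) -> list[PositionGroup]:
    """Partition read pairs into position groups keyed by (contig, start, end).

    The result is sorted by key, so it does not depend on input order.
    """
    groups: dict[tuple[str, int, int], PositionGroup] = {}
    for pair in pairs:
        group = groups.get(pair.key)
        if group is None:
            group = groups[pair.key] = PositionGroup(pair.key)
        if pair.orientation == F1R2:
            group.subgroup_f1r2.append(pair)
        else:
            group.subgroup_f2r1.append(pair)
    return [groups[k] for k in sorted(groups)]


def _strand_consensus(
    windows: Sequence[str], consensus_fraction: float, key: tuple
) -> str:
    """Per-base plurality call over one orientation's window copies.

    The winning base must reach ``consensus_fraction`` of the copies; ties
    or sub-threshold pluralities give N. With the default fraction 1.0 this
    is unanimity.
    """
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ConsensusDataError(f"unequal read lengths in group {key}")
    if len(windows) == 1:
        return windows[0]
    first = windows[0]
    if all(w == first for w in windows[1:]):
        return first
    arrs = np.stack([seq_to_array(w) for w in windows])
    if consensus_fraction >= 1.0:
        agree = (arrs == arrs[0]).all(axis=0)
        out = arrs[0].copy()
        out[~agree] = _N
        return array_to_seq(out)
    # plurality with threshold; resolved column-by-column only where copies differ
    out = arrs[0].copy()
    differ = ~(arrs == arrs[0]).all(axis=0)
    need = consensus_fraction * len(windows)
    for col in np.nonzero(differ)[0]:
        counts = Counter(arrs[:, col].tolist())
        (top, n_top), *rest = counts.most_common()
        if n_top >= need and (not rest or rest[0][1] < n_top):
            out[col] = top
        else:
            out[col] = _N
    return array_to_seq(out)


def _duplex_merge(a: str, b: str) -> str:
    """Keep bases where the two strand consensuses agree (and are not N)."""
    if a == b and "N" not in a:
        return a
    x = seq_to_array(a).copy()
    y = seq_to_array(b)
    x[(x != y) | (x == _N)] = _N
    return array_to_seq(x)


def build_dsdcs(
    group: PositionGroup,
    min_per_strand: int = 1,
    consensus_fraction: float = 1.0,
) -> DsDCSRead | None:
    """Build the duplex consensus for one position group, or reject it.

    A group is rejected (``None``) unless both orientations have at least
    ``min_per_strand`` members — the both-strands requirement that defines
    a dsDCS read.
    """
    n1, n2 = len(group.subgroup_f1r2), len(group.subgroup_f2r1)
    if n1 < min_per_strand or n2 < min_per_strand or n1 == 0 or n2 == 0:
        return None
    lefts1, rights1 = zip(*(p.forward_windows() for p in group.subgroup_f1r2))
    lefts2, rights2 = zip(*(p.forward_windows() for p in group.subgroup_f2r1))
    left = _duplex_merge(
        _strand_consensus(lefts1, consensus_fraction, group.key),
        _strand_consensus(lefts2, consensus_fraction, group.key),
    )
    right = _duplex_merge(
        _strand_consensus(rights1, consensus_fraction, group.key),
        _strand_consensus(rights2, consensus_fraction, group.key),
    )
    return DsDCSRead(group.key, left, right, n1, n2)


def consensus_pass(
    pairs: Sequence[AlignedReadPair],
    min_per_strand: int = 1,
    consensus_fraction: float = 1.0,
) -> tuple[list[DsDCSRead], PassStats]:
    """Group read pairs and build all duplex consensus reads.

    Returns the dsDCS reads plus pass statistics; rejected + yielded always
    equals the number of groups formed.
    """
    pairs = list(pairs)
    groups = group_by_position(pairs)
    stats = PassStats(n_input_pairs=len(pairs), n_groups=len(groups))
    out: list[DsDCSRead] = []
    for group in groups:
        read = build_dsdcs(group, min_per_strand, consensus_fraction)
        if read is None:
            stats.n_rejected_single_orientation += 1
        else:
            out.append(read)
    stats.n_dsdcs = len(out)
    return out, stats
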