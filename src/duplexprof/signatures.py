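"""Trinucleotide (96-dimensional) mutation patterns and cosine similarity.

The 96 bins stratify the six pyrimidine-centred substitutions (C>A … T>G)
by the 5' and 3' flanking reference bases; a substitution at a purine is
reverse-complemented together with its flanks before binning. Patterns can
be expressed as raw counts, as frequencies per 10^6 covered bases of each
trinucleotide context (opportunity-weighted), or as proportions summing
to 1. Similarity between patterns — and against a reference signature set
in the COSMIC SBS tab-separated layout — is measured by cosine similarity,
optionally restricted to the 16 bins of a single substitution class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import BaseCountTable, MutationCall, _contig_trinuc_codes, _BASE_IDX
from .core import (
    BIN_CONTEXT,
    BIN_INDEX,
    CLASS_OF_PYR_SUB,
    PYR_SUB_OF_CLASS,
    PYRIMIDINE_SUBS,
    SIGNATURE_BINS,
    revcomp,
    seq_to_array,
)
from .simulate import ReferenceGenome


class SignatureFormatError(ValueError):
    """Raised for malformed signature tables (missing or foreign bin keys)."""


class ContextError(ValueError):
    """Raised when a trinucleotide context cannot be read from the genome."""


def trinucleotide_context(
    genome: ReferenceGenome, call: MutationCall
) -> tuple[str, str, str]:
    """Pyrimidine-centred (substitution, 5' base, 3' base) of one call.

    Calls at C/T references are read directly; calls at A/G are
    reverse-complemented (substitution and both flanks) so the central
    reference base is a pyrimidine. Contig-edge positions have no context.
    """
    seq = genome.contigs[call.contig]
    pos = call.position
    if pos < 1 or pos > len(seq) - 2:
        raise ContextError(f"position {call.contig}:{pos} lacks both flanking bases")
    if seq[pos] != call.ref_base:
        raise ContextError(
            f"call ref {call.ref_base} does not match genome {seq[pos]} at "
            f"{call.contig}:{pos}"
        )
    if call.ref_base in "CT":
        return f"{call.ref_base}>{call.alt_base}", seq[pos - 1], seq[pos + 1]
    sub = f"{revcomp(call.ref_base)}>{revcomp(call.alt_base)}"
    return sub, revcomp(seq[pos + 1]), revcomp(seq[pos - 1])


@dataclass
class Signature96:
    """Counts, frequencies and proportions over the 96 trinucleotide bins.

    ``frequencies`` are per 10^6 covered bases of each bin's context when an
    opportunity vector was supplied, otherwise they equal the raw counts.
    ``proportions_defined`` is False for an all-zero pattern (proportions
    are then reported as zeros).
    """

    counts: np.ndarray
    frequencies: np.ndarray
    keys: tuple[str, ...] = SIGNATURE_BINS
    n_excluded_edge: int = 0

    @property
    def proportions_defined(self) -> bool:
        return bool(self.frequencies.sum() > 0)

    @property
    def proportions(self) -> np.ndarray:
        total = self.frequencies.sum()
        if total == 0:
            return np.zeros_like(self.frequencies)
        return self.frequencies / total

    def to_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.keys), name="proportion")


def genome_trinucleotide_counts(genome: ReferenceGenome) -> np.ndarray:
    """Static opportunity: genome positions per pyrimidine-centred context (32)."""
    out = np.zeros(32, dtype=np.int64)
    for seq in genome.contigs.values():
        codes = _contig_trinuc_codes(_BASE_IDX[seq_to_array(seq)])
        inner = codes >= 0
        out += np.bincount(codes[inner], minlength=32)
    return out


def build_signature96(
    calls: Iterable[MutationCall],
    genome: ReferenceGenome,
    coverage: BaseCountTable | np.ndarray | None = None,
    genome_opportunity: bool = False,
) -> Signature96:
    """Aggregate calls into a 96-bin pattern.

    ``coverage`` (a :class:`BaseCountTable` or a 32-vector of covered bases
    per trinucleotide context) turns counts into frequencies per 10^6
    covered context bases; ``genome_opportunity=True`` uses the static
    genome context counts instead. With neither, frequencies equal counts,
    so proportions are count proportions. Contig-edge calls are excluded
    and tallied in ``n_excluded_edge``.
    """
    counts = np.zeros(96, dtype=np.int64)
    n_edge = 0
    for call in calls:
        try:
            sub, five, three = trinucleotide_context(genome, call)
        except ContextError:
            n_edge += 1
            continue
        counts[BIN_INDEX[f"{five}[{sub}]{three}"]] += 1

    opportunity: np.ndarray | None = None
    if genome_opportunity:
        opportunity = genome_trinucleotide_counts(genome).astype(float)
    elif isinstance(coverage, BaseCountTable):
        opportunity = coverage.trinuc_coverage.astype(float)
    elif coverage is not None:
        opportunity = np.asarray(coverage, dtype=float)
        if opportunity.shape != (32,):
            raise SignatureFormatError("coverage vector must have 32 context entries")

    if opportunity is None:
        frequencies = counts.astype(float)
    else:
        per_bin_opp = opportunity[BIN_CONTEXT]
        with np.errstate(divide="ignore", invalid="ignore"):
            frequencies = np.where(
                per_bin_opp > 0, 1e6 * counts / per_bin_opp, 0.0
            )
        if ((counts > 0) & (per_bin_opp == 0)).any():
            raise SignatureFormatError(
                "calls observed in a context with zero coverage opportunity"
            )
    return Signature96(counts=counts, frequencies=frequencies, n_excluded_edge=n_edge)


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """a·b / (‖a‖‖b‖); undefined (error) for a zero vector."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def _class_slice(cls: str) -> np.ndarray:
    sub = PYR_SUB_OF_CLASS.get(cls, cls)
    if sub not in PYRIMIDINE_SUBS:
        raise ValueError(f"unknown substitution class {cls!r}")
    idx = [i for i, key in enumerate(SIGNATURE_BINS) if key[2:5] == sub]
    return np.asarray(idx)


def subpattern_cs(
    sig_a: Signature96 | np.ndarray,
    sig_b: Signature96 | np.ndarray,
    cls: str,
) -> float:
    """Cosine similarity over the 16 bins of one substitution class.

    ``cls`` may be a collapsed class (``"G:C>T:A"``) or a pyrimidine
    substitution (``"C>A"``). No renormalisation: the 16-entry slices are
    compared directly.
    """
    idx = _class_slice(cls)
    va = sig_a.proportions if isinstance(sig_a, Signature96) else np.asarray(sig_a, float)
    vb = sig_b.proportions if isinstance(sig_b, Signature96) else np.asarray(sig_b, float)
    return cosine_similarity(va[idx], vb[idx])


@dataclass
class ReferenceSignatureSet:
    """Named reference signatures as 96-proportion vectors in canonical bin order."""

    names: list[str]
    matrix: np.ndarray  # (n_signatures, 96)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.names), 96):
            raise SignatureFormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.names)} signatures x 96 bins"
            )
        if (self.matrix < 0).any():
            raise SignatureFormatError("signature proportions must be non-negative")
        sums = self.matrix.sum(axis=1)
        bad = [n for n, s in zip(self.names, sums) if abs(s - 1.0) > 1e-6]
        if bad:
            raise SignatureFormatError(f"signatures not summing to 1: {bad}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceSignatureSet":
        """Parse a COSMIC-style table: bin keys in the first column (or a
        ``Type``/``MutationType``/``Subtype`` column), one column per
        signature. Rows are matched by key, never by order."""
        frame = frame.copy()
        key_col = None
        for cand in ("Type", "MutationType", "Subtype", frame.columns[0]):
            if cand in frame.columns and frame[cand].astype(str).str.contains(r"\[").all():
                key_col = cand
                break
        if key_col is None:
            raise SignatureFormatError("no column of 96-bin keys (like 'A[C>A]A') found")
        frame = frame.set_index(key_col)
        missing = sorted(set(SIGNATURE_BINS) - set(frame.index))
        foreign = sorted(set(frame.index) - set(SIGNATURE_BINS))
        if missing or foreign:
            raise SignatureFormatError(
                f"bin-key mismatch: missing {missing[:4]}..., foreign {foreign[:4]}..."
            )
        frame = frame.loc[list(SIGNATURE_BINS)]
        names = [str(c) for c in frame.columns]
        return cls(names=names, matrix=frame.to_numpy(dtype=float).T)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceSignatureSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def vector(self, name: str) -> np.ndarray:
        return self.matrix[self.names.index(name)]


@dataclass
class SimilarityReport:
    """Cosine similarities of one query pattern against a reference set."""

    query: str
    entries: list[tuple[str, float]] = field(default_factory=list)

    @property
    def best(self) -> tuple[str, float]:
        return self.entries[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["signature", "cosine_similarity"])


def compare_to_reference(
    sig: Signature96 | np.ndarray,
    refset: ReferenceSignatureSet,
    query_name: str = "query",
) -> SimilarityReport:
    """CS of the query against every reference signature, ranked descending
    (ties broken by signature name)."""
    v = sig.proportions if isinstance(sig, Signature96) else np.asarray(sig, float)
    entries = [
        (name, cosine_similarity(v, refset.matrix[i]))
        for i, name in enumerate(refset.names)
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return SimilarityReport(query=query_name, entries=entries)


def reverse_complement_genome(genome: ReferenceGenome) -> ReferenceGenome:
    """Reverse-complement every contig (known-variant positions re-mapped);
    useful for strand-symmetry checks."""
    contigs = {name: revcomp(seq) for name, seq in genome.contigs.items()}
    known = {
        (c, len(genome.contigs[c]) - 1 - p) for c, p in genome.known_variant_positions
    }
    return ReferenceGenome(contigs, known)
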