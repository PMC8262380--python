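"""Shared vocabulary: bases, complement, base-substitution classes, 96-bin keys.

Base substitutions are reported in six complementary-collapsed classes
(e.g. ``G:C>A:T`` covers both G→A and C→T on the forward reference strand).
Trinucleotide (96-dimensional) patterns centre the mutated reference base on
a pyrimidine: a substitution at a purine is reverse-complemented together
with its flanking bases before binning.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


#: the six complementary-collapsed base-substitution classes, in the
#: conventional reporting order (G:C classes first).
SIX_CLASSES = (
    "G:C>T:A",
    "G:C>C:G",
    "G:C>A:T",
    "A:T>T:A",
    "A:T>C:G",
    "A:T>G:C",
)

#: forward-strand (ref, alt) -> collapsed class
CLASS_OF_SUBSTITUTION = {
    ("G", "T"): "G:C>T:A", ("C", "A"): "G:C>T:A",
    ("G", "C"): "G:C>C:G", ("C", "G"): "G:C>C:G",
    ("G", "A"): "G:C>A:T", ("C", "T"): "G:C>A:T",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
}

#: the six pyrimidine-centred substitution labels, COSMIC order
PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: collapsed class <-> pyrimidine-centred substitution
PYR_SUB_OF_CLASS = {
    "G:C>T:A": "C>A",
    "G:C>C:G": "C>G",
    "G:C>A:T": "C>T",
    "A:T>T:A": "T>A",
    "A:T>G:C": "T>C",
    "A:T>C:G": "T>G",
}
CLASS_OF_PYR_SUB = {v: k for k, v in PYR_SUB_OF_CLASS.items()}

#: the 96 trinucleotide bins, substitution-major then 5' then 3'
#: (``A[C>A]A``, ``A[C>A]C``, ... ``T[T>G]T``)
SIGNATURE_BINS = tuple(
    f"{five}[{sub}]{three}"
    for sub in PYRIMIDINE_SUBS
    for five in BASES
    for three in BASES
)
BIN_INDEX = {key: i for i, key in enumerate(SIGNATURE_BINS)}

#: the 32 pyrimidine-centred trinucleotide contexts (5' + centre + 3'),
#: the "opportunity" classes of the 96 bins
TRINUC_CONTEXTS = tuple(
    f"{five}{centre}{three}"
    for centre in "CT"
    for five in BASES
    for three in BASES
)
TRINUC_INDEX = {t: i for i, t in enumerate(TRINUC_CONTEXTS)}

#: context of each 96 bin (bin index -> trinucleotide-context index)
BIN_CONTEXT = np.array(
    [TRINUC_INDEX[f"{key[0]}{key[2]}{key[6]}"] for key in SIGNATURE_BINS]
)


def bin_key(sub: str, five: str, three: str) -> str:
    """Build a 96-bin key such as ``A[C>T]G``."""
    return f"{five}[{sub}]{three}"


def seq_to_array(seq: str) -> np.ndarray:
    """Encode a base string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")
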