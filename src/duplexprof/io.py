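"""File formats: FASTA, SAM, FASTQ, call/stat tables, minimal VCF.

SAM records are written with proper paired-end FLAG bits so that the
orientation (F1R2 / F2R1) and the fragment placement round-trip exactly;
reverse-strand mates are stored forward-strand per the SAM convention.
Internally everything is 0-based half-open; SAM text is 1-based on disk
(pysam handles the shift).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import BaseCountTable, MutationCall
from .consensus import F1R2, F2R1, AlignedReadPair, DsDCSRead, PassStats
from .core import revcomp
from .simulate import GroundTruth, ReferenceGenome


def write_fasta(genome: ReferenceGenome, path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(genome.contigs.items())
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> ReferenceGenome:
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return ReferenceGenome(contigs)


def _sam_header(genome_or_lengths) -> pysam.AlignmentHeader:
    if isinstance(genome_or_lengths, ReferenceGenome):
        lengths = {c: len(s) for c, s in genome_or_lengths.contigs.items()}
    else:
        lengths = dict(genome_or_lengths)
    names = sorted(lengths)
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": lengths[n]} for n in names],
            "RG": [{"ID": "sim", "SM": "synthetic"}],
        }
    )


def write_sam(
    pairs: Sequence[AlignedReadPair],
    path: str | Path,
    genome: ReferenceGenome | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> Path:
    """Write read pairs as primary SAM records (two per pair).

    FLAGs carry paired/proper-pair/strand/mate bits; for F1R2, read 1 maps
    forward at the fragment start (flag 99) and read 2 reverse at the
    fragment end (147); F2R1 swaps the strands (83/163).
    """
    if genome is None and contig_lengths is None:
        lengths: dict[str, int] = {}
        for p in pairs:
            lengths[p.contig] = max(lengths.get(p.contig, 0), p.fragment_end)
        contig_lengths = lengths
    header = _sam_header(genome if genome is not None else contig_lengths)
    path = Path(path)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, pair in enumerate(pairs):
            rl1, rl2 = len(pair.mate1_seq), len(pair.mate2_seq)
            qname = f"pair{i:08d}"
            tlen = pair.fragment_end - pair.fragment_start
            if pair.orientation == F1R2:
                # mate1 forward at start; mate2 reverse at end
                recs = [
                    (99, pair.fragment_start, pair.mate1_seq, pair.mate1_qual,
                     pair.fragment_end - rl2, tlen, True),
                    (147, pair.fragment_end - rl2, revcomp(pair.mate2_seq),
                     pair.mate2_qual[::-1], pair.fragment_start, -tlen, False),
                ]
            else:
                # mate1 reverse at end; mate2 forward at start
                recs = [
                    (83, pair.fragment_end - rl1, revcomp(pair.mate1_seq),
                     pair.mate1_qual[::-1], pair.fragment_start, -tlen, True),
                    (163, pair.fragment_start, pair.mate2_seq, pair.mate2_qual,
                     pair.fragment_end - rl1, tlen, False),
                ]
            for flag, pos, seq, qual, mate_pos, tl, _is_read1 in recs:
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                a.flag = flag
                a.reference_name = pair.contig
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{len(seq)}M"
                a.next_reference_name = pair.contig
                a.next_reference_start = mate_pos
                a.template_length = tl
                a.query_sequence = seq
                if qual:
                    a.query_qualities = pysam.qualitystring_to_array(qual)
                a.set_tag("RG", "sim")
                out.write(a)
    return path


def read_sam(path: str | Path) -> list[AlignedReadPair]:
    """Parse primary paired SAM records back into aligned read pairs.

    Soft-clipped or indel-containing alignments are skipped (substitution
    -only scope), as are unpaired or secondary records.
    """
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            if rec.cigartuples is None or any(op != 0 for op, _ in rec.cigartuples):
                continue  # require pure-match alignments
            by_name.setdefault(rec.query_name, []).append(rec)
    pairs: list[AlignedReadPair] = []
    for name in sorted(by_name):
        recs = by_name[name]
        if len(recs) != 2:
            continue
        r1 = next((r for r in recs if r.is_read1), None)
        r2 = next((r for r in recs if r.is_read2), None)
        if r1 is None or r2 is None or r1.reference_name != r2.reference_name:
            continue
        fwd, rev = (r1, r2) if not r1.is_reverse else (r2, r1)
        start = fwd.reference_start
        end = rev.reference_end
        orientation = F1R2 if not r1.is_reverse else F2R1

        def as_sequenced(rec: pysam.AlignedSegment) -> tuple[str, str]:
            seq = rec.query_sequence
            qual = pysam.qualities_to_qualitystring(rec.query_qualities or [])
            if rec.is_reverse:
                return revcomp(seq), qual[::-1]
            return seq, qual

        m1, q1 = as_sequenced(r1)
        m2, q2 = as_sequenced(r2)
        pairs.append(
            AlignedReadPair(
                r1.reference_name, start, end, orientation, m1, m2, q1, q2
            )
        )
    return pairs


def write_fastq(
    pairs: Sequence[AlignedReadPair], prefix: str | Path
) -> tuple[Path, Path]:
    """Paired FASTQ files (``<prefix>_R1.fastq`` / ``_R2.fastq``), alignment-free."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for i, pair in enumerate(pairs):
            name = f"pair{i:08d}"
            q1 = pair.mate1_qual or "F" * len(pair.mate1_seq)
            q2 = pair.mate2_qual or "F" * len(pair.mate2_seq)
            f1.write(f"@{name}/1\n{pair.mate1_seq}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{pair.mate2_seq}\n+\n{q2}\n")
    return p1, p2


def emit_reads(
    pairs: Sequence[AlignedReadPair],
    fmt: str,
    out: str | Path,
    genome: ReferenceGenome | None = None,
):
    """Write read pairs as ``sam`` (aligned) or ``fastq`` (paired files)."""
    fmt = fmt.lower()
    if fmt == "sam":
        return write_sam(pairs, out, genome=genome)
    if fmt == "fastq":
        return write_fastq(pairs, out)
    raise ValueError(f"unknown format {fmt!r}; expected 'sam' or 'fastq'")


def write_dsdcs_sam(
    reads: Sequence[DsDCSRead],
    path: str | Path,
    genome: ReferenceGenome | None = None,
) -> Path:
    """dsDCS reads as single-end SAM records (left and right windows)."""
    if genome is not None:
        header = _sam_header(genome)
    else:
        lengths: dict[str, int] = {}
        for r in reads:
            lengths[r.contig] = max(lengths.get(r.contig, 0), r.fragment_end)
        header = _sam_header(lengths)
    path = Path(path)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, read in enumerate(reads):
            for suffix, pos, seq in (
                ("L", read.fragment_start, read.consensus_left),
                ("R", read.fragment_end - len(read.consensus_right), read.consensus_right),
            ):
                a = pysam.AlignedSegment(header)
                a.query_name = f"dsdcs{i:08d}{suffix}"
                a.flag = 0
                a.reference_name = read.contig
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigarstring = f"{len(seq)}M"
                a.query_sequence = seq
                a.set_tag("dF", read.depth_f1r2)
                a.set_tag("dR", read.depth_f2r1)
                out.write(a)
    return path


def write_pass_stats(stats: PassStats, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([stats.as_dict()]).to_csv(path, sep="\t", index=False)
    return path


def write_calls_tsv(calls: Iterable[MutationCall], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "contig": c.contig,
            "pos0": c.position,
            "ref": c.ref_base,
            "alt": c.alt_base,
            "context5": c.context5,
            "context3": c.context3,
            "class": c.bs_class,
            "sample": c.sample_id,
            "dose": c.dose_label,
            "mode": c.culture_mode,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["contig", "pos0", "ref", "alt", "context5", "context3",
                 "class", "sample", "dose", "mode"],
    ).to_csv(path, sep="\t", index=False)
    return path


def read_calls_tsv(path: str | Path) -> list[MutationCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        MutationCall(
            contig=str(r.contig),
            position=int(r.pos0),
            ref_base=str(r.ref),
            alt_base=str(r.alt),
            context5=str(r.context5),
            context3=str(r.context3),
            sample_id=str(r.sample),
            dose_label=str(r.dose),
            culture_mode=str(r.mode),
        )
        for r in df.itertuples()
    ]


def write_base_counts(table: BaseCountTable, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "gc_read_bases": table.gc_read_bases,
                "at_read_bases": table.at_read_bases,
                "reads_discarded": table.n_reads_discarded,
            }
        ]
    ).to_csv(path, sep="\t", index=False)
    return path


def write_vcf(
    calls: Sequence[MutationCall],
    path: str | Path,
    genome: ReferenceGenome | None = None,
    sample: str = "SAMPLE",
) -> Path:
    """Minimal single-sample VCF (GT:AD:DP with per-site call counts)."""
    path = Path(path)
    from collections import Counter

    site_counts = Counter(
        (c.contig, c.position, c.ref_base, c.alt_base) for c in calls
    )
    lines = ["##fileformat=VCFv4.2", "##source=duplexprof"]
    if genome is not None:
        for name in sorted(genome.contigs):
            lines.append(f"##contig=<ID={name},length={len(genome.contigs[name])}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for (contig, pos, ref, alt), n in sorted(site_counts.items()):
        lines.append(
            f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD:DP\t"
            f"0/1:0,{n}:{n}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "contig": m.contig,
            "pos0": m.position,
            "ref": m.ref,
            "alt": m.alt,
            "n_fragments": len(m.fragment_ids),
        }
        for m in truth.injected_mutations
    ]
    pd.DataFrame(
        rows, columns=["contig", "pos0", "ref", "alt", "n_fragments"]
    ).to_csv(path, sep="\t", index=False)
    return path


def read_position_mask(path: str | Path) -> set[tuple[str, int]]:
    """Known-variant mask from TSV (contig, pos0) or 3-column BED."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    mask: set[tuple[str, int]] = set()
    if df.shape[1] >= 3 and pd.api.types.is_integer_dtype(df[2]):
        for r in df.itertuples(index=False):
            for pos in range(int(r[1]), int(r[2])):
                mask.add((str(r[0]), pos))
    else:
        for r in df.itertuples(index=False):
            mask.add((str(r[0]), int(r[1])))
    return mask
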