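"""End-to-end orchestration: simulate → consensus → call → spectra → report.

One JSON-style configuration drives the whole chain. Each *sample* block
describes a mutagen × dose group with replicate tubes; every replicate is
an independent simulated library. Stage outputs are TSV files in the
output directory, and ``manifest.json`` records the configuration hash,
derived seeds and per-stage record counts so a rerun with the same
configuration reproduces every non-timestamp byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .calling import (
    SUSPENSION,
    SpectrumSet,
    colony_dedup_filter,
    compute_spectrum,
    detect_mutations,
)
from .consensus import consensus_pass
from .core import SIX_CLASSES
from .io import (
    write_calls_tsv,
    write_fasta,
    write_ground_truth,
    write_pass_stats,
    write_sam,
)
from .signatures import build_signature96
from .simulate import (
    ReferenceGenome,
    SimulationConfig,
    generate_genome,
    simulate_duplex_experiment,
)
from .stats import DoseResponseProfile, compute_mtsf, dunnett_test, pca_spectra, significance_mark


class PipelineConfigError(ValueError):
    pass


@dataclass
class SampleBlock:
    """One mutagen × dose group of replicate libraries."""

    mutagen: str
    dose: str
    replicates: int = 3
    mutation_frequency: float = 0.0
    mutation_spectrum: dict[str, float] | None = None
    n_fragments: int | None = None
    culture_mode: str = SUSPENSION


@dataclass
class PipelineConfig:
    seed: int = 0
    genome_length: int = 50_000
    gc_fraction: float = 0.5
    n_known_variants: int = 0
    n_fragments: int = 20_000
    fragment_length_mean: float = 350.0
    fragment_length_sd: float = 30.0
    read_length: int = 100
    family_size_mean: float = 2.0
    strand_error_rate: float = 1e-3
    duplex_error_rate: float = 0.0
    min_per_strand: int = 1
    consensus_fraction: float = 1.0
    max_mismatches_per_read: int = 5
    write_reads: bool = False
    samples: list[SampleBlock] = field(default_factory=list)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        samples = [SampleBlock(**s) for s in raw.pop("samples", [])]
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(samples=samples, **raw)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> PipelineConfig:
    """A small two-mutagen demo: a G:C>A:T-dominant 'alkylator-like' agent
    and a G:C>T:A-dominant 'oxidative-like' agent, each at two doses plus a
    zero-dose control, three replicates each. Both demo spectra put all
    mass on G:C classes, so A:T sites carry no injected mutations (the
    six-class spectrum conditions within each base pair)."""
    alkyl = {"G:C>A:T": 0.9, "G:C>T:A": 0.1}
    oxid = {"G:C>T:A": 0.85, "G:C>C:G": 0.15}
    samples = []
    for mutagen, spectrum, top in (("alkylatorX", alkyl, 2e-5), ("oxidizerY", oxid, 1e-5)):
        samples.append(SampleBlock(mutagen=mutagen, dose="0", mutation_frequency=0.0))
        samples.append(
            SampleBlock(mutagen=mutagen, dose="low", mutation_frequency=top / 4,
                        mutation_spectrum=spectrum)
        )
        samples.append(
            SampleBlock(mutagen=mutagen, dose="high", mutation_frequency=top,
                        mutation_spectrum=spectrum)
        )
    return PipelineConfig(seed=seed, samples=samples)


def _derived_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence(entropy=(base, index)).generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stage_counts: dict[str, Any] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full chain into ``outdir`` and return its path.

    Outputs: ``genome.fasta``, per-replicate ``calls/*.tsv``,
    ``pass_stats.tsv``, ``spectra.tsv`` (one row per replicate),
    ``signature96.tsv`` (per mutagen×dose proportions), ``truth/*.tsv``
    and ``manifest.json``.
    """
    if not config.samples:
        raise PipelineConfigError("config has no sample blocks")
    outdir = Path(outdir)
    (outdir / "calls").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    genome = generate_genome(config.genome_length, config.gc_fraction, seed=config.seed)
    if config.n_known_variants:
        rng = np.random.default_rng(_derived_seed(config.seed, 0xFACE))
        contig = sorted(genome.contigs)[0]
        positions = rng.choice(
            config.genome_length, size=config.n_known_variants, replace=False
        )
        genome.known_variant_positions = {(contig, int(p)) for p in positions}
    write_fasta(genome, outdir / "genome.fasta")

    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, version=__version__
    )
    spectra = SpectrumSet()
    pass_rows = []
    sig_counts: dict[tuple[str, str], list] = {}
    rep_index = 0
    for block in config.samples:
        for rep in range(block.replicates):
            sample_id = f"{block.mutagen}_{block.dose}_r{rep + 1}"
            sim = SimulationConfig(
                n_fragments=block.n_fragments or config.n_fragments,
                fragment_length_mean=config.fragment_length_mean,
                fragment_length_sd=config.fragment_length_sd,
                read_length=config.read_length,
                family_size_mean=config.family_size_mean,
                strand_error_rate=config.strand_error_rate,
                duplex_error_rate=config.duplex_error_rate,
                mutation_frequency=block.mutation_frequency,
                mutation_spectrum=block.mutation_spectrum,
                seed=_derived_seed(config.seed, rep_index),
            )
            rep_index += 1
            pairs, truth = simulate_duplex_experiment(genome, sim)
            if config.write_reads:
                write_sam(pairs, outdir / f"calls/{sample_id}.sam", genome=genome)
            dsdcs, pstats = consensus_pass(
                pairs, config.min_per_strand, config.consensus_fraction
            )
            calls, counts = detect_mutations(
                dsdcs,
                genome,
                sample_id=sample_id,
                dose_label=block.dose,
                culture_mode=block.culture_mode,
                max_mismatches_per_read=config.max_mismatches_per_read,
            )
            calls = colony_dedup_filter(calls)
            write_calls_tsv(calls, outdir / f"calls/{sample_id}.tsv")
            write_ground_truth(truth, outdir / f"truth/{sample_id}.tsv")
            spectra.append(
                compute_spectrum(
                    calls, counts, sample_id=sample_id, dose_label=block.dose,
                    culture_mode=block.culture_mode,
                )
            )
            key = (block.mutagen, block.dose)
            sig = build_signature96(calls, genome, coverage=counts)
            sig_counts.setdefault(key, []).append(sig)
            pass_rows.append(
                {"sample_id": sample_id, "mutagen": block.mutagen, "dose": block.dose,
                 **pstats.as_dict(), "calls": len(calls),
                 "gc_read_bases": counts.gc_read_bases,
                 "at_read_bases": counts.at_read_bases}
            )
            manifest.stage_counts[sample_id] = {
                "read_pairs": pstats.n_input_pairs,
                "position_groups": pstats.n_groups,
                "dsdcs_reads": pstats.n_dsdcs,
                "calls": len(calls),
            }

    pass_frame = pd.DataFrame(pass_rows)
    pass_frame.to_csv(outdir / "pass_stats.tsv", sep="\t", index=False)

    frame = spectra.to_frame()
    frame.insert(0, "mutagen", [s.sample_id.rsplit("_", 2)[0] for s in spectra.spectra])
    frame.to_csv(outdir / "spectra.tsv", sep="\t", index=False, float_format="%.6g")

    sig_rows = []
    for (mutagen, dose), sigs in sorted(sig_counts.items()):
        mean_prop = np.mean([s.proportions for s in sigs], axis=0)
        total = mean_prop.sum()
        row = {"mutagen": mutagen, "dose": dose}
        row.update(
            dict(zip(sigs[0].keys, mean_prop / total if total > 0 else mean_prop))
        )
        sig_rows.append(row)
    pd.DataFrame(sig_rows).to_csv(
        outdir / "signature96.tsv", sep="\t", index=False, float_format="%.6g"
    )

    manifest.write(outdir / "manifest.json")
    return outdir


def make_report(outdir: str | Path, plots: bool = True) -> Path:
    """Summarise a pipeline run into ``<outdir>/report``.

    Writes the per-dose 6-class spectrum table with Dunnett significance
    tiers against each mutagen's zero-dose group, the 96-bin signature
    table, PCA scores over mutagen × dose mean spectra (when at least
    three), and the MTSF table with log10 values; optionally a bar-chart
    PNG per mutagen.
    """
    outdir = Path(outdir)
    report = outdir / "report"
    report.mkdir(exist_ok=True)
    spectra = pd.read_csv(outdir / "spectra.tsv", sep="\t")

    # 6-class table with significance vs the zero-dose control
    rows = []
    for mutagen, grp in spectra.groupby("mutagen", sort=True):
        control = grp[grp["dose_label"].astype(str) == "0"]
        for dose, dgrp in grp.groupby("dose_label", sort=True):
            row: dict[str, Any] = {"mutagen": mutagen, "dose": dose, "n": len(dgrp)}
            for cls in SIX_CLASSES:
                vals = dgrp[cls].to_numpy()
                row[cls] = vals.mean()
                row[f"{cls} sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
                mark = ""
                if (
                    str(dose) != "0"
                    and len(control) >= 2
                    and len(vals) >= 2
                ):
                    res = dunnett_test(control[cls].to_numpy(), [vals])
                    mark = significance_mark(float(res.pvalues[0]))
                row[f"{cls} sig"] = mark
            rows.append(row)
    spectrum_table = pd.DataFrame(rows)
    spectrum_table.to_csv(report / "spectra_6dim.tsv", sep="\t", index=False,
                          float_format="%.6g")

    # MTSF per mutagen (log10 as plotted)
    mtsf_rows = []
    for mutagen, grp in spectra.groupby("mutagen", sort=True):
        profile = DoseResponseProfile(mutagen)
        for r in grp.itertuples():
            profile.add(str(r.dose_label), float(r.total_bs_frequency))
        mtsf = compute_mtsf(profile)
        mtsf_rows.append(
            {"mutagen": mutagen, "mtsf_per_1e6bp": mtsf,
             "log10_mtsf": np.log10(mtsf) if mtsf > 0 else float("nan")}
        )
    pd.DataFrame(mtsf_rows).to_csv(report / "mtsf.tsv", sep="\t", index=False,
                                   float_format="%.6g")

    # PCA over mutagen x dose mean 6-class spectra
    means = (
        spectra.groupby(["mutagen", "dose_label"])[list(SIX_CLASSES)].mean().reset_index()
    )
    if len(means) >= 3:
        labels = [f"{r.mutagen}@{r.dose_label}" for r in means.itertuples()]
        try:
            res = pca_spectra(
                means[list(SIX_CLASSES)].to_numpy(), feature_names=list(SIX_CLASSES),
                sample_names=labels,
            )
        except ValueError:
            res = None
        if res is not None:
            k = res.scores.shape[1]
            score_frame = pd.DataFrame(
                res.scores, columns=[f"PC{i + 1}" for i in range(k)]
            )
            score_frame.insert(0, "sample", labels)
            score_frame.to_csv(report / "pca_scores.tsv", sep="\t", index=False,
                               float_format="%.6g")
            pd.DataFrame(
                {"component": [f"PC{i + 1}" for i in range(k)],
                 "variance_proportion": res.variance_proportions}
            ).to_csv(report / "pca_variance.tsv", sep="\t", index=False,
                     float_format="%.6g")

    # 96-bin table is copied through for the report bundle
    sig = pd.read_csv(outdir / "signature96.tsv", sep="\t")
    sig.to_csv(report / "signature96.tsv", sep="\t", index=False)

    if plots:
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:
            plots = False
    if plots:
        for mutagen, grp in spectrum_table.groupby("mutagen"):
            fig, ax = plt.subplots(figsize=(7, 3.2))
            doses = grp["dose"].astype(str).tolist()
            x = np.arange(len(SIX_CLASSES))
            width = 0.8 / max(len(doses), 1)
            for i, (_, r) in enumerate(grp.iterrows()):
                ax.bar(
                    x + i * width,
                    [r[cls] for cls in SIX_CLASSES],
                    width,
                    yerr=[r[f"{cls} sd"] for cls in SIX_CLASSES],
                    label=f"dose {doses[i]}",
                    capsize=2,
                )
            ax.set_xticks(x + 0.4 - width / 2)
            ax.set_xticklabels(SIX_CLASSES, rotation=30, ha="right", fontsize=7)
            ax.set_ylabel("BS / 10^6 bp")
            ax.set_title(str(mutagen))
            ax.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(report / f"spectrum_{mutagen}.png", dpi=120)
            plt.close(fig)

    return report
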