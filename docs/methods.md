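# Methods

`duplexprof` implements the analysis stack of a duplex-consensus
mutational-profiling experiment: error-corrected rare base-substitution
(BS) calling from paired-end read families, spectrum construction,
signature comparison, and the replicate-level statistics used to compare
mutagen-exposed samples with solvent controls. Every stage is driven by a
synthetic-data generator with exact ground truth, so the pipeline is fully
testable without sequencing data.

## The duplex consensus model

A sequenced DNA fragment appears in the library as PCR duplicates in two
strand orientations: F1R2 (read 1 maps forward) and F2R1 (read 1 maps
reverse), corresponding to the two strands of the original duplex. All
read pairs sharing the exact fragment placement `(contig, start, end)`
form a *position group*; the group key uses both endpoints so that
different fragments sharing one endpoint are never merged. Within a group
the two orientation subgroups vote independently per base (default:
unanimity, `consensus_fraction = 1.0`; ties or sub-threshold pluralities
give `N`), and the double-strand consensus (dsDCS) base is kept only where
both strand consensuses agree. Groups populated in a single orientation
are rejected outright (`min_per_strand = 1` is the default threshold
beyond the both-strands requirement).

Under this rule a polymerase or sequencer error — which lives on one
strand copy — survives only if the opposite strand independently acquires
the same substitution at the same position. For a per-base, per-copy error
rate *e* with uniformly chosen erroneous base, the surviving artefact rate
in singleton-by-singleton families is ≈ *e*²/3; at *e* = 10⁻³ this is
≈ 3×10⁻⁷ per base, versus 10⁻³ raw, i.e. >10³-fold suppression (larger
families suppress further through within-strand voting). True mutations,
present on both strands of the fragment, pass unanimously. Disagreements
are masked as `N` and drop out of both numerator and denominator, so
masking never biases the frequency estimate.

Re-mapping of consensus reads with an external aligner is replaced by
coordinate carry-over: a consensus read inherits its family's placement.
Alignments with indels or soft-clips are dropped before grouping
(substitution-only scope).

## Frequency estimation

Every non-`N` consensus base differing from the reference at an unmasked
position is one call; every non-`N` consensus base at an unmasked position
enters the denominator, split by whether the reference position is G:C or
A:T. Calls are collapsed into the six complementary classes (G:C>T:A,
G:C>C:G, G:C>A:T, A:T>T:A, A:T>C:G, A:T>G:C); the class frequency is
10⁶ × count / matching-pair denominator, and the total BS frequency is
10⁶ × all calls / combined denominator. Denominators count *consensus*
bases, not raw read bases — the estimand is mutations per interrogated
duplex base, the only reading under which solvent-control frequencies of
order 10⁻⁷–10⁻⁸ per base are attainable.

Two sample-level filters precede frequency computation:

* **known-variant mask** — strain-specific variant positions contribute
  neither calls nor denominator (they would otherwise dominate counts);
* **colony de-duplication** — in samples grown on agar plates, a
  (position, ref, alt) substitution observed ≥3 times in one sample is
  removed entirely, as recurrences are taken to be clonal descendants of
  one event in a single colony. Suspension cultures are exempt. The mask
  and the colony filter commute.

A consensus read with more than 5 mismatches to the reference is discarded
as misassembled (tunable); this guards against chimeric families.

## Trinucleotide signatures and cosine similarity

The 96-bin pattern stratifies the six pyrimidine-centred substitutions by
the 5′ and 3′ reference flanks; substitutions at purines are
reverse-complemented with their flanks before binning, which makes the
pattern invariant to reverse-complementing the genome (a tested
involution). Frequencies divide each bin's count by its *opportunity* —
by default the consensus-covered bases of that bin's trinucleotide
context, matching the per-10⁶-read-bases convention of the 6-class case; a
`genome_opportunity` switch substitutes static genome trinucleotide
counts, and with no opportunity the proportions are count proportions.
Whether published 96-bin figures normalise frequencies or raw counts is
ambiguous in general; frequency-based proportions are the default here,
with both computable.

Similarity between patterns, and against a reference signature set in the
COSMIC SBS tab-separated layout (parsed by bin key, never row order), is
cosine similarity CS = a·b/(‖a‖‖b‖); a 16-bin restriction to one
substitution class compares context preferences independently of the class
mix, without renormalisation.

## Statistics

* **Plate-count arithmetic** — n-fold increase = treated mean / concurrent
  control mean (3 significant figures); CV = SD/mean (3 decimals).
* **Dunnett's many-to-one test** — two-sided, pooled variance. The joint
  distribution of the comparison statistics is multivariate t with
  correlations λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)); the max-|t| probability is
  evaluated by deterministic quadrature (Gauss–Hermite over the shared
  control variate, 96 nodes, × Gauss–Legendre over the pooled-SD variable,
  160 nodes), accurate to ~10⁻⁸ and cross-checked in the tests against
  scipy's independent implementation. The family-wise error under the null
  is calibrated by simulation in the acceptance suite.
* **Student's t** — two-sided, equal variance by default (a flag selects
  Welch); degenerate zero-variance input returns p = 1 for equal means.
* **PCA** — six-class spectra are standardised per feature (mean 0,
  variance 1, ddof = 1), decomposed by full SVD; variance proportions sum
  to 1, loadings are orthonormal, and each component's sign is fixed by
  making its largest-magnitude loading positive. Zero-variance features
  are dropped with a warning.
* **MTSF** — the maximum over doses of the mean replicate total BS
  frequency; invariant to dose and replicate ordering.
* **TD50 correlation** — MTSF against the lowest available TD50 potency,
  reporting both Spearman's ρ and Pearson's r on log₁₀ values, neither
  privileged (the appropriate choice for potency data is not settled).
* Significance tiers mirror the usual figure annotation: 0.05 / 0.01 /
  0.001.

## The synthetic-data generator

The generator emulates the statistical structure of a duplex library made
from mutagen-exposed bacterial DNA:

* **genome** — i.i.d. bases at a configurable GC fraction (default 0.5;
  the Salmonella genome is ≈0.52); real analyses substitute a FASTA.
* **fragments** — uniform placement, Gaussian lengths with mean 350 bp
  (the typical shearing peak) and SD 30 bp, clipped to the read length;
  2×100 bp reads by default.
* **families** — per-orientation duplicate counts geometric on
  {0, 1, 2, …} with mean 2, truncated so every family has at least one
  copy. This is singleton-heavy like real libraries and produces
  single-orientation families, exercising the duplex rejection path. The
  real family-size law of any given library is unknown; the geometric mean
  is a modelling choice, configurable.
* **errors** — substitution errors drawn independently for every
  single-strand copy at `strand_error_rate` (default study condition
  10⁻³ per base, far above the true mutation frequency; the
  frequency-recovery runs use 5×10⁻⁴, representative of quality-filtered
  data and chosen so coincident-error artefacts sit well below the 10⁻⁶
  per-base reporting floor). `duplex_error_rate` plants damage-like
  substitutions on both strands; default 0.
* **mutations** — each fragment base mutates independently with
  probability `mutation_frequency` (study conditions span 10⁻⁷–10⁻⁵ per
  base); the substitution is drawn from the configured 6- or 96-dim
  spectrum *restricted to entries compatible with that base and
  renormalised*; a base with no compatible mass never mutates. Under this
  rule the spectrum acts as a conditional distribution within each base
  pair (or trinucleotide context): a pure-G:C spectrum at rate *f* injects
  at *f* per G:C base — exactly the class-frequency estimand — and a
  spectrum spanning both pairs injects ≈ *f* per covered base overall. The
  flip side is that the *ratio* of spectrum mass across the two base pairs
  is not expressed in the realised burden; spectra intended to silence a
  base pair must give it zero mass (the bundled demo does). Exact 96-bin
  generation for signature-recovery studies uses
  `sample_calls_from_signature`, which draws bins from the spectrum and
  positions from matching genome contexts, so count proportions converge
  to the generator spectrum.
* **not emulated** — PCR chimeras, GC bias, coverage waviness, alignment
  artefacts, quality-score error models, indels. Consequently, passing
  tests demonstrate the correctness of the consensus/calling/statistics
  machinery under the stated error model, not robustness to real-library
  artefacts such as mapping error or context-dependent error spectra.

Simulated coordinates are 0-based half-open on the forward strand; SAM
emission converts to the standard's 1-based form via pysam. Qualities are
constant Q37; consensus voting is quality-blind (a real-data path should
pre-filter low-quality bases before voting).

## Problem sizes and numerical choices

The bundled verification runs use a 10⁵ bp genome with 1.2–2×10⁵ fragments
(≈10⁷ consensus bases, enough for ≥3-Poisson-SD resolution at 10⁻⁵ per
base), 6,000 sampled calls for signature recovery, and 10⁴ Monte-Carlo
replicates for the Dunnett calibration; these sizes give tight stochastic
bounds while a full verification pass completes in minutes. Spectrum
validation tolerates 10⁻⁹ deviation from unit sum; reference signature
sets tolerate 10⁻⁶. Consensus ties break to `N`, never to a base.
Derived seeds come from `numpy.random.SeedSequence` so parallel stages
never share streams.

## Known limitations

* Coordinate collisions (distinct fragments with identical placement)
  merge into one family; at the default densities this affects a small
  fraction of groups, masking a few true-variant bases as `N` —
  conservative, not biasing.
* Denominators do not exclude positions adjacent to masked sites, and no
  per-position depth cap is applied.
* Dunnett p-values assume homoscedastic normal replicates; with n = 3 per
  group this is an approximation inherited from the standard test.
* Real-data parity (external FASTQ → aligner → this pipeline) is supported
  through the SAM interfaces but not validated here against any published
  dataset.
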