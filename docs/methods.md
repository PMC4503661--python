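# Methods

This note documents the models and estimators implemented in `scc2xpress`,
the parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinates and read model

All coordinates are 0-based half-open internally. BED input is native;
GFF3/GTF (1-based inclusive) is converted on read, so a GFF exon
`101..200` becomes `[100, 200)` and the TSS of a minus-strand gene is the
position `end − 1`. An aligned read is an interval plus an ordered list of
non-overlapping blocks; a read with more than one block is a split
(junction-spanning) read. BED12 blocks and BAM CIGAR blocks (via pysam's
block extraction) both map onto this structure. Mates of a pair are treated
as independent reads, and no mapping-quality filter is applied by default
(a `min_mapq` option exists on BAM ingestion).

## ChIP coverage and metagene profiles

Single-block reads are extended to 150 bp before coverage is computed:
the 5′ coordinate is the anchor and the read grows in the 3′ direction
(standard single-end ChIP practice approximating the sequenced fragment);
reads already ≥ 150 bp are never trimmed. Coverage at a base is the number
of read blocks overlapping it; RPM divides by library size / 10⁶. For a
gene group, RPM coverage at offsets −W..+W around each anchor (TSS;
W = 600 bp default) is averaged per base pair. Offsets are oriented in the
transcription sense (negative = upstream) by reversing minus-strand
windows. Window positions falling outside a chromosome contribute 0 but
still count in the denominator, so profiles have fixed length at the cost
of a documented downward bias at contig edges. Gene-body features (tDNAs,
snoDNAs) are anchored at the TSS like all other groups; an alternative
anchor can be supplied by constructing the `AnchorSet` directly.

## Counting, RPKM, MA and enrichment

A read increments a feature when any block overlaps it by ≥ 1 bp; a read
overlapping k features increments all k (the alternative union/strict rules
can be layered on the same interval index later). RPKM is
count · 10⁹ / (length_bp · library_size). MA quantities use a pseudocount
ε = 0.5 RPKM (applied to both samples before the log; keeps zero-RPKM
features finite and shrinks extreme ratios at low expression).
Differential-expression calls are *consumed* from an upstream table of
adjusted p-values — the negative-binomial count model that produced them is
out of scope here — and classified at adj-p < α (default 0.05), optionally
with an absolute log₂ fold-change cutoff (1.5-fold ↔ 0.585, displayed as
0.6). Gene-set over-representation is the upper-tail hypergeometric
probability P[X ≥ x] including the observed overlap; BH adjustment is
applied within each analysis family separately (one enrichment call, one
splicing-unit scan), never pooled across families.

## Percent spliced out (PSO)

A splicing unit is one annotated intron with its two flanking exons, with
donor/acceptor named in the transcription sense. The junction coverage is
the count of split reads having two consecutive blocks whose inner gap
matches the intron exactly (a ±N bp tolerance flag exists; default 0 —
unambiguous and conservative). The exonic coverage is total block overlap
with the two flanking exons divided by their summed length. PSO = 100 ×
junction / exonic coverage. PSO is deliberately not capped at 100: deep
junction support over short exons can exceed it because the numerator is a
count and the denominator a mean depth. A zero denominator yields a missing
value (never 0 %). Units with exonic coverage below 1 read-per-base are
flagged low-confidence but still reported. Genotype differences are tested
per unit with one-way fixed-effects ANOVA on raw PSO percentages (no
arcsine transform) and BH-adjusted across all tested units; units with any
missing PSO are dropped with a logged reason. When between-group variance
is exactly zero the ANOVA is reported as F = 0, p = 1 rather than the
indeterminate form.

## Cytometry KS framework

The ECDF is right-continuous (F(x) = fraction ≤ x); D is the supremum of
|F₁ − F₂| over observed values and is invariant under any strictly monotone
transform of both samples. The exact two-sample p-value is used when
n·m ≤ 10⁴ and there are no ties (with ties it falls back to the asymptotic
form with a warning); the asymptotic p is the Kolmogorov limit evaluated at
√(nm/(n+m))·D, which agrees with the exact value to < 0.01 at n = m ≥ 50.
Because n ≈ 10,000 cells makes the KS test significant for trivial shifts,
the decision rule requires an effect size: a genotype pair is flagged as
shifted only when **every** between-genotype D exceeds the **largest**
within-genotype replicate D *and* every between-pair p < α (default 0.05).
Each genotype therefore needs ≥ 2 replicates. A GFP-positive gate
(intensity > threshold, default 0 = no gate) is applied before ECDFs.

## Dual-luciferase calculators

Each well yields a firefly/renilla ratio; renilla is the cap-dependent
internal control, making all derived quantities exactly invariant under a
common plate gain. Frameshifting efficiency = 100 × mean ratio of the PRF
construct / mean ratio of the 0-frame control; readthrough = 100 × stop /
sense reporter; IRES activity = 100 × strain / reference strain. The
default aggregation is the ratio of replicate-mean ratios; a per-replicate
paired mode is available for matched well layouts (both are reported
identically when the control is constant). Strain comparisons use the
two-sample equal-variance Student t-test (Welch available); with fewer
than 3 replicates the p-value is withheld. Degenerate zero-variance
replicate sets return p = 1 (equal means) or p = 0 (unequal).

## Growth rates

μ_max is the steepest slope of ln(OD) versus time (h⁻¹) over sliding
windows of 5 consecutive points. Windows whose log-linear fit has
r² < 0.95 are excluded as candidates (falling back to all windows when none
qualify): with additive plate-reader noise, ln(OD) at low OD is
noise-dominated and the maximum over windows would otherwise be driven by
noise rather than growth. OD values are used as given (assumed
background-subtracted); `blank="first"` or a numeric blank subtracts before
fitting, and non-positive blanked values exclude a window. A perfectly flat
window is reported as slope 0 with r² = 1. Relative growth is 100 ×
test μ_max / reference μ_max.

## Synthetic data

Every generator is deterministic given (seed, config): streams are derived
from `SeedSequence([seed, stream_key])` with a fixed key per generator, so
adding one generator call never perturbs another. Truth records are emitted
alongside the data and recovery tests read truth only from them.

* **ChIP** — background reads uniform over a 4 × 100 kb toy genome with 60
  genes; a target group receives reads at `enrichment` × the background
  rate (multinomial allocation at the configured depth, 36-bp single-block
  reads, random strand). Defaults: enrichment 5, depth 2 × 10⁵
  (≈ 200× the 100-kb scale). Not modeled: fragment-size distributions,
  mappability, PCR duplicates.
* **Spliced RNA-seq** — per splicing unit, each 50-bp fragment is spliced
  with probability θ (start uniform over mRNA positions; junction-spanning
  fragments become two blocks with gap = intron) or unspliced (start
  uniform over the genomic span, one block). The truth record includes the
  analytic expected PSO computed by exhaustive enumeration of start
  positions — the oracle for recovery tests. The per-unit PSO estimator has
  a sampling sd of ≈ 2.7 points at θ = 0.5 and 10⁴ reads (the junction
  count is ~330), so recovery is assessed on the genome-wide mean over the
  20 synthetic units (sd ≈ 0.6 points), matching how splicing indices are
  reported across units.
* **Cytometry** — log-normal intensities (median 500, log-sd 0.5), 10,000
  cells × 2 replicates per genotype; the mutant genotype is scaled by a
  multiplicative shift. No instrument saturation, debris or autofluorescence.
* **Luciferase** — renilla drawn around a plate mean and firefly = renilla
  × true ratio × log-normal noise of the configured CV, so CV = 0 returns
  the configured truths exactly. Default truths mirror the study's
  efficiencies (−1 PRF 1.1 % vs 3.4 %; IRES 100 % vs 55 %).
* **Growth** — logistic OD with additive Gaussian noise (σ = 0.005),
  r = 0.6 h⁻¹ (WT) / 0.42 h⁻¹ (mutant), K = 2.0, N₀ = 0.05, readings every
  30 min for 24 h — an overnight plate-reader run in rich medium in which a
  5-point window spans ≈ 1.7 WT doublings, keeping window fits
  signal-dominated. With these conditions the 3-replicate strain mean
  recovers μ_max within 10 % in ≥ 90 % of seeds; single noisy curves and
  much slower strains are less reliable because the max-over-windows
  selection inflates estimates when cultures linger at low OD.

Passing recovery tests on these generators demonstrates estimator
correctness under the stated statistical structure; real datasets add
alignment artifacts, coverage biases and instrument effects that the
generators intentionally omit.

## Pipeline runs

`run_pipeline` validates a versioned YAML config (unknown keys are errors),
checks that all referenced input files exist before running, executes
stages in order, and writes TSVs whose first line records the tool version
and a hash of the stage parameters and seed. The log records one line per
stage with parameters and SHA-256 input checksums; deterministic stages are
bit-identical across reruns with the same config. A failing stage aborts
with a stage-named error and leaves its outputs suffixed `.partial`.
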