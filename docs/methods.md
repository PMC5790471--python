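# Methods

`pairedcna` analyses paired primary-tumor / metastasis allele-specific
copy-number profiles. Its input boundary is segmented data: per sample, a
set of non-overlapping genomic intervals with integer total and
minor-allele copy number, as produced upstream by SNP-array or sequencing
segmentation. Raw array processing, segmentation and purity estimation
are out of scope.

## Copy-number state model

Each interval state `(t, m)` (total and minor-allele copy number,
`m <= t - m`) is classified into one of five altered categories plus the
diploid-heterozygous baseline:

| category | rule |
|---|---|
| HOMDEL | t = 0 |
| LOSS | t = 1 |
| CN_LOH | t = 2, m = 0 |
| NEUTRAL_HET | t = 2, m = 1 |
| GAIN | 3 <= t <= 5 |
| AMP | t >= 6 |

The amplification bin is open-ended: on arrays the category is usually
quoted as CN 6–8, but higher integers occur (for example after a doubling
on top of a gain), so values above 8 are still classified AMP with a
warning rather than rejected. LOH is defined as `m = 0` with `t >= 1`;
homozygous deletion is not LOH.

Coordinates are 0-based half-open (BED convention) in every file and in
memory. Sex chromosomes are not part of the default layouts because the
category table assumes a diploid-heterozygous baseline, which does not
hold for male X/Y; a user can still supply any layout explicitly.
Purity is metadata only: values below 0.5 (the usual array-analysis
inclusion floor) trigger a warning, never an error.

## Whole-genome duplication call

A sample is called whole-genome duplicated when more than 70% (strict)
of the length of at least half (inclusive: `ceil(n/2)`) of the
chromosomes is at total copy number 3 or 4 with both parental alleles
present (`m >= 1`). "Between 3 and 4" is the closed integer set {3, 4}
since segmented copy numbers are integers. Fraction denominators are
full chromosome lengths, so bases without segments count against a call
— missing data cannot create WGD. The genome-wide fraction of biallelic
3–4 state is reported as a diagnostic (typically above 45% in duplicated
genomes) but is not a decision gate.

## Windowed pair discordance

The genome is tiled into fixed windows (10 kb default); the final window
of each chromosome may be short and is weighted equally (fractions count
windows, not bases). Each window takes the state of the segment with
the largest overlap inside the window; overlap ties go to the segment
with the smaller start, which makes assignment deterministic and
order-independent. Windows with no overlapping segment are missing, and
only windows with a state in both samples enter any denominator.

Per window, the difference is metastasis total minus primary total.
A window is copy-number concordant when the difference is 0, or — with
the WGD correction enabled — when it is +1 or +2 with unchanged LOH
status: a doubling of the metastasis genome raises copy numbers without
selecting between alleles, so such differences carry no allelic
information. The correction is one-sided (−1/−2 are never forgiven)
because metastasis-only doubling is the empirically observed direction;
it is applied to all pairs when enabled, with a flag to disable.

LOH is classified separately into three per-window states: unchanged,
LOH acquired in the metastasis, and heterozygosity retained in the
metastasis (LOH only in the primary). The two metrics are deliberately
independent: a window at (2,0) vs (2,1) is copy-number concordant
(difference 0) yet belongs to the het-retained LOH class.

Genome-level per-sample fractions use segment-covered bases as
denominator: the altered fraction counts bases with `t != 2`
(copy-neutral LOH is not a copy-number change), the LOH fraction counts
bases with `m = 0, t >= 1`.

## Gene-level status

A gene footprint spans TSS to the last base of its longest transcript.
The gene's status is the state of the largest-overlap segment over the
footprint — the same rule as windows, so a gene coinciding with a grid
window gets the window's state. Metastasis-private events are tabulated
per gene over evaluable pairs (both statuses present): in the default
broad mode "amplification" means GAIN or AMP and "loss" means LOSS or
HOMDEL; a strict mode restricts to AMP and HOMDEL. The strict reading
is the appropriate one for doubled cohorts, where a whole-genome
doubling puts most of the metastasis at (4,2) = GAIN and would otherwise
count as a private amplification at nearly every gene.

The cohort "shared gene" fraction counts genes whose status matches
within every evaluable pair. By default matching means identical
category; an optional doubling correction also accepts a +1/+2 total
difference with unchanged LOH, mirroring the windowed rule. Without
that option a cohort containing metastasis-only-doubled pairs reports a
near-zero shared fraction for purely arithmetic reasons, so the pipeline
applies its correction flag to this summary as well.

## Group comparisons

Cohort metrics (copy-number discordant fraction, the two unique-LOH
class fractions, per-sample genome fractions, WGD flags) are compared
between groups — treatment-naive vs post-therapy metastases, and
synchronous vs metachronous disease — with a two-tailed two-sample
t-test on the raw fractions. The default is the pooled-variance
Student's test; Welch's correction is available behind a flag. Raw
p-values are reported without multiple-testing correction, with a
significance flag at p < 0.05. Fractions are compared untransformed
(no arcsine/logit), matching standard practice for this cohort size.

## Synthetic paired cohorts

The generator builds each patient from a diploid heterozygous genome:
shared trunk events are applied to both branches, then private branch
events, then optionally a whole-genome doubling of either branch
(doubling last by default, i.e. late WGD; configurable). Event types
are loss (minor allele removed with probability `loh_bias` = 0.7), gain
(+1..3 major copies), amplification (+4..7), homozygous deletion, and
copy-neutral LOH, with weights 0.30/0.30/0.05/0.05/0.30. States are
clipped to `t >= 0` and re-normalized so the minor allele is the lesser
one; adjacent equal states are merged before emission, so profiles are
always valid and cover every base.

Two features of real data are deliberately emulated:

- **Scaled geometry.** The default layout is 22 autosomes of 5 Mb
  (11,000 windows at 10 kb), keeping full-pipeline tests fast while
  leaving enough windows for stable fractions; a full-length hg19-like
  autosome layout is provided for realism runs. Event lengths are
  log-uniform over 0.1–1.2 Mb — focal to sub-chromosomal at this scale —
  and default rates (trunk 25, branch 8 expected events) put non-doubled
  genomes near the low end of observed altered-genome fractions (~15%).
- **Recurrent hotspots.** All event placement is concentrated (12:1) on
  a fixed "hot" subset of roughly 40% of the chromosomes, emulating the
  chromosome-level clustering of real somatic alterations. This also
  keeps a doubled genome detectable by the per-chromosome WGD rule: a
  genome whose alterations were uniformly scattered could never hold
  >70% biallelic 3–4 state on half its chromosomes.

In **targeted mode**, window-aligned private events are planted to
realize requested genome fractions of copy-number discordance and of the
two unique-LOH classes (the three classes occupy disjoint windows; their
sum may not exceed 1, otherwise the configuration errors out).
Planted events are doubling-aware so that each class means what it says
in every doubling configuration: copy-number discordant windows differ
by an amount the +1/+2 correction never forgives with LOH unchanged
(a +3 gain on the metastasis, or on the primary when only the metastasis
is doubled, or a one-copy post-doubling loss when both are doubled), and
LOH-class windows are pure allelic events whose totals match the other
branch. LOH classes are planted only on windows heterozygous in the
trunk, so planted fractions are realized exactly up to whole-window
rounding. Targeted mode replaces the Poisson branch events.

Ground truth is computed from the generator's own state maps by an
independent reference implementation of the windowing and comparison (a
direct per-window scan, distinct from the vectorized pipeline path), so
pipeline results can be checked against the generator without shared
code.

The default 16-patient cohort mirrors a paired colorectal-cancer liver-
metastasis study design: 10 treatment-naive / 6 post-therapy metastases,
9 synchronous / 7 metachronous, doubling of both samples in 4 pairs and
of the metastasis only in 5. Planted group means are 0.28 (naive) vs
0.12 (post-therapy) for copy-number discordance (cohort mean 0.22), and
LOH-class means (naive: 0.03 met-only / 0.09 primary-only; post-therapy:
0.11 / 0.02) that put the mean total LOH difference near 0.124 with
metastasis-acquired LOH dominating after therapy. Per-pair values are
drawn from clipped normals (SD 0.08 for copy number, 0.02 for LOH) as a
realistic inter-patient spread.

### What the generator does not emulate

- Segmentation gaps and probe-density effects: emitted profiles cover
  every base, so missing-window handling is exercised only by unit
  tests, not by the simulator.
- Purity dilution and subclonal (non-integer) copy numbers.
- Locus-specific recurrence: genes are placed uniformly at random and
  planted events recur only at chromosome scale, so the cohort-level
  shared-gene fraction is far lower than in real cohorts, where both
  driver-gene panels and alteration breakpoints cluster in the same
  loci. Passing gene-bookkeeping tests therefore demonstrates correct
  counting, not realistic gene-level concordance values.

## Numerical and operational choices

- All randomness flows through one `numpy.random.default_rng(seed)` per
  simulated pair; identical (config, seed) reproduces byte-identical
  output files. Cohort-level draws derive child seeds below 2^31.
- Window assignment is exact integer arithmetic; no floating-point
  tolerance is involved anywhere except t-test p-values.
- Pipeline outputs are TSVs with fixed column order and a commented
  header carrying the package version, a hash of the analysis-relevant
  configuration (the output directory is excluded) and the seed; a
  manifest records SHA-256 checksums, and a rerun with the same
  configuration is byte-identical.
- Degenerate inputs fail loudly with the offending sample, patient,
  file and line named: empty profiles, overlapping segments, unknown
  chromosomes, groups smaller than 2, pairs with missing results.

## Problem sizes used in the shipped checks

Unit and property tests run on toy genomes up to 100 kb against
per-base brute-force oracles (exact agreement). Parameter-recovery
checks use 22 x 10 Mb layouts (22,000 windows) with planted discordance
0–0.5. The cohort-scale checks and the reproduction script use the
default 22 x 5 Mb layout with 16 pairs. These sizes make the entire
suite run in well under a minute while keeping at least 11,000 windows
in every fraction estimate.
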