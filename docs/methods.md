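# Methods

## Signal model and transformation

The segmentation substrate is a per-chromosome bivariate series: LRR and
informative mirrored BAF (imBAF), both modelled as piecewise constant with
independent residuals. BAF is mirrored along 0.5; probes whose mBAF reaches
the homozygous band are discarded as non-informative. Homozygosity is
decided by a global threshold (`hom_threshold`, default 0.95 on the mBAF
scale): in an unpaired sample there is no paired-normal genotype to
consult, and a plain threshold is the established practice in mBAF
pipelines. A consequence worth stating: regions of constitutive (germline)
homozygosity collapse entirely to missing imBAF, and in a 100% pure tumour
copy-neutral somatic LOH does the same, because every heterozygous probe's
BAF is pushed to 0/1. Such boundaries produce *no* signal change in either
variable and are invisible to any unpaired LRR/imBAF method; the evaluation
utilities therefore provide `detectable_changepoints`, which excludes them
(a boundary is detectable when the flanking states differ in expected LRR,
or both flanks keep informative heterozygous probes and differ in expected
mBAF).

Missing values (non-polymorphic probes, discarded homozygous probes) are
imputed by constant interpolation — last observation carried forward, with
the head back-filled from the first observation. Constant rather than
linear interpolation preserves the banded structure of imBAF; linear
interpolation would insert values between bands and distort change-point
placement. Imputation only guarantees gap-free value arrays: the
pre-imputation observation masks are kept, and only observed values enter
segment means, residuals and the per-variable counts, so imputed entries
carry zero weight in the cost.

## Segment energy and optimisation

Segment energy is the missing-value-weighted Minkowski combination

δ_s = ((l_r/(l_r+l_b))·rss_r^p + (l_b/(l_r+l_b))·β·rss_b^p)^(1/p)

with defaults p = 1/4 and β = 1. Since segmentation minimises Σδ_s,
sub-additive orders p < 1 reward strong fits concentrated in one variable:
a (near-zero, moderate) RSS pair scores lower than two moderate RSSs of
equal sum, which promotes boundaries supported by a single variable (copy
number change at constant allelic ratio, or allelic change at constant
copy number) while still pooling evidence for joint shifts. p = 1 is the
additive special case; because LRR residual variance is roughly 36× the
imBAF residual variance at realistic noise (sd ratio ≈ 6), the additive
combination is dominated by LRR and needs visibly larger imBAF-only steps
before a boundary pays off — the acceptance suite measures both detection
thresholds.

The global minimum of the cost for every segment count S = 1..S_max is
found by dynamic programming over segment end positions, with the inner
loop bounded by the maximum segment length l (time O(n·l·S_max), memory
O(n·S_max); per-segment statistics are O(1) via prefix sums of observed
values). Ties between predecessor positions break toward the smaller
index, making the change-point vector deterministic and lexicographically
smallest. The inner loop is JIT-compiled with numba when available, with a
pure-Python fallback; orders p ∈ {1/4, 1/2, 1} use sqrt/multiply instead
of generic powers. Default constraints are l = min(n, 3000) and
S_max = ceil(n/10), both configurable; analyses in this repository use
l = 400 and S_max = 80 for the benchmark samples (longest simulated
fragment 160 probes plus background spacers) and adaptive values for
noiseless runs.

Numerical guards: segment RSS from prefix sums is clamped to exactly zero
both when cancellation drives it negative and when it falls below 1e-10 of
the segment's sum of squares. The relative clamp matters: on noiseless
data the residue of cancellation (~1e-12) otherwise exceeds the
model-selection floor and masquerades as fittable signal, drawing spurious
segments. The clamp would only misfire for genuine residual structure
below ~1e-10 of signal power, far outside any realistic noise regime.

## Model selection

S is chosen by maximising logL = −N/2·(1 + log(2πδ/N)) − k·S·log N, where
δ is the optimal S-segment cost and N counts observed values across both
variables — the same values that form δ. Perfect fits (δ = 0) are floored
at N·ε before the logarithm so they compare through the penalty alone;
ties break toward fewer segments. The multiplier k (default 1, plain BIC)
is the sensitivity dial: the selected S is non-increasing in k, and
`roc_sweep` turns a k-grid into mean sensitivity/specificity curves.

On pure-noise constant signals this criterion keeps a single segment about
96% of the time at chromosome scale (n ≈ 2500), with the rate decreasing
for shorter series (≈ 90% at n = 400–800); the residual over-segmentation
is the classical optimism of a penalised scan over all split positions,
amplified slightly by the bivariate weighted cost, and is measured (not
hidden) by the acceptance suite.

## Synthetic benchmark

Samples follow a two-population mixture: tumour fraction 1 − w with the
simulated state, diploid normal fraction w. Expected signals per probe are
LRR = log2((w·2 + (1−w)·c)/2) + baseline_shift and
BAF = (w·b_n + (1−w)·b)/(w·2 + (1−w)·c), so both converge to diploid
values as contamination grows. The baseline shift defaults to
−log2(mixture ploidy/2), mimicking median-centred array normalisation of
non-diploid genomes.

Five qualitative patterns are provided (near-diploid, near-triploid,
near-tetraploid, LOH-enriched, complex). Each lays one fragment per
(state × length) combination — lengths 10/20/40/80/160 probes — on the
pattern's background, in seeded random order with background spacers of
40–60 probes and 60-probe margins (≈ 2600–4000 probes per sample). The
LOH-enriched pattern adds two extra 240-probe germline-LOH stretches
(≈ 25–30% of its probes end up in germline LOH). State tables are the
generator's own quantitative definition of the named patterns and are
fully configurable. Germline genotypes are heterozygous with probability
`het_rate` (default 0.3), forced homozygous inside germline-LOH regions;
which parental allele counts as "B" is re-drawn per SNP, which mirroring
renders irrelevant in mBAF. Noise is i.i.d. Gaussian (LRR sd 0.30, BAF sd
0.05, honouring the ≈6× ratio observed on real arrays; absolute levels are
the generator's choice), BAF clamped to [0,1] rather than
truncated-renormalised, and BAF set missing with probability 0.05
(non-polymorphic probes). Layout and noise use independent seeded RNG
streams, so a profile can be re-noised without changing the truth.

Intra-tumour heterogeneity is available but off by default: an
`AlterationSpec.cell_fraction` < 1 mixes the altered state with the
tumour background state, producing the continuous intermediate mean
levels that subclones cause on real arrays
(`profile_from_alterations` builds custom layouts with such specs; the
named patterns keep cell fraction 1).

What the generator does *not* emulate: autocorrelated LRR waves, dye bias,
probe-specific variance and the spatially irregular probe spacing of real
arrays. Passing tests therefore demonstrate correctness of the
segmentation machinery and its behaviour under the stated mixture/noise
model, not performance on wave-contaminated real data, where pre-correction
of LRR would be needed.

## Evaluation conventions

A true change-point is recalled if a prediction lies within ±window probes
(default 3); a prediction is matched if it lies within the window of any
true change-point, so repeated calls of one boundary do not hurt.
Sensitivity = recalled/true (1 if no truth); specificity =
matched/distinct predictions (a precision-like reading; 1 if no
predictions); F = harmonic mean, 0 if either is 0. The trivial boundaries
at 0 and n are excluded before scoring. Noisy-benchmark scores are
computed against the detectable subset of truth; for the near-diploid
pattern without contamination this equals the full truth set.

## Design choices that were genuinely open

- Homozygosity by global threshold rather than region context (no paired
  normal; region-aware classification would require a second segmentation
  pass and is out of scope).
- N in the BIC as observed values over both variables (alternatives —
  probe count, LRR-only count — are defensible; this one matches what δ
  integrates).
- β = 1 as printed default, with no pre-standardisation of variable
  variances: the ~6× noise asymmetry is instead absorbed by the order
  p = 1/4, and β stays an explicit dial.
- Problem sizes in tests/acceptance: 50 noisy samples for the recovery
  study, 12 per contamination level, 200 replicates for the DP oracle and
  the pure-noise study, n = 2500 for the latter — chosen to estimate each
  rate to a few percent at desk scale.

## Known limitations

- Copy-neutral LOH boundaries in pure tumours and germline-LOH boundaries
  at any purity are invisible by construction (see above); detecting the
  latter requires a genotype-aware channel, which is deliberately not a
  separate segmentation input here.
- The BIC criterion mildly over-segments short series; on chromosome-scale
  constant noise the false-segmentation rate is ≈ 4–5%. Raising k trades
  this against short-fragment sensitivity.
- Exact DP cost grows linearly in the segment-length bound and segment
  budget; genome-wide runs should keep `max_segment_length` near the
  longest plausible constant stretch rather than n.
- At window 0, boundaries supported only by imBAF are localisable only up
  to the nearest informative probes; with het_rate < 1 exact-probe
  recovery of such boundaries is undetermined even without noise.
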