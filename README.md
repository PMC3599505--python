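# bivarseg

Bivariate segmentation of SNP-array tumour data for allele-specific copy
number (ASCN) analysis.

SNP arrays report two signals per probe: the **log R ratio** (LRR, log2 total
intensity relative to a diploid reference, tracking total copy number) and
the **B allele frequency** (BAF, the B allele's share of the signal, tracking
the allelic ratio). Copy number alterations and loss of heterozygosity (LOH)
in tumours move these signals in segments, but tumour biopsies are mixtures:
a normal-cell fraction *w* shrinks both signals towards their diploid values,
and probe noise blurs them further. Finding the segment boundaries
(change-points) jointly in both signals is the problem this package solves —
univariate segmentation wastes the shared information, while naive additive
bivariate costs drown changes that occur in only one signal.

## Method

BAF is mirrored along 0.5 (mBAF = |BAF − 0.5| + 0.5) and homozygous probes
(mBAF ≥ 0.95 by default) are dropped, giving **informative mirrored BAF**
(imBAF); remaining gaps are bridged by constant interpolation, with the
original observation masks retained. Both variables are then modelled as
piecewise constant (a structural change model). A candidate segment *s* with
per-variable residual sums of squares rss_r (LRR) and rss_b (imBAF), over
l_r and l_b observed values, gets the energy

    δ_s = ( l_r/(l_r+l_b) · rss_r^p  +  l_b/(l_r+l_b) · β · rss_b^p )^(1/p)

a missing-value-weighted Minkowski combination of order *p* (default 1/4)
with imBAF weight β (default 1). Orders *p* < 1 make one near-perfect fit
dominate the combination, so a strong mean shift in a *single* variable —
e.g. a copy-number change at constant allelic ratio — still pays for a
boundary. The segmentation cost G(t_1…t_S) = Σ_s δ_s is minimised exactly by
dynamic programming (O(n·l) per segment count with maximum segment length
*l*), and the number of segments S is chosen by the BIC-penalised Gaussian
log-likelihood

    log L = −N/2 · (1 + log(2π δ / N)) − k·S·log N

over the observed-value count N, with penalty multiplier k (default 1) as
the sensitivity dial.

The package also ships a synthetic Illumina-like benchmark generator
(five tumour patterns, copy numbers 1–5 with somatic/germline LOH, fragment
lengths 10–160 probes, contamination 0–75%, LRR noise ≈ 6× imBAF noise) and
the windowed change-point scoring (±3-probe recall window, precision-like
specificity that does not penalise duplicate calls, F-measure) used to
evaluate it.

## Worked example

Simulate a near-diploid tumour sample with known truth, segment it and score
the result:

```sh
bivarseg simulate --pattern near_diploid --seed 7 --out-prefix tumor
bivarseg segment --input tumor.sample.tsv --out-prefix tumor_seg \
    --max-seg-length 400 --max-segments 80
bivarseg evaluate --predicted tumor_seg.changepoints.tsv \
    --truth tumor.truth.changepoints.tsv
```

The segment step logs

```
INFO bivarseg: chrom 1: n=2855 observed LRR=2855 imBAF=977 selected S=53 cost=147.989 (1.56s)
```

— 2855 probes, of which 977 carry informative imBAF, segmented into S = 53
segments with total energy G ≈ 148. The evaluation prints

```
n_true=50  n_predicted=52  sensitivity=1.0000  specificity=0.9615  f_measure=0.9804
```

all 50 true alteration boundaries recalled within the 3-probe window, with 2
of the 52 predicted boundaries spurious. `tumor_seg.segments.tsv` holds one
row per segment (probe range, genomic positions, per-variable means, δ_s):

```
chrom  start_probe  end_probe  ...  n_informative  mean_lrr    mean_imbaf  delta
1      0            60         ...  21             -0.00381168 0.661906    3.09574
1      60           72         ...  2              0.455884    0.89516     0.564251
```

(the second row is a 12-probe gain: mean LRR ≈ 0.46 ≈ log2(3/2) and mBAF
≈ 0.9, a three-copy segment with allelic imbalance).

The same pipeline is available as library calls: `to_imbaf` →
`impute_constant` → `optimal_segmentation` → `select_model`, with
`generate_profile`/`simulate_sample` for synthetic data and
`score`/`roc_sweep` for evaluation.

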