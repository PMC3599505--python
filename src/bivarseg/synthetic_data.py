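"""Synthetic SNP-array tumour samples with known copy-number truth.

Generates Illumina-like probe tables (LRR + BAF) from a two-population
mixture model: a tumour cell fraction ``1 - w`` carrying the simulated
alterations and a normal diploid fraction ``w`` (the contamination).  For
a probe with tumour copy number ``c`` carrying ``b`` copies of the B
allele, and germline B-allele count ``b_n`` (0, 1 or 2 by genotype), the
expected signals are::

    LRR = log2( (w*2 + (1-w)*c) / 2 ) + baseline_shift
    BAF = (w*b_n + (1-w)*b) / (w*2 + (1-w)*c)

so both signals shrink towards their diploid values as contamination
grows.  ``baseline_shift`` models the renormalisation of LRR to the
sample's overall ploidy (arrays are normalised so the genome-wide median
sits at 0, which re-centres non-diploid genomes).

Samples follow five qualitative alteration patterns -- near-diploid,
near-triploid, near-tetraploid, LOH-enriched and complex -- each laying
fragments of copy number 1..5, with and without somatic or germline LOH,
spanning 10/20/40/80/160 probes on the pattern's background state, with
background spacers between fragments.  LRR noise is ~6x imBAF noise at
the defaults (sd 0.30 vs 0.05).

Germline genotypes are AB with probability ``het_rate`` (default 0.3),
else AA/BB equiprobably; probes inside germline-LOH regions are forced
homozygous.  Because which parental allele is labelled "B" is arbitrary
per SNP, heterozygous probes carry ``b`` or ``c - b`` B alleles with equal
probability; mirroring makes the two choices equivalent in mBAF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_transform import ProbeTrack, mirror_baf

__all__ = [
    "AlterationSpec",
    "GeneratorConfig",
    "TruthProfile",
    "expected_lrr",
    "expected_baf",
    "generate_profile",
    "profile_from_alterations",
    "simulate_sample",
    "detectable_changepoints",
    "PATTERNS",
]

# Per-pattern background state (copy_number, n_b_alleles) and alteration
# states (copy_number, n_b_alleles, loh_type) crossed with the length grid.
# The patterns are qualitative archetypes of tumour genomes: the
# quantitative layout (which states, spacers, lengths) is this generator's
# own definition and is fully configurable.
PATTERNS = {
    "near_diploid": {
        "background": (2, 1),
        "states": [
            (1, 0, "somatic"),
            (3, 1, "none"),
            (3, 0, "somatic"),
            (4, 2, "none"),
            (5, 1, "none"),
        ],
        "extra_germline": 0,
    },
    "near_triploid": {
        "background": (3, 1),
        "states": [
            (1, 0, "somatic"),
            (2, 1, "none"),
            (2, 0, "somatic"),
            (4, 2, "none"),
            (5, 2, "none"),
        ],
        "extra_germline": 0,
    },
    "near_tetraploid": {
        "background": (4, 2),
        "states": [
            (1, 0, "somatic"),
            (2, 1, "none"),
            (2, 0, "somatic"),
            (3, 1, "none"),
            (5, 2, "none"),
        ],
        "extra_germline": 0,
    },
    "loh_enriched": {
        "background": (2, 1),
        "states": [
            (1, 0, "somatic"),
            (2, 0, "somatic"),
            (3, 0, "somatic"),
            (4, 0, "somatic"),
            (2, 0, "germline"),
        ],
        "extra_germline": 2,  # additional long germline-LOH stretches
    },
    "complex": {
        "background": (2, 1),
        "states": [
            (1, 0, "somatic"),
            (3, 1, "none"),
            (3, 0, "somatic"),
            (4, 2, "none"),
            (5, 1, "none"),
            (2, 0, "somatic"),
            (2, 0, "germline"),
        ],
        "extra_germline": 0,
    },
}

EXTRA_GERMLINE_LENGTH = 240


@dataclass(frozen=True)
class AlterationSpec:
    """One placed alteration: tumour state over a probe range.

    LOH holds iff ``n_b_alleles`` is 0 or ``copy_number`` (one parental
    allele absent).  ``loh_type`` distinguishes somatically acquired LOH
    from constitutive (germline) homozygosity.
    """

    start_probe: int
    n_probes: int
    copy_number: int
    n_b_alleles: int
    loh_type: str = "none"  # none | somatic | germline
    cell_fraction: float = 1.0  # fraction of tumour cells carrying it (subclones)

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if not (0 <= self.n_b_alleles <= self.copy_number):
            raise ValueError(
                f"n_b_alleles {self.n_b_alleles} outside [0, {self.copy_number}]"
            )
        if self.loh_type not in ("none", "somatic", "germline"):
            raise ValueError(f"unknown loh_type {self.loh_type!r}")
        if not (0.0 < self.cell_fraction <= 1.0):
            raise ValueError("cell_fraction must be in (0, 1]")

    @property
    def end_probe(self) -> int:
        return self.start_probe + self.n_probes


@dataclass
class GeneratorConfig:
    """Benchmark sample recipe.

    ``contamination`` is the normal-cell fraction w (benchmark grid
    0/0.25/0.50/0.75).  Noise defaults honour the ~6:1 LRR-to-imBAF
    standard-deviation ratio of real Illumina data.  ``baseline_shift``
    None means "derive from the pattern's mixture ploidy" (median-centred
    LRR); ``n_probes_total`` None sizes the genome to fit the layout.
    """

    pattern: str = "near_diploid"
    contamination: float = 0.0
    sd_lrr: float = 0.30
    sd_baf: float = 0.05
    het_rate: float = 0.30
    missing_baf_rate: float = 0.05
    baseline_shift: float | None = None
    n_probes_total: int | None = None
    seed: int = 0
    alteration_lengths: tuple = (10, 20, 40, 80, 160)
    spacer: int = 40
    spacer_jitter: int = 20
    margin: int = 60
    lrr_floor: float = -5.0
    probe_spacing_bp: int = 1000
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {sorted(PATTERNS)}")
        if not (0.0 <= self.contamination <= 1.0):
            raise ValueError("contamination must be in [0, 1]")
        if self.sd_lrr < 0 or self.sd_baf < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not (0.0 <= self.het_rate <= 1.0):
            raise ValueError("het_rate must be in [0, 1]")
        if not (0.0 <= self.missing_baf_rate < 1.0):
            raise ValueError("missing_baf_rate must be in [0, 1)")

    def resolved_baseline_shift(self) -> float:
        """LRR re-centring so the background (mixture) state reads 0."""
        if self.baseline_shift is not None:
            return self.baseline_shift
        bg_copy = PATTERNS[self.pattern]["background"][0]
        w = self.contamination
        mixture_ploidy = w * 2.0 + (1.0 - w) * bg_copy
        return -math.log2(mixture_ploidy / 2.0)


@dataclass
class TruthProfile:
    """Per-probe ground truth plus the true change-point set.

    ``true_changepoints`` are the series indices t where the tumour state
    (copy_number, n_b_alleles, loh_type) of probe t differs from probe
    t - 1, matching the half-open boundary convention of the segmenter.
    """

    copy_number: np.ndarray
    n_b_alleles: np.ndarray
    loh_type: np.ndarray
    genotype: np.ndarray  # germline: AA / AB / BB
    cell_fraction: np.ndarray  # tumour-cell fraction carrying the local state
    true_changepoints: np.ndarray
    alterations: list
    background: tuple  # (copy_number, n_b_alleles) of the background state

    @property
    def n(self) -> int:
        return len(self.copy_number)

    @property
    def informative(self) -> np.ndarray:
        """Probes whose germline genotype carries allelic-ratio information."""
        return self.genotype == "AB"


def expected_lrr(copy_number, contamination: float, baseline_shift: float = 0.0, floor: float = -5.0):
    """Expected LRR of a tumour/normal mixture, relative to diploid.

    ``log2((w*2 + (1-w)*c) / 2) + baseline_shift``; a mixture with zero
    total copy (homozygous deletion in a pure tumour) returns the
    configured floor instead of -infinity.
    """
    c = np.asarray(copy_number, dtype=float)
    w = contamination
    if not (0.0 <= w <= 1.0):
        raise ValueError("contamination must be in [0, 1]")
    if np.any(c < 0):
        raise ValueError("copy_number must be >= 0")
    mixture = w * 2.0 + (1.0 - w) * c
    with np.errstate(divide="ignore"):
        out = np.where(mixture > 0, np.log2(np.maximum(mixture, 1e-300) / 2.0) + baseline_shift, floor)
    if np.isscalar(copy_number):
        return float(out)
    return out


def expected_baf(n_b_tumour, copy_tumour, n_b_normal, contamination: float):
    """Expected BAF of a tumour/normal mixture at a SNP.

    ``(w*b_n + (1-w)*b) / (w*2 + (1-w)*c)`` -- the B-allele share of all
    allele copies in the cell mixture.
    """
    b = np.asarray(n_b_tumour, dtype=float)
    c = np.asarray(copy_tumour, dtype=float)
    bn = np.asarray(n_b_normal, dtype=float)
    w = contamination
    if np.any(b < 0) or np.any(b > c):
        raise ValueError("n_b_tumour must lie in [0, copy_tumour]")
    if np.any((bn < 0) | (bn > 2)):
        raise ValueError("n_b_normal must be 0, 1 or 2")
    denom = w * 2.0 + (1.0 - w) * c
    if np.any(denom <= 0):
        raise ValueError("mixture has zero total copy number; BAF undefined")
    out = (w * bn + (1.0 - w) * b) / denom
    if np.isscalar(n_b_tumour) and np.isscalar(copy_tumour):
        return float(out)
    return out


def _pattern_alterations(config: GeneratorConfig, rng: np.random.Generator):
    """Draw the alteration layout: shuffled state x length grid with spacers."""
    pat = PATTERNS[config.pattern]
    items = [
        (c, b, loh, length)
        for (c, b, loh) in pat["states"]
        for length in config.alteration_lengths
    ]
    items += [(2, 0, "germline", EXTRA_GERMLINE_LENGTH)] * pat["extra_germline"]
    order = rng.permutation(len(items))
    specs = []
    cursor = config.margin
    for idx in order:
        c, b, loh, length = items[idx]
        specs.append(AlterationSpec(cursor, length, c, b, loh))
        cursor += length + config.spacer
        if config.spacer_jitter > 0:
            cursor += int(rng.integers(0, config.spacer_jitter + 1))
    needed = cursor - config.spacer + config.margin
    return specs, needed


def _fill_profile(specs, n, background, config: GeneratorConfig, rng) -> TruthProfile:
    bg_c, bg_b = background
    cn = np.full(n, bg_c, dtype=np.int64)
    nb = np.full(n, bg_b, dtype=np.int64)
    loh = np.full(n, "none", dtype="<U8")
    cf = np.ones(n)
    for a in specs:
        if a.start_probe < 0 or a.end_probe > n:
            raise ValueError(f"alteration [{a.start_probe}, {a.end_probe}) outside [0, {n})")
        cn[a.start_probe : a.end_probe] = a.copy_number
        nb[a.start_probe : a.end_probe] = a.n_b_alleles
        loh[a.start_probe : a.end_probe] = a.loh_type
        cf[a.start_probe : a.end_probe] = a.cell_fraction

    # germline genotypes; germline-LOH regions are constitutively homozygous
    het = rng.random(n) < config.het_rate
    het[loh == "germline"] = False
    hom_is_bb = rng.random(n) < 0.5
    genotype = np.where(het, "AB", np.where(hom_is_bb, "BB", "AA")).astype("<U2")

    state_change = (
        (np.diff(cn) != 0)
        | (np.diff(nb) != 0)
        | (loh[1:] != loh[:-1])
        | (np.diff(cf) != 0)
    )
    cps = np.where(state_change)[0] + 1
    return TruthProfile(
        copy_number=cn,
        n_b_alleles=nb,
        loh_type=loh,
        genotype=genotype,
        cell_fraction=cf,
        true_changepoints=cps.astype(np.int64),
        alterations=list(specs),
        background=(bg_c, bg_b),
    )


def generate_profile(config: GeneratorConfig):
    """Lay out the pattern's alterations and derive the ground truth.

    Returns ``(alterations, TruthProfile)``.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 11])
    specs, needed = _pattern_alterations(config, rng)
    n = config.n_probes_total if config.n_probes_total is not None else needed
    if n < needed:
        raise ValueError(
            f"n_probes_total = {n} too small for the {config.pattern!r} layout "
            f"(needs {needed} probes)"
        )
    truth = _fill_profile(specs, n, PATTERNS[config.pattern]["background"], config, rng)
    return specs, truth


def profile_from_alterations(alterations, n_probes_total: int, config: GeneratorConfig,
                             background: tuple | None = None) -> TruthProfile:
    """Ground truth for an explicit alteration layout (e.g. subclonal states).

    Bypasses the pattern tables: alterations (which may carry
    ``cell_fraction`` < 1 to emulate intra-tumour heterogeneity) are placed
    verbatim on the given background.  Deterministic given ``config.seed``.
    """
    spans = sorted((a.start_probe, a.end_probe) for a in alterations)
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if e0 > s1:
            raise ValueError("alterations overlap")
    rng = np.random.default_rng([config.seed, 11])
    bg = background if background is not None else PATTERNS[config.pattern]["background"]
    return _fill_profile(list(alterations), n_probes_total, bg, config, rng)


def simulate_sample(profile: TruthProfile, config: GeneratorConfig) -> ProbeTrack:
    """Realise noisy LRR/BAF observations around the mixture expectations.

    Deterministic given ``config.seed`` (an RNG stream independent of the
    layout stream, so the same profile can be re-noised by varying seed).
    """
    rng = np.random.default_rng([config.seed, 23])
    n = profile.n
    w = config.contamination
    shift = config.resolved_baseline_shift()

    c = profile.copy_number
    b_region = profile.n_b_alleles
    gt = profile.genotype
    cf = profile.cell_fraction
    bg_c, bg_b = profile.background
    n_b_normal = np.where(gt == "AB", 1, np.where(gt == "BB", 2, 0))

    # tumour B-allele count per probe: region value (or its mirror, since the
    # B label is arbitrary per SNP) at heterozygous probes; 0 or c at
    # homozygous probes, whose single germline allele is simply re-counted.
    # Subclonal alterations (cell_fraction < 1) mix the altered state with
    # the tumour background state, the same mirror pick applying to both.
    mirror_pick = rng.random(n) < 0.5
    b_alt = np.where(mirror_pick, b_region, c - b_region)
    b_alt = np.where(gt == "AB", b_alt, np.where(gt == "BB", c, 0))
    b_bg = np.where(mirror_pick, bg_b, bg_c - bg_b)
    b_bg = np.where(gt == "AB", b_bg, np.where(gt == "BB", bg_c, 0))
    c_eff = cf * c + (1.0 - cf) * bg_c
    b_eff = cf * b_alt + (1.0 - cf) * b_bg

    lrr = expected_lrr(c_eff, w, shift, floor=config.lrr_floor)
    baf = expected_baf(b_eff, c_eff, n_b_normal, w)
    if config.sd_lrr > 0:
        lrr = lrr + rng.normal(0.0, config.sd_lrr, n)
    if config.sd_baf > 0:
        baf = np.clip(baf + rng.normal(0.0, config.sd_baf, n), 0.0, 1.0)
    if config.missing_baf_rate > 0:
        baf = np.where(rng.random(n) < config.missing_baf_rate, np.nan, baf)

    return ProbeTrack(
        chrom=config.chrom,
        probe_id=np.array([f"P{i + 1:06d}" for i in range(n)], dtype=object),
        position=(np.arange(n, dtype=np.int64) + 1) * config.probe_spacing_bp,
        lrr=np.asarray(lrr, dtype=float),
        baf=np.asarray(baf, dtype=float),
    )


def _region_signal(c, b, loh: str, w: float, hom_threshold: float, het_rate: float):
    """(expected LRR sans shift, informative?, expected het mBAF) of a state.

    ``c`` and ``b`` may be fractional (subclonal mixtures of the altered and
    background states).
    """
    lrr = expected_lrr(float(c), w, 0.0)
    if het_rate <= 0 or loh == "germline":
        return lrr, False, float("nan")
    mbaf = mirror_baf(expected_baf(float(b), float(c), 1, w))
    return lrr, mbaf < hom_threshold, mbaf


def detectable_changepoints(
    profile: TruthProfile,
    config: GeneratorConfig,
    hom_threshold: float = 0.95,
    tol: float = 1e-9,
) -> np.ndarray:
    """True change-points visible to the LRR/imBAF pipeline in expectation.

    A boundary is detectable if the flanking states differ in expected LRR,
    or if both flanks retain informative heterozygous probes (mBAF below the
    homozygosity threshold) and differ in expected mBAF.  Boundaries of
    copy-neutral germline-LOH regions, and of copy-neutral somatic LOH in a
    pure tumour, produce no signal change after the imBAF transform and are
    excluded: an unpaired-sample pipeline cannot see them.
    """
    w = config.contamination
    bg_c, bg_b = profile.background
    out = []

    def _effective(i):
        cf = profile.cell_fraction[i]
        c_eff = cf * profile.copy_number[i] + (1.0 - cf) * bg_c
        b_eff = cf * profile.n_b_alleles[i] + (1.0 - cf) * bg_b
        return c_eff, b_eff

    for t in profile.true_changepoints:
        cl, bl = _effective(t - 1)
        cr, br = _effective(t)
        left = _region_signal(cl, bl, profile.loh_type[t - 1], w, hom_threshold, config.het_rate)
        right = _region_signal(cr, br, profile.loh_type[t], w, hom_threshold, config.het_rate)
        if abs(left[0] - right[0]) > tol:
            out.append(t)
        elif left[1] and right[1] and abs(left[2] - right[2]) > tol:
            out.append(t)
    return np.asarray(out, dtype=np.int64)
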