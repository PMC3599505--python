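"""Transformation of raw SNP-array signals into the bivariate segmentation substrate.

SNP arrays report two signals per probe: the log R ratio (LRR), a log2
measure of total copy number, and the B allele frequency (BAF), the relative
intensity contribution of one of the two alleles.  BAF is awkward to segment
directly because heterozygous states split into two symmetric bands (e.g.
AAB regions show bands near 1/3 and 2/3).  The standard remedy is:

1. mirror BAF along the 0.5 axis, giving mirrored BAF (mBAF) on [0.5, 1];
2. drop non-informative SNPs -- homozygous probes, whose mBAF sits in a
   band near 1 regardless of copy number -- leaving informative mirrored
   BAF (imBAF).

imBAF has a high rate of missing values (every homozygous or
non-polymorphic probe).  For a bivariate method, dropping those probes
would also discard their perfectly good LRR observations, so missing
values are instead imputed by constant (last-observation-carried-forward)
interpolation.  Linear interpolation is deliberately avoided: it inserts
values between imBAF bands and distorts the piecewise-constant profile.
The pre-imputation observation masks are preserved because the downstream
segment cost weights each variable by its number of truly observed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ProbeTrack",
    "BivariateSeries",
    "mirror_baf",
    "classify_informative",
    "to_imbaf",
    "impute_constant",
]

DEFAULT_HOM_THRESHOLD = 0.95


@dataclass
class ProbeTrack:
    """Ordered probe series for one chromosome, carrying raw LRR and BAF.

    Missing values are encoded as NaN.  Positions are 1-based genomic
    coordinates and must be strictly increasing.
    """

    chrom: str
    probe_id: np.ndarray
    position: np.ndarray
    lrr: np.ndarray
    baf: np.ndarray

    def __post_init__(self) -> None:
        self.probe_id = np.asarray(self.probe_id, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        n = len(self.probe_id)
        if n == 0:
            raise ValueError(f"empty probe track for chromosome {self.chrom!r}")
        for name in ("position", "lrr", "baf"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} has length mismatch on chromosome {self.chrom!r}")
        if n > 1 and not np.all(np.diff(self.position) > 0):
            bad = np.where(np.diff(self.position) <= 0)[0]
            ids = ", ".join(str(self.probe_id[i + 1]) for i in bad[:5])
            raise ValueError(
                f"positions not strictly increasing on chromosome {self.chrom!r} "
                f"(first offending probes: {ids})"
            )
        obs = ~np.isnan(self.baf)
        if np.any((self.baf[obs] < 0.0) | (self.baf[obs] > 1.0)):
            bad = np.where(obs & ((self.baf < 0.0) | (self.baf > 1.0)))[0]
            ids = ", ".join(str(self.probe_id[i]) for i in bad[:5])
            raise ValueError(f"BAF outside [0, 1] at probes: {ids}")

    def __len__(self) -> int:
        return len(self.probe_id)

    @property
    def n(self) -> int:
        return len(self.probe_id)


@dataclass
class BivariateSeries:
    """Aligned LRR / imBAF arrays with per-variable observation masks.

    ``lrr_observed`` / ``imbaf_observed`` record which entries were truly
    measured *before* any imputation; only those entries contribute to
    segment means, residual sums of squares and the per-variable
    observation counts used by the segment cost.  ``index_map`` maps each
    series index back to the row of the source probe track.
    """

    lrr: np.ndarray
    imbaf: np.ndarray
    lrr_observed: np.ndarray
    imbaf_observed: np.ndarray
    index_map: np.ndarray = None
    chrom: str = ""
    _prefix_cache: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.imbaf = np.asarray(self.imbaf, dtype=float)
        self.lrr_observed = np.asarray(self.lrr_observed, dtype=bool)
        self.imbaf_observed = np.asarray(self.imbaf_observed, dtype=bool)
        n = len(self.lrr)
        if n < 1:
            raise ValueError("empty series")
        if not (len(self.imbaf) == len(self.lrr_observed) == len(self.imbaf_observed) == n):
            raise ValueError("series arrays have mismatched lengths")
        if self.index_map is None:
            self.index_map = np.arange(n, dtype=np.int64)
        else:
            self.index_map = np.asarray(self.index_map, dtype=np.int64)
            if len(self.index_map) != n:
                raise ValueError("index_map length mismatch")
        ob = self.imbaf[self.imbaf_observed]
        ob = ob[~np.isnan(ob)]
        if ob.size and (ob.min() < 0.5 - 1e-12 or ob.max() > 1.0 + 1e-12):
            raise ValueError("observed imBAF values must lie on the mirrored scale [0.5, 1]")

    def __len__(self) -> int:
        return len(self.lrr)

    @property
    def n(self) -> int:
        return len(self.lrr)

    @property
    def n_observed(self) -> int:
        """Total count of observed values across both variables (the BIC N)."""
        return int(self.lrr_observed.sum() + self.imbaf_observed.sum())


def mirror_baf(baf, probe_id=None):
    """Mirror BAF along the 0.5 axis: ``|baf - 0.5| + 0.5``.

    Accepts scalars or arrays; NaN (missing) propagates.  Values outside
    [0, 1] raise, naming the offending probe when ``probe_id`` is given.
    """
    arr = np.asarray(baf, dtype=float)
    obs = ~np.isnan(arr)
    bad = obs & ((arr < 0.0) | (arr > 1.0))
    if np.any(bad):
        if probe_id is not None:
            ids = ", ".join(str(p) for p in np.asarray(probe_id, dtype=object)[np.atleast_1d(bad)][:5])
        else:
            ids = ", ".join(str(i) for i in np.where(np.atleast_1d(bad))[0][:5])
        raise ValueError(f"BAF outside [0, 1] at: {ids}")
    out = np.abs(arr - 0.5) + 0.5
    if np.isscalar(baf) or arr.ndim == 0:
        return float(out)
    return out


def classify_informative(mbaf, hom_threshold: float = DEFAULT_HOM_THRESHOLD):
    """Flag informative SNPs: observed mBAF strictly below the homozygous band.

    Homozygous probes have mBAF close to 1 and carry no allelic-ratio
    information about the segment they sit in; they are removed before
    segmentation.  Missing mBAF is non-informative by definition.
    """
    if not (0.5 < hom_threshold <= 1.0):
        raise ValueError(f"hom_threshold must be in (0.5, 1], got {hom_threshold}")
    arr = np.asarray(mbaf, dtype=float)
    obs = ~np.isnan(arr)
    vals = arr[obs]
    if vals.size and (vals.min() < 0.5 - 1e-12 or vals.max() > 1.0 + 1e-12):
        raise ValueError("mBAF values must lie in [0.5, 1]")
    out = obs & (arr < hom_threshold)
    if np.isscalar(mbaf) or arr.ndim == 0:
        return bool(out)
    return out


def to_imbaf(track: ProbeTrack, hom_threshold: float = DEFAULT_HOM_THRESHOLD) -> BivariateSeries:
    """Build the bivariate LRR / imBAF series for one chromosome.

    imBAF is present exactly at informative probes and missing (NaN)
    elsewhere; LRR is copied through with its own missingness.  The
    returned masks reflect the pre-imputation observation state.
    """
    mbaf = mirror_baf(track.baf, probe_id=track.probe_id)
    informative = classify_informative(mbaf, hom_threshold)
    imbaf = np.where(informative, mbaf, np.nan)
    return BivariateSeries(
        lrr=track.lrr.copy(),
        imbaf=imbaf,
        lrr_observed=~np.isnan(track.lrr),
        imbaf_observed=informative,
        index_map=np.arange(track.n, dtype=np.int64),
        chrom=track.chrom,
    )


def _ffill_with_head_backfill(values: np.ndarray, mask: np.ndarray, what: str, chrom: str) -> np.ndarray:
    if not mask.any():
        raise ValueError(
            f"no observed {what} values on chromosome {chrom!r}; the bivariate model "
            "cannot be fitted here -- run a univariate (LRR-only) segmentation for "
            "this chromosome instead"
        )
    idx = np.where(mask, np.arange(len(values)), -1)
    idx = np.maximum.accumulate(idx)
    first = np.argmax(mask)  # first observed index
    idx[idx < 0] = first
    return values[idx]


def impute_constant(series: BivariateSeries) -> BivariateSeries:
    """Replace missing values by constant interpolation (carry-forward).

    Each missing value takes the nearest preceding observed value of the
    same variable; leading missing values take the first observed value.
    Observed masks are unchanged -- imputed entries still carry zero
    weight in the segment cost.
    """
    lrr = _ffill_with_head_backfill(series.lrr, series.lrr_observed, "LRR", series.chrom)
    imbaf = _ffill_with_head_backfill(series.imbaf, series.imbaf_observed, "imBAF", series.chrom)
    return replace(series, lrr=lrr, imbaf=imbaf, _prefix_cache=None)
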