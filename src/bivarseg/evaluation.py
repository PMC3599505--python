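"""Windowed change-point scoring: sensitivity, specificity, F-measure, ROC sweeps.

A true change-point is *recalled* if at least one predicted change-point
falls within a window of +/- ``window`` probes (default 3) from it; a
predicted change-point is *matched* if it falls within the window of some
true change-point.  Sensitivity is the fraction of true change-points
recalled; "specificity" is the fraction of (distinct) predictions that
are matched -- a precision-like reading under which repeated calls of the
same change-point are not penalised.  The F-measure is the harmonic mean
of the two.

Only interior boundaries are scored: the trivial change-points at 0 and n
exist in every segmentation by construction and must be stripped before
calling :func:`score` (use ``SegmentationResult.interior_changepoints``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_selection import select_model
from .scm_core import optimal_segmentation

__all__ = [
    "EvalReport",
    "match_changepoints",
    "score",
    "recall_by_length",
    "roc_sweep",
]

DEFAULT_WINDOW = 3


@dataclass
class EvalReport:
    n_true: int
    n_predicted: int
    n_recalled_true: int
    n_matched_predictions: int
    sensitivity: float
    specificity: float
    f_measure: float
    window: int = DEFAULT_WINDOW


def _as_sorted_unique(cps) -> np.ndarray:
    return np.unique(np.asarray(cps, dtype=np.int64))


def match_changepoints(true_cps, predicted_cps, window: int = DEFAULT_WINDOW):
    """Return ``(recalled_true, matched_predictions)`` under the +/-window rule.

    Duplicate predictions of the same true change-point all count as
    matched, so they do not reduce specificity.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    t = _as_sorted_unique(true_cps)
    p = _as_sorted_unique(predicted_cps)
    if t.size == 0 or p.size == 0:
        return t[:0], p[:0]
    dist = np.abs(t[:, None] - p[None, :])
    recalled = t[(dist <= window).any(axis=1)]
    matched = p[(dist <= window).any(axis=0)]
    return recalled, matched


def score(true_cps, predicted_cps, window: int = DEFAULT_WINDOW) -> EvalReport:
    """Score a prediction against truth under the windowed matching rule.

    Conventions for the degenerate cases: sensitivity is 1 when there are
    no true change-points, specificity is 1 when nothing is predicted, and
    the F-measure is 0 whenever either component is 0.
    """
    t = _as_sorted_unique(true_cps)
    p = _as_sorted_unique(predicted_cps)
    recalled, matched = match_changepoints(t, p, window)
    sens = 1.0 if t.size == 0 else recalled.size / t.size
    spec = 1.0 if p.size == 0 else matched.size / p.size
    f = 0.0 if (sens == 0.0 or spec == 0.0) else 2.0 * sens * spec / (sens + spec)
    return EvalReport(
        n_true=int(t.size),
        n_predicted=int(p.size),
        n_recalled_true=int(recalled.size),
        n_matched_predictions=int(matched.size),
        sensitivity=float(sens),
        specificity=float(spec),
        f_measure=float(f),
        window=window,
    )


def recall_by_length(alterations, predicted_cps, window: int = DEFAULT_WINDOW,
                     eligible_cps=None) -> pd.DataFrame:
    """Per-alteration-length recall of alteration boundaries.

    Each alteration contributes its start and end boundary; a boundary
    counts as recalled if a prediction lies within the window.  If
    ``eligible_cps`` is given, boundaries outside it (e.g. ones invisible
    to the pipeline in expectation) are excluded from the denominator.
    """
    p = _as_sorted_unique(predicted_cps)
    eligible = None if eligible_cps is None else set(int(x) for x in np.asarray(eligible_cps))
    rows = {}
    for a in alterations:
        for cp in (a.start_probe, a.end_probe):
            if eligible is not None and cp not in eligible:
                continue
            hit = bool(p.size) and bool((np.abs(p - cp) <= window).any())
            n_tot, n_hit = rows.get(a.n_probes, (0, 0))
            rows[a.n_probes] = (n_tot + 1, n_hit + int(hit))
    table = pd.DataFrame(
        [
            {"length": length, "n_boundaries": tot, "n_recalled": hit,
             "recall": hit / tot if tot else float("nan")}
            for length, (tot, hit) in sorted(rows.items())
        ]
    )
    return table


def roc_sweep(samples, penalty_grid, config, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Sweep the model-selection penalty k into an ROC table.

    ``samples`` is a list of ``(series, truth)`` pairs where ``truth`` is
    either an array of true change-point indices or an object with a
    ``true_changepoints`` attribute.  The dynamic programme runs once per
    sample; only the model selection is repeated across the grid.  Rows
    are sorted by ``penalty_k``.
    """
    grid = sorted(float(k) for k in penalty_grid)
    if not grid or not samples:
        raise ValueError("need a non-empty penalty grid and at least one sample")
    prepared = []
    for series, truth in samples:
        cps = getattr(truth, "true_changepoints", truth)
        results = optimal_segmentation(series, config)
        prepared.append((results, series.n_observed, np.asarray(cps, dtype=np.int64)))
    rows = []
    for k in grid:
        reports = []
        for results, n_obs, true_cps in prepared:
            best = select_model(results, n_obs, penalty_k=k)
            reports.append(score(true_cps, best.interior_changepoints, window))
        rows.append(
            {
                "penalty_k": k,
                "sensitivity": float(np.mean([r.sensitivity for r in reports])),
                "specificity": float(np.mean([r.specificity for r in reports])),
                "f_measure": float(np.mean([r.f_measure for r in reports])),
            }
        )
    return pd.DataFrame(rows)
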