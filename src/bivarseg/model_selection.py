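"""Choosing the number of segments by BIC-penalised Gaussian log-likelihood.

The dynamic programme returns, for every candidate segment count S, the
minimum total energy delta (the fitted residual cost).  Assuming
independent Gaussian residuals, the profile log-likelihood of the
S-segment model, penalised in BIC fashion, is::

    logL = -N/2 * (1 + log(2*pi*delta/N)) - k * S * log(N)

where N is the number of observations and k scales the penalty (k = 1 is
plain BIC; smaller k yields more change-points, larger k fewer -- the
sensitivity dial of the method).  Under missingness N counts the observed
values across both variables, i.e. exactly the values that contribute to
delta.

A perfect fit (delta = 0, e.g. on noiseless data) would send the log term
to -infinity; delta is floored at N times machine epsilon so perfect fits
compare among themselves purely through the segment-count penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ModelScore", "bic_loglik", "score_models", "select_model"]


@dataclass
class ModelScore:
    n_segments: int
    total_cost: float
    n_obs: int
    penalty_k: float
    loglik: float


def bic_loglik(total_cost: float, n_obs: int, n_segments: int, penalty_k: float = 1.0) -> float:
    """BIC-penalised log-likelihood of a fitted S-segment model."""
    if n_obs < 2:
        raise ValueError(f"need at least 2 observations, got {n_obs}")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if total_cost < 0:
        raise ValueError("total_cost must be non-negative")
    floor = n_obs * 2.220446049250313e-16  # N * machine epsilon
    delta = max(total_cost, floor)
    n = float(n_obs)
    return -n / 2.0 * (1.0 + math.log(2.0 * math.pi * delta / n)) - penalty_k * n_segments * math.log(n)


def score_models(results, n_obs: int, penalty_k: float = 1.0):
    """Score every candidate segmentation; results must be one per S."""
    return [
        ModelScore(
            n_segments=r.n_segments,
            total_cost=r.total_cost,
            n_obs=n_obs,
            penalty_k=penalty_k,
            loglik=bic_loglik(r.total_cost, n_obs, r.n_segments, penalty_k),
        )
        for r in results
    ]


def select_model(results, n_obs: int, penalty_k: float = 1.0):
    """Return the candidate segmentation maximising the penalised log-likelihood.

    Ties break toward the smaller segment count (parsimony).
    """
    if not results:
        raise ValueError("no candidate segmentations to select from")
    ordered = sorted(results, key=lambda r: r.n_segments)
    best = None
    best_ll = -math.inf
    for r in ordered:
        ll = bic_loglik(r.total_cost, n_obs, r.n_segments, penalty_k)
        if ll > best_ll:
            best_ll = ll
            best = r
    return best
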