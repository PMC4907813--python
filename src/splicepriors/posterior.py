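"""Bayesian combination of a prior with observational likelihood ratios.

posterior odds = prior odds x product(LR); the posterior probability is then
mapped to the five-tier IARC classification (1 = not pathogenic ... 5 =
pathogenic) by posterior-probability cut-points.  Computation is done in
log-odds space so very large LR products do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "IarcCutpoints",
    "ClassificationResult",
    "posterior",
    "iarc_class",
    "sufficient_observational_data",
    "classify",
]


@dataclass(frozen=True)
class IarcCutpoints:
    """Posterior-probability class boundaries.

    Defaults: class 5 p > 0.99; class 4 0.95 <= p <= 0.99; class 3
    0.05 <= p < 0.95; class 2 0.001 <= p < 0.05; class 1 p < 0.001.
    """

    class5_above: float = 0.99  # strict
    class4_at_least: float = 0.95
    class3_at_least: float = 0.05
    class2_at_least: float = 0.001


def posterior(prior: float, lrs: Sequence[float]) -> float:
    """Posterior probability of pathogenicity.

    ``prior`` must lie strictly inside (0, 1) — priors of exactly 0 or 1
    cannot be used in a Bayesian calculation — and every LR must be positive.
    """
    if not 0 < prior < 1:
        raise ValueError(
            f"prior must lie strictly in (0, 1); got {prior} (priors of 0.00 "
            "cannot be used in a Bayesian calculation)"
        )
    for lr in lrs:
        if not (lr > 0 and math.isfinite(lr)):
            raise ValueError(f"likelihood ratios must be finite and > 0; got {lr}")
    # fsum keeps the combination exactly order-invariant
    log_odds = math.fsum(
        [math.log(prior) - math.log1p(-prior), *(math.log(lr) for lr in lrs)]
    )
    # logistic of the log odds
    if log_odds >= 0:
        return 1.0 / (1.0 + math.exp(-log_odds))
    e = math.exp(log_odds)
    return e / (1.0 + e)


def iarc_class(p: float, cutpoints: IarcCutpoints = IarcCutpoints()) -> int:
    """Five-tier class of a posterior probability."""
    if not 0 <= p <= 1:
        raise ValueError(f"posterior must lie in [0, 1]; got {p}")
    if p > cutpoints.class5_above:
        return 5
    if p >= cutpoints.class4_at_least:
        return 4
    if p >= cutpoints.class3_at_least:
        return 3
    if p >= cutpoints.class2_at_least:
        return 2
    return 1


def sufficient_observational_data(lrs: Sequence[float]) -> bool:
    """Whether the combined observational LR is informative enough for a
    valid integrated evaluation (product <= 0.5 or >= 2)."""
    log_product = 0.0
    for lr in lrs:
        if not (lr > 0 and math.isfinite(lr)):
            raise ValueError(f"likelihood ratios must be finite and > 0; got {lr}")
        log_product += math.log(lr)
    return log_product <= math.log(0.5) or log_product >= math.log(2.0)


@dataclass(frozen=True)
class ClassificationResult:
    prior: float
    lrs: tuple[float, ...]
    posterior: float
    iarc_class: int
    sufficient_data: bool


def classify(
    prior: float,
    lrs: Sequence[float],
    cutpoints: IarcCutpoints = IarcCutpoints(),
) -> ClassificationResult:
    """Full integrated evaluation of one variant."""
    p = posterior(prior, lrs)
    return ClassificationResult(
        prior=prior,
        lrs=tuple(float(x) for x in lrs),
        posterior=p,
        iarc_class=iarc_class(p, cutpoints),
        sufficient_data=sufficient_observational_data(lrs),
    )
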