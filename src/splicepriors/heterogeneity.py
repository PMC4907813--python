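"""Heterogeneity-likelihood estimation of the proportion pathogenic.

A stratum collects sequence variants with per-variant observational
likelihood ratios LR_v (e.g. summary family-history LRs: the probability of
the carriers' histories if the variant is pathogenic over the probability if
it is neutral).  Modelling each variant as pathogenic with probability
alpha, the stratum log-likelihood is

    l(alpha) = sum_v ln(alpha * LR_v + 1 - alpha)

alpha-hat maximizes l on [0, 1]; approximate 95% confidence bounds are the
points where l drops from its maximum by chi2(1, 0.95)/2 = 1.9207 (profile
likelihood-ratio bounds), clipped at 0 and 1.  Nested partitions of the same
variants into strata are compared by the likelihood-ratio chi-square with
df = difference in group counts.

Exact binomial (Clopper-Pearson) proportion utilities, including the
add-one-discordant-observation rule for degenerate 0/n or n/n tables, also
live here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "StratumObservations",
    "AlphaEstimate",
    "BinomialProportion",
    "loglik",
    "estimate_alpha",
    "compare_partitions",
    "exact_binomial",
    "simulate_stratum",
]

# chi2(df=1) 0.95 quantile / 2: profile-likelihood drop for a 95% CI
_CI_DROP = float(sps.chi2.ppf(0.95, df=1) / 2)


@dataclass(frozen=True)
class StratumObservations:
    """Per-variant combined observational likelihood ratios in one stratum."""

    label: str
    variant_lrs: tuple[float, ...]

    def __post_init__(self) -> None:
        lrs = np.asarray(self.variant_lrs, dtype=float)
        if lrs.size == 0:
            raise ValueError("stratum has no variants")
        if not np.all(np.isfinite(lrs)) or np.any(lrs < 0):
            raise ValueError("likelihood ratios must be finite and >= 0")
        object.__setattr__(self, "variant_lrs", tuple(float(x) for x in lrs))


@dataclass(frozen=True)
class AlphaEstimate:
    alpha_hat: float
    ci: tuple[float, float]
    log_likelihood: float
    identifiable: bool

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not 0 <= lo <= self.alpha_hat <= hi <= 1:
            raise ValueError("CI must satisfy 0 <= lo <= alpha <= hi <= 1")


def loglik(alpha: float, stratum: StratumObservations | Sequence[float]) -> float:
    """Mixture log-likelihood sum_v ln(alpha*LR_v + 1 - alpha)."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    lrs = np.asarray(
        stratum.variant_lrs if isinstance(stratum, StratumObservations) else stratum,
        dtype=float,
    )
    terms = alpha * lrs + (1.0 - alpha)
    if np.any(terms <= 0):
        return float("-inf")
    return float(np.log(terms).sum())


def estimate_alpha(
    stratum: StratumObservations | Sequence[float],
    ci_level: float = 0.95,
    tol: float = 1e-6,
) -> AlphaEstimate:
    """Maximum-likelihood proportion pathogenic with profile-likelihood CI."""
    lrs = tuple(
        stratum.variant_lrs if isinstance(stratum, StratumObservations) else stratum
    )
    if not lrs:
        raise ValueError("stratum has no variants")

    def nll(a: float) -> float:
        return -loglik(min(max(a, 0.0), 1.0), lrs)

    grid = np.linspace(0.0, 1.0, 201)
    grid_ll = np.array([loglik(a, lrs) for a in grid])
    if np.nanmax(grid_ll) - np.nanmin(grid_ll[np.isfinite(grid_ll)]) < 1e-10:
        # flat likelihood (all LRs ~ 1): alpha is unidentifiable
        return AlphaEstimate(
            alpha_hat=0.5,
            ci=(0.0, 1.0),
            log_likelihood=float(grid_ll[100]),
            identifiable=False,
        )
    a0 = float(grid[int(np.nanargmax(grid_ll))])
    lo_b = max(0.0, a0 - 0.01)
    hi_b = min(1.0, a0 + 0.01)
    res = optimize.minimize_scalar(
        nll, bounds=(lo_b, hi_b), method="bounded", options={"xatol": tol / 10}
    )
    alpha_hat = float(res.x)
    # the bounded optimum can sit at an interior grid point; also compare the
    # hard boundaries so a maximizer at exactly 0 or 1 is not missed
    candidates = [alpha_hat, 0.0, 1.0, a0]
    alpha_hat = max(candidates, key=lambda a: loglik(a, lrs))
    ll_max = loglik(alpha_hat, lrs)
    drop = sps.chi2.ppf(ci_level, df=1) / 2
    target = ll_max - drop

    def ci_side(lo: float, hi: float, increasing: bool) -> float:
        """Bisect for loglik == target on a monotone side of the maximum."""
        for _ in range(100):
            mid = (lo + hi) / 2
            if loglik(mid, lrs) >= target:
                if increasing:
                    hi = mid
                else:
                    lo = mid
            else:
                if increasing:
                    lo = mid
                else:
                    hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    alpha_l = 0.0 if loglik(0.0, lrs) >= target else ci_side(0.0, alpha_hat, True)
    alpha_u = 1.0 if loglik(1.0, lrs) >= target else ci_side(alpha_hat, 1.0, False)
    return AlphaEstimate(
        alpha_hat=alpha_hat,
        ci=(min(alpha_l, alpha_hat), max(alpha_u, alpha_hat)),
        log_likelihood=ll_max,
        identifiable=True,
    )


def compare_partitions(
    coarse: Mapping[str, Sequence[float]],
    fine: Mapping[str, Sequence[float]],
    membership: Mapping[str, str] | None = None,
) -> tuple[float, int, float]:
    """Likelihood-ratio test of a finer nested stratification.

    ``coarse`` and ``fine`` map group labels to per-variant LR lists; each
    fine group must lie entirely within one coarse group.  ``membership``
    maps fine labels to coarse labels; when omitted, nesting is checked by
    multiset containment of the LR lists.  Returns ``(chi_square, df, p)``
    with chi_square = 2 (lnL_fine - lnL_coarse) >= 0.
    """
    if membership is not None:
        grouped: dict[str, list[float]] = {k: [] for k in coarse}
        for f_label, lrs in fine.items():
            c_label = membership[f_label]
            if c_label not in grouped:
                raise ValueError(f"fine group {f_label!r} maps to unknown coarse group")
            grouped[c_label].extend(lrs)
        for label, lrs in grouped.items():
            if sorted(lrs) != sorted(coarse[label]):
                raise ValueError(
                    f"fine groups do not nest within coarse group {label!r}"
                )
    else:
        pooled_fine = sorted(x for lrs in fine.values() for x in lrs)
        pooled_coarse = sorted(x for lrs in coarse.values() for x in lrs)
        if pooled_fine != pooled_coarse:
            raise ValueError("partitions do not cover the same variants")
    ll_coarse = sum(estimate_alpha(lrs).log_likelihood for lrs in coarse.values())
    ll_fine = sum(estimate_alpha(lrs).log_likelihood for lrs in fine.values())
    chi_square = max(0.0, 2.0 * (ll_fine - ll_coarse))
    df = len(fine) - len(coarse)
    if df < 1:
        return chi_square, df, 1.0 if chi_square == 0 else float("nan")
    p = float(sps.chi2.sf(chi_square, df=df))
    return chi_square, df, p


@dataclass(frozen=True)
class BinomialProportion:
    proportion: float
    ci_low: float
    ci_high: float


def exact_binomial(
    x: int,
    n: int,
    level: float = 0.95,
    degenerate_rule: bool = False,
) -> BinomialProportion:
    """Clopper-Pearson exact binomial proportion and confidence interval.

    With ``degenerate_rule`` and x == 0 or x == n, one discordant observation
    is added to the zero-count outcome before computing the non-degenerate
    CI bound (the reported proportion stays x/n and the degenerate-side bound
    stays at the boundary).
    """
    if not (0 <= x <= n) or n < 1:
        raise ValueError(f"invalid counts x={x}, n={n}")
    alpha = 1 - level

    def cp(x_: int, n_: int) -> tuple[float, float]:
        lo = 0.0 if x_ == 0 else float(sps.beta.ppf(alpha / 2, x_, n_ - x_ + 1))
        hi = 1.0 if x_ == n_ else float(sps.beta.ppf(1 - alpha / 2, x_ + 1, n_ - x_))
        return lo, hi

    proportion = x / n
    if degenerate_rule and x == n:
        lo, _ = cp(x, n + 1)  # one added failure
        return BinomialProportion(proportion, lo, 1.0)
    if degenerate_rule and x == 0:
        _, hi = cp(1, n + 1)  # one added success
        return BinomialProportion(proportion, 0.0, hi)
    lo, hi = cp(x, n)
    return BinomialProportion(proportion, lo, hi)


def simulate_stratum(
    n_variants: int,
    alpha: float,
    rng: np.random.Generator,
    n_carriers: int = 3,
    positive_lr: float = 4.0,
    p_positive_pathogenic: float = 0.8,
    p_positive_neutral: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-variant observational LRs for a stratum.

    Each variant is pathogenic with probability ``alpha``.  Each of its
    ``n_carriers`` carriers has a "positive family history" with probability
    0.8 if the variant is pathogenic and 0.2 if neutral; a positive history
    contributes LR 4 (= 0.8/0.2) and a negative one LR 0.25 (= 0.2/0.8), and
    the variant's LR is the product over carriers.  Returns
    ``(lrs, is_pathogenic)``.
    """
    negative_lr = (1 - p_positive_pathogenic) / (1 - p_positive_neutral)
    is_path = rng.random(n_variants) < alpha
    p_pos = np.where(is_path, p_positive_pathogenic, p_positive_neutral)
    positives = rng.binomial(n_carriers, p_pos)
    lrs = positive_lr**positives * negative_lr ** (n_carriers - positives)
    return lrs, is_path
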