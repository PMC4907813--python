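"""Score standardization and calibrated prior probabilities of pathogenicity.

Raw splice-fitness scores are standardized to z-scores against the mean/SD of
a reference set of wild-type junctions (donors and acceptors separately; the
shipped defaults are the BRCA1/BRCA2/ATM reference-junction statistics).  The
z-scores are then binned into qualitative categories whose prior
probabilities of pathogenicity were calibrated against family-history data,
with three special rules:

* **protection** — junctions whose wild-type score is already very low
  (acceptor z < -1.0, donor z < -1.5) require a z drop of at least 0.5 before
  a variant is placed in the high category (it is demoted to moderate
  otherwise);
* **promotion** — a de novo donor scoring above the exon's own wild-type
  donor moves up one category;
* **gating** — a de novo donor prior applies only when using the new donor
  would frameshift the transcript or remove part of a key functional domain;
  otherwise the variant keeps the baseline exonic prior.

Expert-knowledge overrides (initiator-codon prior, per-region ceilings) and
the max-combination with a missense prior live in :func:`combine_priors`.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import json

from .splice_fitness import SiteType
from .window_scan import DeNovoConsequence, FrameEffect

__all__ = [
    "JunctionStats",
    "NativeDamageCategory",
    "DeNovoCategory",
    "DeNovoBin",
    "ProtectionRule",
    "PriorConfig",
    "PriorResult",
    "DONOR_REFERENCE_STATS",
    "ACCEPTOR_REFERENCE_STATS",
    "zscore",
    "reference_stats",
    "classify_native",
    "classify_denovo_donor",
    "native_prior",
    "denovo_prior",
    "combine_priors",
    "midpoint_prior",
    "round_half_up",
]


def round_half_up(x: float, digits: int = 2) -> float:
    """Round half away from zero, matching printed report precision."""
    factor = 10**digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class JunctionStats:
    """Mean/SD (bits) of a reference set of wild-type junction scores."""

    site_type: SiteType
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("junction-score SD must be > 0")


# Reference wild-type junction statistics (BRCA1, BRCA2, ATM canonical exons).
DONOR_REFERENCE_STATS = JunctionStats(SiteType.DONOR, 8.02, 2.31, 110)
ACCEPTOR_REFERENCE_STATS = JunctionStats(SiteType.ACCEPTOR, 7.98, 2.44, 110)


def zscore(score: float, stats: JunctionStats) -> float:
    return (score - stats.mean) / stats.sd


def reference_stats(
    junction_scores: Sequence[float], site_type: SiteType
) -> JunctionStats:
    """Sample mean and SD (n-1 denominator) of wild-type junction scores."""
    if len(junction_scores) < 2:
        raise ValueError("need at least 2 junction scores")
    mean = statistics.fmean(junction_scores)
    sd = statistics.stdev(junction_scores)
    if sd <= 0:
        raise ValueError("junction scores are degenerate (SD = 0)")
    return JunctionStats(site_type, mean, sd, len(junction_scores))


class NativeDamageCategory(str, Enum):
    IMPROVED = "improved"
    MINIMAL = "minimal"
    MODERATE = "moderate"
    HIGH = "high"


class DeNovoBin(int, Enum):
    WEAK_NULL_LOW = 0
    MODERATE = 1
    INCREASED = 2

    @property
    def label(self) -> str:
        return {"WEAK_NULL_LOW": "weak_null_low"}.get(self.name, self.name.lower())


@dataclass(frozen=True)
class DeNovoCategory:
    value: DeNovoBin
    promoted: bool = False


@dataclass(frozen=True)
class ProtectionRule:
    """Low-score-junction protection thresholds."""

    acceptor_wt_z_threshold: float = -1.0
    donor_wt_z_threshold: float = -1.5
    min_delta_z: float = 0.5


def classify_native(
    site_type: SiteType,
    z_ref: float,
    z_alt: float,
    protection: ProtectionRule | None = ProtectionRule(),
) -> NativeDamageCategory:
    """Qualitative category for potential damage to a native junction.

    Improved: the variant raises the junction z-score.  Otherwise the variant
    junction z is binned — donors: minimal z > 0, moderate -2 <= z <= 0, high
    z < -2; acceptors: minimal z > 0.5, moderate -1.5 <= z <= 0.5, high
    z < -1.5 (moderate closed at both ends).  The protection rule then keeps
    variants in already-low-scoring junctions out of the high category unless
    they drop the z-score by at least 0.5.
    """
    if not (math.isfinite(z_ref) and math.isfinite(z_alt)):
        raise ValueError("z-scores must be finite")
    if z_alt > z_ref:
        return NativeDamageCategory.IMPROVED
    if site_type is SiteType.DONOR:
        minimal_above, high_below = 0.0, -2.0
    else:
        minimal_above, high_below = 0.5, -1.5
    if z_alt > minimal_above:
        category = NativeDamageCategory.MINIMAL
    elif z_alt < high_below:
        category = NativeDamageCategory.HIGH
    else:
        category = NativeDamageCategory.MODERATE
    if protection is not None and category is NativeDamageCategory.HIGH:
        threshold = (
            protection.donor_wt_z_threshold
            if site_type is SiteType.DONOR
            else protection.acceptor_wt_z_threshold
        )
        if z_ref < threshold and (z_ref - z_alt) < protection.min_delta_z:
            category = NativeDamageCategory.MODERATE
    return category


def classify_denovo_donor(z_dn: float, z_wt: float) -> DeNovoCategory:
    """Qualitative category for de novo donor creation.

    Bins: weak/null-and-low z < -2; moderate -2 <= z < 0; increased z >= 0.
    A de novo donor scoring above the exon's wild-type donor is promoted one
    category (never skipping a level, never past "increased").
    """
    if not (math.isfinite(z_dn) and math.isfinite(z_wt)):
        raise ValueError("z-scores must be finite")
    if z_dn >= 0:
        bin_ = DeNovoBin.INCREASED
    elif z_dn >= -2:
        bin_ = DeNovoBin.MODERATE
    else:
        bin_ = DeNovoBin.WEAK_NULL_LOW
    if z_dn > z_wt and bin_ is not DeNovoBin.INCREASED:
        return DeNovoCategory(DeNovoBin(bin_ + 1), promoted=True)
    return DeNovoCategory(bin_, promoted=False)


@dataclass
class PriorConfig:
    """Calibrated category-to-prior mapping plus special-rule parameters."""

    native_priors: dict[NativeDamageCategory, float] = field(
        default_factory=lambda: {
            NativeDamageCategory.IMPROVED: 0.04,
            NativeDamageCategory.MINIMAL: 0.04,
            NativeDamageCategory.MODERATE: 0.34,
            NativeDamageCategory.HIGH: 0.97,
        }
    )
    denovo_priors: dict[DeNovoBin, float] = field(
        default_factory=lambda: {
            DeNovoBin.WEAK_NULL_LOW: 0.02,
            DeNovoBin.MODERATE: 0.30,
            DeNovoBin.INCREASED: 0.64,
        }
    )
    baseline_exonic_prior: float = 0.02
    initiator_met_prior: float = 0.97
    protection_rule: ProtectionRule = field(default_factory=ProtectionRule)

    def __post_init__(self) -> None:
        for p in (
            *self.native_priors.values(),
            *self.denovo_priors.values(),
            self.baseline_exonic_prior,
            self.initiator_met_prior,
        ):
            if not 0 < p < 1:
                raise ValueError(f"priors must lie in (0, 1); got {p}")

    def to_json(self, path: str | Path) -> None:
        data = {
            "native_priors": {c.value: p for c, p in self.native_priors.items()},
            "denovo_priors": {b.label: p for b, p in self.denovo_priors.items()},
            "baseline_exonic_prior": self.baseline_exonic_prior,
            "initiator_met_prior": self.initiator_met_prior,
            "protection_rule": {
                "acceptor_wt_z_threshold": self.protection_rule.acceptor_wt_z_threshold,
                "donor_wt_z_threshold": self.protection_rule.donor_wt_z_threshold,
                "min_delta_z": self.protection_rule.min_delta_z,
            },
        }
        Path(path).write_text(json.dumps(data, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PriorConfig":
        data = json.loads(Path(path).read_text())
        by_label = {b.label: b for b in DeNovoBin}
        kwargs = {}
        if "native_priors" in data:
            kwargs["native_priors"] = {
                NativeDamageCategory(c): p for c, p in data["native_priors"].items()
            }
        if "denovo_priors" in data:
            kwargs["denovo_priors"] = {
                by_label[c]: p for c, p in data["denovo_priors"].items()
            }
        for key in ("baseline_exonic_prior", "initiator_met_prior"):
            if key in data:
                kwargs[key] = data[key]
        if "protection_rule" in data:
            kwargs["protection_rule"] = ProtectionRule(**data["protection_rule"])
        return cls(**kwargs)


def native_prior(category: NativeDamageCategory, config: PriorConfig) -> float:
    return config.native_priors[category]


def denovo_prior(
    category: DeNovoCategory,
    consequence: DeNovoConsequence | None,
    config: PriorConfig,
) -> float:
    """Prior for de novo donor creation, gated on the mRNA consequence.

    The category prior applies only when using the de novo donor would either
    frameshift the transcript or delete part of a key functional domain;
    otherwise (including when no consequence is computable) the variant keeps
    the baseline exonic prior.
    """
    if consequence is not None and (
        consequence.frame_effect is FrameEffect.FRAMESHIFT
        or consequence.hits_key_domain
    ):
        return config.denovo_priors[category.value]
    return config.baseline_exonic_prior


def midpoint_prior(
    point_estimate: float,
    ci: tuple[float, float],
    threshold: float = 0.01,
) -> float:
    """Reassign near-zero calibrated proportions to their CI midpoint.

    Calibrated point estimates at or below ``threshold`` (the 0.00/0.01
    strata, which cannot enter a Bayesian update as-is) become
    ``(low + high) / 2``; larger estimates pass through unchanged.
    """
    low, high = ci
    if not (0 <= low <= point_estimate <= high <= 1):
        raise ValueError(f"malformed CI {ci} for point estimate {point_estimate}")
    if point_estimate <= threshold:
        return (low + high) / 2
    return point_estimate


@dataclass(frozen=True)
class PriorResult:
    """Combined prior for one variant, with the audit trail of applied rules."""

    native_category: NativeDamageCategory | None
    native_prior: float | None
    denovo_category: DeNovoCategory | None
    denovo_prior: float | None
    missense_prior: float | None
    selected_prior: float
    applied_rules: tuple[str, ...]


def combine_priors(
    native: float | None = None,
    denovo: float | None = None,
    missense: float | None = None,
    *,
    config: PriorConfig | None = None,
    in_initiator_codon: bool = False,
    ceilings: Sequence[tuple[str, float, str]] = (),
    native_category: NativeDamageCategory | None = None,
    denovo_category: DeNovoCategory | None = None,
    extra_rules: Sequence[str] = (),
) -> PriorResult:
    """Select the highest component prior, then apply expert overrides.

    ``ceilings`` is a sequence of ``(label, ceiling, channels)`` applicable to
    the variant's location; ``channels == "splice"`` caps only the splice
    components before the max (a missense/truncation prior is never capped by
    such a region), ``"all"`` caps the final selected prior.
    """
    config = config or PriorConfig()
    rules = list(extra_rules)
    splice_ceilings = [(lbl, c) for lbl, c, ch in ceilings if ch == "splice"]
    all_ceilings = [(lbl, c) for lbl, c, ch in ceilings if ch == "all"]
    capped_native, capped_denovo = native, denovo
    for lbl, c in splice_ceilings:
        if capped_native is not None and capped_native > c:
            capped_native = c
            rules.append(f"ceiling:{lbl}")
        if capped_denovo is not None and capped_denovo > c:
            capped_denovo = c
            rules.append(f"ceiling:{lbl}")
    components = [p for p in (capped_native, capped_denovo, missense) if p is not None]
    if not components:
        raise ValueError("no component priors supplied")
    selected = max(components)
    if in_initiator_codon and config.initiator_met_prior > selected:
        selected = config.initiator_met_prior
        rules.append("initiator_met")
    for lbl, c in all_ceilings:
        if selected > c:
            selected = c
            rules.append(f"ceiling:{lbl}")
    # deduplicate, preserving order
    seen: set[str] = set()
    rules = [r for r in rules if not (r in seen or seen.add(r))]
    return PriorResult(
        native_category=native_category,
        native_prior=native,
        denovo_category=denovo_category,
        denovo_prior=denovo,
        missense_prior=missense,
        selected_prior=selected,
        applied_rules=tuple(rules),
    )
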