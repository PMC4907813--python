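"""Enrichment ratio for single-nucleotide substitutions (ERS).

New germline substitutions are not equally likely: context-dependent relative
substitution rates r_i (e.g. elevated CpG transitions) determine, for any
algorithmically defined class c of possible SNVs, the probability that a new
variant falls in c:

    p_c = sum_{i in c} r_i / sum_i r_i

Under no selection, the expected count in class c among o_T observed variants
is e_c = p_c * o_T.  The ERS normalizes the observed/expected ratio of a
class by the same ratio for silent (synonymous, non-spliceogenic) variants:

    ERS(c) = (o_c / e_c) / (o_s / e_s) = (o_c / p_c) / (o_s / p_s)

so ERS is invariant to rescaling the whole rate table and equals 1 for the
silent class itself.  A trend test across ordered score bins asks whether
enrichment rises with the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .gene_model import reverse_complement
from .splice_fitness import BASES

__all__ = [
    "RateTable",
    "PossibleSnv",
    "ObservedCounts",
    "relative_rates",
    "enumerate_snvs",
    "class_probability",
    "ers",
    "clean_classes",
    "trend_test",
    "simulate_null_observations",
]


@dataclass(frozen=True)
class PossibleSnv:
    """One of the 3L possible substitutions to an L-base sequence."""

    position: int  # 0-based within the target sequence
    ref: str
    alt: str
    rate: float


class RateTable:
    """Relative substitution rates keyed by trinucleotide context.

    Keys are ``(5'-neighbor, ref, alt, 3'-neighbor)``; a ``(ref, alt)``
    fallback applies when no context-specific entry exists.  Symmetrization
    averages each context with its reverse complement so that sense and
    antisense orientations rate equally.
    """

    def __init__(
        self,
        context_rates: Mapping[tuple[str, str, str, str], float] | None = None,
        base_rates: Mapping[tuple[str, str], float] | None = None,
        strand_symmetrized: bool = False,
    ) -> None:
        self.context_rates = dict(context_rates or {})
        self.base_rates = dict(base_rates or {})
        self.strand_symmetrized = strand_symmetrized
        for rate in (*self.context_rates.values(), *self.base_rates.values()):
            if not np.isfinite(rate) or rate < 0:
                raise ValueError("substitution rates must be finite and >= 0")
        if strand_symmetrized:
            self._symmetrize()

    def _symmetrize(self) -> None:
        sym: dict[tuple[str, str, str, str], float] = {}
        for (l, ref, alt, r), rate in self.context_rates.items():
            rc = (
                reverse_complement(r),
                reverse_complement(ref),
                reverse_complement(alt),
                reverse_complement(l),
            )
            other = self.context_rates.get(rc, rate)
            sym[(l, ref, alt, r)] = (rate + other) / 2
            sym[rc] = (rate + other) / 2
        self.context_rates = sym

    def rate(self, left: str, ref: str, alt: str, right: str) -> float:
        key = (left, ref, alt, right)
        if key in self.context_rates:
            return self.context_rates[key]
        if (ref, alt) in self.base_rates:
            return self.base_rates[(ref, alt)]
        raise KeyError(f"no rate for substitution context {key}")

    # -- built-ins for tests and defaults -----------------------------------

    @classmethod
    def uniform(cls) -> "RateTable":
        rates = {(r, a): 1.0 for r in BASES for a in BASES if r != a}
        return cls(base_rates=rates)

    @classmethod
    def toy_cpg(cls, cpg_factor: float = 10.0) -> "RateTable":
        """Transition/transversion-aware toy table with elevated CpG
        transitions (C>T in CG context and its reverse complement)."""
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        base = {
            (r, a): (3.0 if (r, a) in transitions else 1.0)
            for r in BASES
            for a in BASES
            if r != a
        }
        ctx = {}
        for left in BASES:
            ctx[(left, "C", "T", "G")] = 3.0 * cpg_factor
        for right in BASES:
            ctx[("C", "G", "A", right)] = 3.0 * cpg_factor
        return cls(context_rates=ctx, base_rates=base, strand_symmetrized=True)

    @classmethod
    def from_tsv(cls, path: str | Path, strand_symmetrized: bool = False) -> "RateTable":
        """Read ``context  ref  alt  relative_rate`` rows; ``context`` is the
        two flanking bases (e.g. ``A.G``) or ``.`` for a context-free rate."""
        ctx: dict[tuple[str, str, str, str], float] = {}
        base: dict[tuple[str, str], float] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("context"):
                continue
            context, ref, alt, rate = line.split("\t")
            if context.strip(".") == "":
                base[(ref, alt)] = float(rate)
            else:
                left, right = context.split(".")
                ctx[(left, ref, alt, right)] = float(rate)
        return cls(ctx, base, strand_symmetrized=strand_symmetrized)


def enumerate_snvs(
    sequence: str, rate_table: RateTable, flank5: str = "", flank3: str = ""
) -> list[PossibleSnv]:
    """All 3L possible SNVs of ``sequence`` with their relative rates.

    ``flank5``/``flank3`` provide context for the terminal positions; without
    them the first/last position lacks a neighbor and is an error.
    """
    padded = flank5 + sequence.upper() + flank3
    off = len(flank5)
    out: list[PossibleSnv] = []
    for i, ref in enumerate(sequence.upper()):
        j = i + off
        if j - 1 < 0 or j + 1 >= len(padded):
            raise ValueError(
                f"missing flanking context for terminal position {i}"
            )
        left, right = padded[j - 1], padded[j + 1]
        for alt in BASES:
            if alt == ref:
                continue
            out.append(
                PossibleSnv(i, ref, alt, rate_table.rate(left, ref, alt, right))
            )
    return out


def relative_rates(
    sequence: str, rate_table: RateTable, flank5: str = "", flank3: str = ""
) -> np.ndarray:
    """Array of the 3L relative rates in enumeration order."""
    return np.array(
        [s.rate for s in enumerate_snvs(sequence, rate_table, flank5, flank3)]
    )


def class_probability(
    members: Iterable[bool] | np.ndarray, rates: Sequence[float] | np.ndarray
) -> float:
    """p_c: rate-weighted probability that a new variant falls in the class."""
    rates = np.asarray(rates, dtype=float)
    members = np.asarray(list(members), dtype=bool)
    if rates.size == 0:
        raise ValueError("empty SNV universe")
    total = rates.sum()
    if total <= 0:
        raise ValueError("rate total must be positive")
    return float(rates[members].sum() / total)


@dataclass
class ObservedCounts:
    """Observed counts and class probabilities feeding the ERS."""

    o_c: dict[Hashable, int]
    p_c: dict[Hashable, float]
    silent_class: Hashable

    @property
    def o_T(self) -> int:
        return sum(self.o_c.values())

    def expected(self, label: Hashable) -> float:
        return self.p_c[label] * self.o_T


def ers(label: Hashable, counts: ObservedCounts) -> float:
    """ERS(c) = (o_c/p_c) / (o_s/p_s)."""
    o_s = counts.o_c.get(counts.silent_class, 0)
    p_s = counts.p_c.get(counts.silent_class, 0.0)
    p_c = counts.p_c[label]
    if o_s <= 0:
        raise ValueError("ERS undefined: zero silent observations")
    if p_s <= 0 or p_c <= 0:
        raise ValueError("ERS undefined: zero class probability")
    o_c = counts.o_c.get(label, 0)
    return (o_c / p_c) / (o_s / p_s)


def clean_classes(
    annotations: Sequence[Mapping[str, object]],
    class_defs: Sequence[tuple[Hashable, Callable[[Mapping[str, object]], bool]]],
) -> list[Hashable]:
    """Assign each annotated SNV to exactly one class by precedence.

    ``class_defs`` lists ``(label, predicate)`` in decreasing precedence; a
    likely-spliceogenic class listed first therefore claims silent or
    missense-neutral variants that would otherwise land in a neutral class.
    The last class may use a catch-all predicate.  An SNV matching no class
    is an error (the classes must partition the universe).
    """
    out: list[Hashable] = []
    for ann in annotations:
        for label, predicate in class_defs:
            if predicate(ann):
                out.append(label)
                break
        else:
            raise ValueError(f"SNV matches no class: {ann!r}")
    return out


def trend_test(
    bins: Sequence[tuple[float, float]],
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Score test for a monotone trend in observed/expected across bins.

    ``bins`` is an ordered sequence of ``(observed, expected)`` counts.
    Under the null, each of the n = sum(observed) variants falls in bin b
    with probability e_b / sum(e); the statistic is the standardized linear
    score U = sum_b x_b o_b with x_b the bin index (Cochran-Armitage-style).
    Returns ``(z_statistic, two_sided_p)``; with ``n_permutations`` > 0 the
    p-value is estimated by multinomial simulation instead of the normal
    approximation.
    """
    if len(bins) < 3:
        raise ValueError("need at least 3 ordered bins")
    obs = np.array([b[0] for b in bins], dtype=float)
    exp = np.array([b[1] for b in bins], dtype=float)
    n = obs.sum()
    if n <= 0 or exp.sum() <= 0:
        raise ValueError("degenerate bins: no observations or no expectation")
    pi = exp / exp.sum()
    x = np.arange(len(bins), dtype=float)
    u = float((x * obs).sum())
    mean = n * float((x * pi).sum())
    var = n * float((x**2 * pi).sum() - ((x * pi).sum()) ** 2)
    if var <= 0:
        raise ValueError("degenerate bins: zero trend variance")
    z = (u - mean) / np.sqrt(var)
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        draws = rng.multinomial(int(n), pi, size=n_permutations)
        u_sim = draws @ x
        p = float(
            (np.abs(u_sim - mean) >= abs(u - mean) - 1e-12).mean()
        )
        p = max(p, 1.0 / n_permutations)
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return z, min(p, 1.0)


def simulate_null_observations(
    rates: Sequence[float] | np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw SNV observations proportional to their relative rates (no
    selection); returns per-SNV observed counts."""
    rates = np.asarray(rates, dtype=float)
    p = rates / rates.sum()
    return rng.multinomial(n_draws, p)
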