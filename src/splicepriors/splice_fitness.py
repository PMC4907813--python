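"""Splice-fitness scoring of donor and acceptor k-mers.

Two interchangeable scoring backends produce log2-odds ("bits") splice-fitness
scores for fixed-length windows:

* a position weight-matrix scorer that is self-contained (trainable from a set
  of junction k-mers) and used throughout the test fixtures, and
* a maximum-entropy table scorer that reads the table layout of the published
  MaxEntScan ``splicemodels`` distribution, so user-supplied model files can be
  scored with the canonical donor/acceptor schemes.

Donor sites are scored as 9-mers with the exon|intron junction between window
positions 3 and 4 (three exonic bases, six intronic).  Acceptor sites are
23-mers with the junction between positions 20 and 21 (twenty intronic bases,
three exonic).  Higher scores mean more splice-site-like sequence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "SiteType",
    "Kmer",
    "SpliceFitnessModel",
    "WeightMatrixModel",
    "MaxEntTablesModel",
    "InvalidKmerError",
    "ModelLoadError",
    "score_kmer",
    "train_weight_matrix",
    "load_maxent_tables",
]


class InvalidKmerError(ValueError):
    """A k-mer fails the backend's input contract (length/alphabet)."""


class ModelLoadError(ValueError):
    """A model file set is missing, truncated, or fails validation."""


class SiteType(str, Enum):
    """Donor (5') or acceptor (3') splice site."""

    DONOR = "donor"
    ACCEPTOR = "acceptor"

    @property
    def k(self) -> int:
        return 9 if self is SiteType.DONOR else 23

    @property
    def junction_offset(self) -> int:
        """Number of window bases 5' of the junction (donor 3, acceptor 20)."""
        return 3 if self is SiteType.DONOR else 20


def _validate_sequence(sequence: str, k: int) -> str:
    seq = sequence.upper()
    if len(seq) != k:
        raise InvalidKmerError(
            f"expected a {k}-mer, got length {len(seq)}: {sequence!r}"
        )
    for ch in seq:
        if ch not in BASE_INDEX:
            raise InvalidKmerError(f"invalid base {ch!r} in k-mer {sequence!r}")
    return seq


@dataclass(frozen=True)
class Kmer:
    """A fixed-length splice-window sequence over {A,C,G,T}."""

    sequence: str
    site_type: SiteType

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _validate_sequence(self.sequence, self.site_type.k)
        )

    def __len__(self) -> int:
        return len(self.sequence)


class SpliceFitnessModel:
    """Scoring contract: map a k-mer of the model's site type to bits."""

    site_type: SiteType

    def score(self, sequence: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


def score_kmer(model: SpliceFitnessModel, kmer: Kmer) -> float:
    """Score ``kmer`` with ``model``; site types must match."""
    if kmer.site_type is not model.site_type:
        raise InvalidKmerError(
            f"k-mer site type {kmer.site_type.value} does not match model "
            f"site type {model.site_type.value}"
        )
    return model.score(kmer.sequence)


# ---------------------------------------------------------------------------
# Weight-matrix backend
# ---------------------------------------------------------------------------


@dataclass
class WeightMatrixModel(SpliceFitnessModel):
    """Per-position log2-odds scorer.

    ``probs`` has shape (k, 4) with rows summing to one; ``background`` is a
    length-4 nucleotide distribution.  The score of a k-mer is the sum over
    positions of ``log2(P_model(base) / P_background(base))``, so scores are
    additive: substituting one base shifts the score by exactly that
    position's log-odds difference.
    """

    site_type: SiteType
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        k = self.site_type.k
        if self.probs.shape != (k, 4):
            raise ModelLoadError(
                f"weight matrix must have shape ({k}, 4), got {self.probs.shape}"
            )
        if np.any(self.probs <= 0) or np.any(self.background <= 0):
            raise ModelLoadError("weight-matrix probabilities must be positive")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ModelLoadError("weight-matrix rows must sum to 1 within 1e-9")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ModelLoadError("background distribution must sum to 1")
        self._log_odds = np.log2(self.probs / self.background[None, :])

    def score(self, sequence: str) -> float:
        seq = _validate_sequence(sequence, self.site_type.k)
        idx = [BASE_INDEX[b] for b in seq]
        return float(self._log_odds[np.arange(len(idx)), idx].sum())

    # -- serialization (TSV: position, A, C, G, T) --------------------------

    def to_tsv(self, path: str | Path) -> None:
        lines = ["position\tA\tC\tG\tT"]
        for i, row in enumerate(self.probs):
            lines.append(
                str(i + 1) + "\t" + "\t".join(f"{p:.10g}" for p in row)
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        site_type: SiteType,
        background: Sequence[float] | None = None,
    ) -> "WeightMatrixModel":
        rows = []
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise ModelLoadError(f"cannot read weight matrix {path}: {exc}")
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            rows.append([float(x) for x in parts[1:5]])
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        return cls(site_type=site_type, probs=np.array(rows), background=bg)


def train_weight_matrix(
    junction_kmers: Sequence[Kmer],
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
) -> WeightMatrixModel:
    """Estimate a weight matrix from aligned junction k-mers.

    Per-position probabilities are ``(count + pseudocount) / (n + 4*pseudocount)``.
    """
    if not junction_kmers:
        raise ValueError("need at least one training k-mer")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    site_type = junction_kmers[0].site_type
    if any(km.site_type is not site_type for km in junction_kmers):
        raise ValueError("training k-mers mix site types")
    k = site_type.k
    counts = np.zeros((k, 4))
    for km in junction_kmers:
        for i, b in enumerate(km.sequence):
            counts[i, BASE_INDEX[b]] += 1
    n = len(junction_kmers)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return WeightMatrixModel(site_type=site_type, probs=probs, background=bg)


# ---------------------------------------------------------------------------
# MaxEntScan-table backend
# ---------------------------------------------------------------------------

# Background and junction-consensus nucleotide probabilities of the published
# reference scorers.  The donor scheme scores the two consensus positions
# (the canonical G and T at window positions 4-5) directly and looks the
# remaining 7-mer up in a joint maximum-entropy probability-ratio table; the
# acceptor scheme scores the canonical A and G (positions 19-20) directly and
# combines nine overlapping marginal tables over the remaining 21-mer.
_DEFAULT_BACKGROUND = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
_DONOR_CONS1 = {"A": 0.004, "C": 0.0032, "G": 0.9896, "T": 0.0032}  # +1 (G)
_DONOR_CONS2 = {"A": 0.0034, "C": 0.0039, "G": 0.0042, "T": 0.9884}  # +2 (T)
_ACC_RES1 = (1.0 - 0.9903) / 3
_ACC_RES2 = (1.0 - 0.9930) / 3
_ACCEPTOR_CONS1 = {"A": 0.9903, "C": _ACC_RES1, "G": _ACC_RES1, "T": _ACC_RES1}
_ACCEPTOR_CONS2 = {"A": _ACC_RES2, "C": _ACC_RES2, "G": 0.9930, "T": _ACC_RES2}

# Donor: consensus window positions (0-based) and the non-consensus rest.
_DONOR_CONS_POS = (3, 4)
_DONOR_REST_POS = (0, 1, 2, 5, 6, 7, 8)

# Acceptor: consensus positions and nine (start, length) fragments of the
# 21-mer that remains once the two consensus bases are removed.  The combined
# maximum-entropy probability is s0*s1*s2*s3*s4 / (s5*s6*s7*s8).
_ACCEPTOR_CONS_POS = (18, 19)
_ACCEPTOR_FRAGMENTS = (
    (0, 7),
    (7, 7),
    (14, 7),
    (4, 7),
    (11, 7),
    (4, 3),
    (7, 4),
    (11, 3),
    (14, 4),
)
_ACCEPTOR_NUMERATOR = (True, True, True, True, True, False, False, False, False)


def _kmer_index(seq: str) -> int:
    """Lexicographic (A<C<G<T) base-4 index of a sequence."""
    idx = 0
    for b in seq:
        idx = idx * 4 + BASE_INDEX[b]
    return idx


def _load_table(path: Path, expected_len: int) -> np.ndarray:
    if not path.is_file():
        raise ModelLoadError(f"missing model table file: {path}")
    values = []
    for line in path.read_text().split():
        values.append(float(line))
    arr = np.asarray(values, dtype=float)
    if arr.size != expected_len:
        raise ModelLoadError(
            f"table {path.name} has {arr.size} entries, expected {expected_len}"
        )
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ModelLoadError(
            f"table {path.name} contains negative or non-finite entries"
        )
    return arr


@dataclass
class MaxEntTablesModel(SpliceFitnessModel):
    """Maximum-entropy splice scorer over MaxEntScan-format table files."""

    site_type: SiteType
    tables: list[np.ndarray]
    background: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BACKGROUND)
    )
    cons1: dict[str, float] = field(default_factory=dict)
    cons2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cons1 or not self.cons2:
            if self.site_type is SiteType.DONOR:
                self.cons1 = self.cons1 or dict(_DONOR_CONS1)
                self.cons2 = self.cons2 or dict(_DONOR_CONS2)
            else:
                self.cons1 = self.cons1 or dict(_ACCEPTOR_CONS1)
                self.cons2 = self.cons2 or dict(_ACCEPTOR_CONS2)

    def _consensus_ratio(self, seq: str) -> float:
        p1, p2 = (
            (_DONOR_CONS_POS) if self.site_type is SiteType.DONOR else _ACCEPTOR_CONS_POS
        )
        b1, b2 = seq[p1], seq[p2]
        return (
            self.cons1[b1]
            * self.cons2[b2]
            / (self.background[b1] * self.background[b2])
        )

    def score(self, sequence: str) -> float:
        seq = _validate_sequence(sequence, self.site_type.k)
        if self.site_type is SiteType.DONOR:
            rest = "".join(seq[i] for i in _DONOR_REST_POS)
            ratio = self.tables[0][_kmer_index(rest)]
        else:
            rest = seq[:18] + seq[20:]
            log_num = 0.0
            log_den = 0.0
            for (start, length), num, table in zip(
                _ACCEPTOR_FRAGMENTS, _ACCEPTOR_NUMERATOR, self.tables
            ):
                val = table[_kmer_index(rest[start : start + length])]
                if val <= 0:
                    return float("-inf")
                if num:
                    log_num += math.log(val)
                else:
                    log_den += math.log(val)
            ratio = math.exp(log_num - log_den)
        if ratio <= 0:
            return float("-inf")
        return math.log2(self._consensus_ratio(seq) * ratio)


def load_maxent_tables(path: str | Path) -> MaxEntTablesModel:
    """Load a MaxEntScan ``splicemodels``-layout directory.

    A directory with ``me2x5`` is a donor model; one with ``me2x3acc1`` ..
    ``me2x3acc9`` is an acceptor model.  An optional ``consensus.json`` can
    override the background/consensus nucleotide probabilities.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise ModelLoadError(f"model directory not found: {directory}")
    overrides: dict = {}
    cons_file = directory / "consensus.json"
    if cons_file.is_file():
        overrides = json.loads(cons_file.read_text())
    donor_table = directory / "me2x5"
    acc1 = directory / "me2x3acc1"
    if donor_table.is_file():
        tables = [_load_table(donor_table, 4**7)]
        site_type = SiteType.DONOR
    elif acc1.is_file():
        tables = []
        for i, (_, length) in enumerate(_ACCEPTOR_FRAGMENTS, start=1):
            tables.append(_load_table(directory / f"me2x3acc{i}", 4**length))
        site_type = SiteType.ACCEPTOR
    else:
        raise ModelLoadError(
            f"directory {directory} contains neither 'me2x5' (donor) nor "
            f"'me2x3acc1'..'me2x3acc9' (acceptor) tables"
        )
    return MaxEntTablesModel(
        site_type=site_type,
        tables=tables,
        background=overrides.get("background", dict(_DEFAULT_BACKGROUND)),
        cons1=overrides.get("cons1", {}),
        cons2=overrides.get("cons2", {}),
    )
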