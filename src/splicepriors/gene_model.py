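"""Gene/transcript models, variants, and sequence editing.

Coordinates: all I/O (gene-model config, VCF, HGVS c.) is 1-based; internal
coordinates are 0-based half-open.  All scoring happens in transcript
orientation: a minus-strand gene is reverse-complemented once when the
oriented view is built, after which exons, junction windows and the sliding
scan all work on a single plus-oriented sequence.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

from .splice_fitness import SiteType

__all__ = [
    "Region",
    "VariantKind",
    "GeneModel",
    "KeyDomain",
    "SpecialRegion",
    "OrientedGene",
    "VariantRecord",
    "OrientedVariant",
    "CoordMap",
    "ReferenceMismatchError",
    "apply_variant",
    "reverse_complement",
    "ACCEPTOR_FLANK",
    "DONOR_FLANK",
]

# Proximal splice-junction scope on the intron side: 20 bases upstream of an
# exon (acceptor side) and 6 downstream (donor side).
ACCEPTOR_FLANK = 20
DONOR_FLANK = 6

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceMismatchError(ValueError):
    """A variant's stated reference allele does not match the sequence."""


class Region(str, Enum):
    EXONIC = "exonic"
    SPLICE_REGION_INTRONIC = "splice_region_intronic"
    OUT_OF_SCOPE = "out_of_scope"


class VariantKind(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    DELINS = "delins"


@dataclass(frozen=True)
class KeyDomain:
    """A protein region (codon interval, 1-based inclusive) in which in-frame
    deletions are considered damaging."""

    label: str
    codon_start: int
    codon_end: int


@dataclass(frozen=True)
class SpecialRegion:
    """An expert-knowledge region with a prior-probability ceiling.

    ``exons`` are 1-based exon numbers; ``include_flanks`` extends the region
    over the proximal splice-junction windows; ``channels`` is ``"all"`` (cap
    the final selected prior) or ``"splice"`` (cap only splice-channel priors,
    leaving e.g. a protein-truncation/missense prior untouched).
    """

    label: str
    exons: tuple[int, ...]
    ceiling: float
    include_flanks: bool = True
    channels: str = "all"


@dataclass
class GeneModel:
    """Exon structure of one transcript on a genomic reference."""

    gene_id: str
    contig: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # 1-based inclusive genomic, ascending
    cds_start: int  # genomic position of first coding base
    cds_end: int  # genomic position of last coding base
    key_domains: list[KeyDomain] = field(default_factory=list)
    special_regions: list[SpecialRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1 + 1:
                raise ValueError(
                    "exons must be non-overlapping and separated by at least "
                    f"one intronic base: {(s1, e1)} vs {(s2, e2)}"
                )
        for s, e in exons:
            if s > e:
                raise ValueError(f"exon start after end: {(s, e)}")
        self.exons = exons

    # -- config I/O ---------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        data = {
            "gene_id": self.gene_id,
            "contig": self.contig,
            "strand": self.strand,
            "exons": [list(e) for e in self.exons],
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
            "key_domains": [
                [d.label, d.codon_start, d.codon_end] for d in self.key_domains
            ],
            "special_regions": [
                {
                    "label": r.label,
                    "exons": list(r.exons),
                    "ceiling": r.ceiling,
                    "include_flanks": r.include_flanks,
                    "channels": r.channels,
                }
                for r in self.special_regions
            ],
        }
        Path(path).write_text(json.dumps(data, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneModel":
        data = json.loads(Path(path).read_text())
        return cls(
            gene_id=data["gene_id"],
            contig=data["contig"],
            strand=data["strand"],
            exons=[tuple(e) for e in data["exons"]],
            cds_start=data["cds_start"],
            cds_end=data["cds_end"],
            key_domains=[KeyDomain(*d) for d in data.get("key_domains", [])],
            special_regions=[
                SpecialRegion(
                    label=r["label"],
                    exons=tuple(r["exons"]),
                    ceiling=r["ceiling"],
                    include_flanks=r.get("include_flanks", True),
                    channels=r.get("channels", "all"),
                )
                for r in data.get("special_regions", [])
            ],
        )


@dataclass(frozen=True)
class VariantRecord:
    """A sequence variant in genomic coordinates (reference strand).

    ``pos`` is 1-based; alleles follow VCF conventions (indels anchored on a
    shared leading base).
    """

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")

    @property
    def kind(self) -> VariantKind:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantKind.SNV
        if len(self.ref) < len(self.alt) and self.alt.startswith(self.ref):
            return VariantKind.INSERTION
        if len(self.ref) > len(self.alt) and self.ref.startswith(self.alt):
            return VariantKind.DELETION
        return VariantKind.DELINS


@dataclass(frozen=True)
class OrientedVariant:
    """A variant expressed on the transcript-oriented sequence.

    ``start`` is 0-based into the oriented sequence; ``ref``/``alt`` are
    oriented-strand alleles.
    """

    start: int
    ref: str
    alt: str

    @property
    def end(self) -> int:
        return self.start + len(self.ref)

    @property
    def kind(self) -> VariantKind:
        return VariantRecord("_", 1, self.ref, self.alt).kind


class CoordMap:
    """Coordinate map between a sequence and its edited version.

    Total on positions outside the edited interval; positions inside the
    replaced reference interval map to ``None``.  Monotone and bijective off
    the edit.
    """

    def __init__(self, edit_start: int, ref_len: int, alt_len: int) -> None:
        self.edit_start = edit_start
        self.ref_len = ref_len
        self.alt_len = alt_len
        self.shift = alt_len - ref_len

    def forward(self, pos: int) -> int | None:
        if pos < self.edit_start:
            return pos
        if pos < self.edit_start + self.ref_len:
            return None
        return pos + self.shift

    def forward_right(self, pos: int) -> int:
        """Forward map with right semantics: positions inside the edit map to
        the first position after the replacement."""
        mapped = self.forward(pos)
        if mapped is None:
            return self.edit_start + self.alt_len
        return mapped

    def forward_boundary(self, b: int) -> int:
        """Map a boundary coordinate (the junction between bases b-1 and b).

        Boundaries flanking the edit map around it; a boundary strictly
        inside the replaced interval clamps to the edit start.
        """
        if b <= self.edit_start:
            return b
        if b >= self.edit_start + self.ref_len:
            return b + self.shift
        return self.edit_start

    def backward_boundary(self, b: int) -> int | None:
        """Inverse boundary map; None for boundaries inside the replacement."""
        if b <= self.edit_start:
            return b
        if b >= self.edit_start + self.alt_len:
            return b - self.shift
        return None

    def backward(self, pos: int) -> int | None:
        if pos < self.edit_start:
            return pos
        if pos < self.edit_start + self.alt_len:
            return None
        return pos - self.shift

    @property
    def edited_interval(self) -> tuple[int, int]:
        """Edited interval in mutated coordinates (half-open; for a pure
        deletion this is the zero-length junction point)."""
        return (self.edit_start, self.edit_start + self.alt_len)


def apply_variant(sequence: str, variant: OrientedVariant) -> tuple[str, CoordMap]:
    """Apply an oriented variant to a sequence; returns (mutated, CoordMap)."""
    a, b = variant.start, variant.end
    if a < 0 or b > len(sequence):
        raise ValueError("variant outside sequence bounds")
    if sequence[a:b] != variant.ref:
        raise ReferenceMismatchError(
            f"reference mismatch at {a}: sequence has {sequence[a:b]!r}, "
            f"variant states {variant.ref!r}"
        )
    mutated = sequence[:a] + variant.alt + sequence[b:]
    return mutated, CoordMap(a, len(variant.ref), len(variant.alt))


class OrientedGene:
    """Transcript-oriented view of a gene on its reference sequence.

    Holds the oriented genomic-span sequence (reverse-complemented for minus
    strand genes), exon intervals in oriented 0-based half-open coordinates,
    and the cDNA (c.) coordinate maps.
    """

    def __init__(self, model: GeneModel, contig_seq: str, pad: int = 64) -> None:
        self.model = model
        span_start = max(1, model.exons[0][0] - pad)
        span_end = min(len(contig_seq), model.exons[-1][1] + pad)
        raw = contig_seq[span_start - 1 : span_end].upper()
        self.span_start = span_start  # genomic 1-based of oriented index 0 (+)
        self.span_end = span_end
        self.minus = model.strand == "-"
        self.seq = reverse_complement(raw) if self.minus else raw
        # exons in oriented coords, transcript order
        exons = []
        for s, e in model.exons:
            o1 = self.genomic_to_oriented(s)
            o2 = self.genomic_to_oriented(e)
            exons.append((min(o1, o2), max(o1, o2) + 1))
        exons.sort()
        self.exons: list[tuple[int, int]] = exons
        # CDS bounds in oriented coords
        c1 = self.genomic_to_oriented(model.cds_start)
        c2 = self.genomic_to_oriented(model.cds_end)
        self.cds_lo, self.cds_hi = min(c1, c2), max(c1, c2) + 1
        # cumulative exonic lengths for cDNA mapping (relative to CDS start)
        self._exon_starts = [s for s, _ in exons]
        cum = [0]
        for s, e in exons:
            cum.append(cum[-1] + (e - s))
        self._cum = cum
        self.cds_offset = self._exonic_index(self.cds_lo)
        self.cdna_len = self._exonic_index(self.cds_hi - 1) - self.cds_offset + 1

    # -- coordinate conversions --------------------------------------------

    def genomic_to_oriented(self, pos: int) -> int:
        if self.minus:
            return self.span_end - pos
        return pos - self.span_start

    def oriented_to_genomic(self, opos: int) -> int:
        if self.minus:
            return self.span_end - opos
        return opos + self.span_start

    def _exonic_index(self, opos: int) -> int:
        """0-based index of an exonic oriented position among exonic bases."""
        for i, (s, e) in enumerate(self.exons):
            if s <= opos < e:
                return self._cum[i] + (opos - s)
        raise ValueError(f"oriented position {opos} is not exonic")

    def exon_of(self, opos: int) -> int | None:
        for i, (s, e) in enumerate(self.exons):
            if s <= opos < e:
                return i
        return None

    def cdna_to_oriented(self, c: int) -> int:
        """Map a c. coordinate (1 = first coding base) to an oriented position."""
        if not 1 <= c <= self.cdna_len:
            raise ValueError(f"c.{c} outside the coding sequence (1..{self.cdna_len})")
        target = self.cds_offset + c - 1
        i = bisect_right(self._cum, target) - 1
        s, e = self.exons[i]
        return s + (target - self._cum[i])

    def oriented_to_cdna(self, opos: int) -> tuple[int, int]:
        """Map an oriented position to (c_position, intron_offset).

        Exonic positions get offset 0.  Intronic positions are expressed
        relative to the nearest exon edge: positive offsets count from the
        preceding exon's last base (donor side), negative offsets count back
        from the following exon's first base (acceptor side); the nearer edge
        wins, ties go to the donor side.
        """
        idx = self.exon_of(opos)
        if idx is not None:
            return self._exonic_index(opos) - self.cds_offset + 1, 0
        prev_end = None
        next_start = None
        for s, e in self.exons:
            if e <= opos:
                prev_end = e
            if s > opos and next_start is None:
                next_start = s
        if prev_end is None:
            # upstream of the first exon: acceptor-style negative offset
            s0 = self.exons[0][0]
            return self._exonic_index(s0) - self.cds_offset + 1, opos - s0
        if next_start is None:
            e_last = self.exons[-1][1]
            return self._exonic_index(e_last - 1) - self.cds_offset + 1, opos - (
                e_last - 1
            )
        d_donor = opos - prev_end + 1  # +1-based downstream offset
        d_acc = opos - next_start  # negative
        if d_donor <= -d_acc:
            return (
                self._exonic_index(prev_end - 1) - self.cds_offset + 1,
                d_donor,
            )
        return self._exonic_index(next_start) - self.cds_offset + 1, d_acc

    # -- junctions and windows ---------------------------------------------

    def donor_junctions(self) -> list[int]:
        """Oriented junction coordinates (exon-end exclusive) of exons that
        have a downstream intron."""
        return [e for (s, e) in self.exons[:-1]]

    def acceptor_junctions(self) -> list[int]:
        return [s for (s, e) in self.exons[1:]]

    def junction_window(self, exon_index: int, site_type: SiteType) -> tuple[int, int]:
        """Oriented half-open window of a native junction.

        Donor of exon i: last 3 exonic + first 6 intronic bases.  Acceptor of
        exon i: last 20 intronic + first 3 exonic bases.
        """
        s, e = self.exons[exon_index]
        if site_type is SiteType.DONOR:
            if exon_index == len(self.exons) - 1:
                raise ValueError("last exon has no donor junction")
            return (e - 3, e + 6)
        if exon_index == 0:
            raise ValueError("first exon has no acceptor junction")
        return (s - 20, s + 3)

    def junction_windows(self) -> Iterator[tuple[int, SiteType, tuple[int, int]]]:
        for i in range(len(self.exons)):
            if i > 0:
                yield i, SiteType.ACCEPTOR, self.junction_window(i, SiteType.ACCEPTOR)
            if i < len(self.exons) - 1:
                yield i, SiteType.DONOR, self.junction_window(i, SiteType.DONOR)

    def native_kmer(self, exon_index: int, site_type: SiteType) -> str:
        lo, hi = self.junction_window(exon_index, site_type)
        return self.seq[lo:hi]

    # -- scope --------------------------------------------------------------

    def in_scope_intervals(self) -> list[tuple[int, int]]:
        """Oriented intervals of the analysed region: each exon extended by
        20 bases upstream and 6 downstream (merged where overlapping)."""
        raw = [(s - ACCEPTOR_FLANK, e + DONOR_FLANK) for s, e in self.exons]
        merged: list[tuple[int, int]] = []
        for s, e in raw:
            s = max(s, 0)
            e = min(e, len(self.seq))
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def region_of(self, start: int, end: int | None = None) -> Region:
        """Region of an oriented position or half-open interval."""
        if end is None:
            end = start + 1
        probe = range(start, max(end, start + 1))
        if any(self.exon_of(p) is not None for p in probe):
            return Region.EXONIC
        for s, e in self.in_scope_intervals():
            if start < e and end > s:
                return Region.SPLICE_REGION_INTRONIC
        return Region.OUT_OF_SCOPE

    # -- variant orientation -------------------------------------------------

    def orient_variant(self, variant: VariantRecord) -> OrientedVariant:
        if variant.contig != self.model.contig:
            raise ValueError(
                f"variant contig {variant.contig!r} does not match gene contig "
                f"{self.model.contig!r}"
            )
        if self.minus:
            g_end = variant.pos + len(variant.ref) - 1
            start = self.genomic_to_oriented(g_end)
            return OrientedVariant(
                start=start,
                ref=reverse_complement(variant.ref),
                alt=reverse_complement(variant.alt),
            )
        return OrientedVariant(
            start=self.genomic_to_oriented(variant.pos),
            ref=variant.ref.upper(),
            alt=variant.alt.upper(),
        )

    def deorient_variant(self, ov: OrientedVariant) -> VariantRecord:
        if self.minus:
            g_end = self.oriented_to_genomic(ov.start)
            pos = g_end - len(ov.ref) + 1
            return VariantRecord(
                contig=self.model.contig,
                pos=pos,
                ref=reverse_complement(ov.ref),
                alt=reverse_complement(ov.alt),
            )
        return VariantRecord(
            contig=self.model.contig,
            pos=self.oriented_to_genomic(ov.start),
            ref=ov.ref,
            alt=ov.alt,
        )
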