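"""Native-junction scoring and the sliding-window de novo junction scan.

Native damage and de novo creation are reported as separate channels: the
scan over a variant-bearing sequence excludes any window whose implied
junction coincides with a native junction of the gene, so a healthy wild-type
site never shows up as a "de novo" hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .gene_model import (
    CoordMap,
    OrientedGene,
    OrientedVariant,
    apply_variant,
)
from .splice_fitness import SiteType, SpliceFitnessModel

__all__ = [
    "WindowScanResult",
    "FrameEffect",
    "DeNovoConsequence",
    "ContextError",
    "scan_denovo",
    "scan_denovo_sequence",
    "score_native_junction",
    "denovo_consequence",
]


class ContextError(ValueError):
    """Not enough flanking sequence to score every frame."""


class FrameEffect(str, Enum):
    FRAMESHIFT = "frameshift"
    IN_FRAME = "in_frame"


@dataclass(frozen=True)
class WindowScanResult:
    """Best-scoring frame of the sliding-window scan.

    ``best_frame_offset`` is the position (0-based, 0..k-1) of the variant
    within the winning window; ties are broken toward the smallest offset.
    ``implied_junction`` is the junction coordinate (oriented reference,
    half-open exon-end convention) the winning window would create, or None
    when it falls inside an edited interval and has no reference coordinate.
    """

    site_type: SiteType
    best_score: float
    best_frame_offset: int
    implied_junction: int | None
    all_frame_scores: tuple[float, ...]


@dataclass(frozen=True)
class DeNovoConsequence:
    """mRNA-level consequence of using an exonic de novo donor.

    The de novo junction supplants the exon's native donor, deleting the
    exonic span between the two junctions from the transcript.
    """

    frame_effect: FrameEffect
    deleted_span: tuple[int, int]  # oriented half-open interval
    hits_key_domain: bool

    @property
    def deleted_length(self) -> int:
        return self.deleted_span[1] - self.deleted_span[0]


def scan_denovo_sequence(
    mutated: str,
    edited_interval: tuple[int, int],
    model: SpliceFitnessModel,
    exclude_junctions: Sequence[int] = (),
    coord_map: CoordMap | None = None,
) -> WindowScanResult:
    """Slide the model's k-window across every frame containing the edit.

    ``edited_interval`` is the half-open interval of the replacement in
    mutated coordinates (for an SNV, one base; the scan then scores exactly k
    frames with the variant moving from position 1 to position k of the
    window).  For indels every k-mer overlapping the edited interval (or, for
    a pure deletion, its junction point) is enumerated.  ``exclude_junctions``
    are junction coordinates in *mutated* coordinates whose frames are
    omitted from the maximum (native junctions).
    """
    k = model.site_type.k
    joff = model.site_type.junction_offset
    a, b = edited_interval
    b_eff = max(b, a + 1)  # pure deletion: scan frames around the junction
    lo = a - k + 1
    hi = b_eff - 1  # inclusive start of last window
    if lo < 0 or hi + k > len(mutated):
        raise ContextError(
            f"need {k - 1} bases of context on each side of the edit; have "
            f"[{a}, {b}) in a sequence of length {len(mutated)}"
        )
    excluded = set(exclude_junctions)
    scores: list[float] = []
    best: tuple[float, int, int, int | None] | None = None
    # iterate from the last window (variant at offset 0) upward so that ties
    # resolve to the smallest frame offset
    for s in range(hi, lo - 1, -1):
        score = model.score(mutated[s : s + k])
        offset = a - s if a - s >= 0 else 0
        junction_mut = s + joff
        scores.append(score)
        if junction_mut in excluded:
            continue
        if best is None or score > best[0]:
            if coord_map is None:
                junction_ref: int | None = junction_mut
            else:
                junction_ref = coord_map.backward_boundary(junction_mut)
            best = (score, offset, junction_mut, junction_ref)
    if best is None:
        raise ContextError("all frames excluded as native junctions")
    return WindowScanResult(
        site_type=model.site_type,
        best_score=best[0],
        best_frame_offset=best[1],
        implied_junction=best[3],
        all_frame_scores=tuple(scores[::-1]),
    )


def scan_denovo(
    gene: OrientedGene,
    variant: OrientedVariant,
    model: SpliceFitnessModel,
) -> WindowScanResult:
    """Apply ``variant`` to the gene's oriented sequence and scan it."""
    mutated, cmap = apply_variant(gene.seq, variant)
    junctions = gene.donor_junctions() if model.site_type is SiteType.DONOR else gene.acceptor_junctions()
    excluded = [cmap.forward_boundary(j) for j in junctions]
    return scan_denovo_sequence(
        mutated, cmap.edited_interval, model, excluded, coord_map=cmap
    )


def score_native_junction(
    gene: OrientedGene,
    exon_index: int,
    site_type: SiteType,
    model: SpliceFitnessModel,
    variant: OrientedVariant | None = None,
) -> tuple[float, float] | None:
    """Score a native junction in its fixed frame, wild-type and variant.

    Returns ``(ref_score, alt_score)``; with no variant both are the
    wild-type score.  Returns None (not applicable) when the variant does not
    overlap the junction's window — the caller then falls back to the de novo
    scan only.
    """
    lo, hi = gene.junction_window(exon_index, site_type)
    if lo < 0 or hi > len(gene.seq):
        raise ContextError("junction window extends beyond the reference span")
    ref_score = model.score(gene.seq[lo:hi])
    if variant is None:
        return ref_score, ref_score
    v_lo, v_hi = variant.start, max(variant.end, variant.start + 1)
    if v_hi <= lo or v_lo >= hi:
        return None
    mutated, cmap = apply_variant(gene.seq, variant)
    junction = gene.exons[exon_index][1] if site_type is SiteType.DONOR else gene.exons[exon_index][0]
    j_mut = cmap.forward_boundary(junction)
    joff = site_type.junction_offset
    m_lo, m_hi = j_mut - joff, j_mut + (site_type.k - joff)
    if m_lo < 0 or m_hi > len(mutated):
        raise ContextError("variant window extends beyond the reference span")
    alt_score = model.score(mutated[m_lo:m_hi])
    return ref_score, alt_score


def denovo_consequence(
    gene: OrientedGene,
    implied_junction: int | None,
) -> DeNovoConsequence | None:
    """Consequence of an exonic de novo *donor* junction.

    The deleted span runs from the implied junction to the native donor of
    the exon the junction falls in.  Returns None (not applicable) when the
    junction is not exonic, has no reference coordinate, or the exon has no
    native donor (last exon).
    """
    if implied_junction is None:
        return None
    exon_index = gene.exon_of(implied_junction)
    if exon_index is None and implied_junction > 0:
        # a junction exactly at an exon start belongs to the upstream intron
        exon_index = gene.exon_of(implied_junction - 1)
        exon_index = None if exon_index is None else exon_index
    if exon_index is None:
        return None
    if exon_index == len(gene.exons) - 1:
        return None  # no native donor to supplant
    exon_start, exon_end = gene.exons[exon_index]
    if implied_junction <= exon_start or implied_junction >= exon_end:
        return None
    deleted = (implied_junction, exon_end)
    length = deleted[1] - deleted[0]
    effect = FrameEffect.IN_FRAME if length % 3 == 0 else FrameEffect.FRAMESHIFT
    hits = _span_hits_key_domain(gene, deleted)
    return DeNovoConsequence(
        frame_effect=effect, deleted_span=deleted, hits_key_domain=hits
    )


def _span_hits_key_domain(gene: OrientedGene, span: tuple[int, int]) -> bool:
    lo, hi = span
    try:
        c_lo, _ = gene.oriented_to_cdna(lo)
        c_hi, _ = gene.oriented_to_cdna(hi - 1)
    except ValueError:
        return False
    for dom in gene.model.key_domains:
        d_lo = (dom.codon_start - 1) * 3 + 1
        d_hi = dom.codon_end * 3
        if c_lo <= d_hi and c_hi >= d_lo:
            return True
    return False
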