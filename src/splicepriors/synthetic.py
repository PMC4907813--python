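"""Synthetic toy-gene fixtures for offline, download-free testing.

The generator builds a small multi-exon gene on a random reference contig
with consensus donor/acceptor junction windows, weight-matrix splice models
whose canonical GT/AG dinucleotides carry near-deterministic probability mass
(so disrupting them is catastrophic, as for real splice sites), reference
junction-score statistics estimated from sampled wild-type-like junctions,
and a truth table of spiked variants:

* a planted near-consensus exonic 9-mer that one SNV completes into a
  high-scoring de novo donor (frameshifting span to the native donor),
* a canonical-dinucleotide disruption of a native donor, and
* a verified-neutral exonic SNV.

Expected categories in the truth table are computed by direct weight-matrix
arithmetic at generation time, independent of the window-scan machinery, and
the generator raises if a spike cannot be verified.  Regeneration from the
same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import JunctionStats, reference_stats
from .gene_model import GeneModel, OrientedGene, SpecialRegion, KeyDomain, VariantRecord
from .splice_fitness import BASES, BASE_INDEX, SiteType, WeightMatrixModel

__all__ = ["SpikedVariant", "ToyGeneFixture", "generate_toy_gene"]

# Consensus sequences and per-position target probabilities of the consensus
# base.  Canonical GT (donor window positions 4-5) and AG (acceptor 19-20)
# carry near-deterministic mass whenever junction_strength > 0; the other
# positions scale linearly with junction_strength.
_DONOR_CONSENSUS = "CAGGTAAGT"
_DONOR_TARGETS = (0.55, 0.60, 0.65, None, None, 0.70, 0.60, 0.55, 0.50)
_ACCEPTOR_CONSENSUS = "TTTTCTTTTTCTTTTCTTAGGTG"
_ACCEPTOR_TARGETS = (
    0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45,
    0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45, 0.45,
    None, None, 0.50, 0.45, 0.45,
)
_CANONICAL_P = 0.9995


def _build_matrix(
    consensus: str,
    targets: tuple[float | None, ...],
    strength: float,
    site_type: SiteType,
) -> WeightMatrixModel:
    k = len(consensus)
    probs = np.full((k, 4), 0.25)
    for i, (cons, target) in enumerate(zip(consensus, targets)):
        if strength <= 0:
            continue
        p = _CANONICAL_P if target is None else 0.25 + (target - 0.25) * strength
        rest = (1.0 - p) / 3
        probs[i] = rest
        probs[i, BASE_INDEX[cons]] = p
    return WeightMatrixModel(site_type=site_type, probs=probs)


def _matrix_score(model: WeightMatrixModel, kmer: str) -> float:
    """Direct log-odds sum, used for generation-time truth verification."""
    log_odds = np.log2(model.probs / model.background[None, :])
    return float(
        sum(log_odds[i, BASE_INDEX[b]] for i, b in enumerate(kmer))
    )


def _sample_junction_kmers(
    model: WeightMatrixModel,
    consensus: str,
    targets: tuple[float | None, ...],
    n: int,
    rng: np.random.Generator,
) -> list[str]:
    """Sample wild-type-like junction k-mers: canonical positions fixed to
    consensus (real wild-type junctions keep GT/AG), others drawn from the
    matrix."""
    out = []
    for _ in range(n):
        bases = []
        for i, (cons, target) in enumerate(zip(consensus, targets)):
            if target is None:
                bases.append(cons)
            else:
                bases.append(rng.choice(list(BASES), p=model.probs[i]))
        out.append("".join(bases))
    return out


@dataclass(frozen=True)
class SpikedVariant:
    """One truth-table entry: a variant with its expected assessment."""

    hgvs_c: str
    variant: VariantRecord
    channel: str  # "denovo_donor" | "native_donor" | "neutral"
    expected_category: str
    expected_prior: float
    note: str = ""


@dataclass
class ToyGeneFixture:
    seed: int
    contig: str
    reference: str
    gene: GeneModel
    donor_model: WeightMatrixModel
    acceptor_model: WeightMatrixModel
    donor_stats: JunctionStats | None
    acceptor_stats: JunctionStats | None
    truth: list[SpikedVariant]
    calibration_usable: bool = True

    def oriented(self) -> OrientedGene:
        return OrientedGene(self.gene, self.reference)

    @property
    def models(self) -> dict[SiteType, WeightMatrixModel]:
        return {SiteType.DONOR: self.donor_model, SiteType.ACCEPTOR: self.acceptor_model}

    @property
    def stats(self) -> dict[SiteType, JunctionStats]:
        if not self.calibration_usable:
            raise ValueError(
                "fixture generated with junction_strength 0 is unusable for "
                "calibration (degenerate junction-score distribution)"
            )
        return {SiteType.DONOR: self.donor_stats, SiteType.ACCEPTOR: self.acceptor_stats}

    # -- text artifacts ------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        lines = [f">{self.contig}"]
        for i in range(0, len(self.reference), 70):
            lines.append(self.reference[i : i + 70])
        Path(path).write_text("\n".join(lines) + "\n")

    def write_vcf(self, path: str | Path) -> None:
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={self.contig},length={len(self.reference)}>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for spike in sorted(self.truth, key=lambda s: s.variant.pos):
            v = spike.variant
            lines.append(
                f"{v.contig}\t{v.pos}\t{spike.hgvs_c}\t{v.ref}\t{v.alt}\t.\t.\t."
            )
        Path(path).write_text("\n".join(lines) + "\n")


def generate_toy_gene(
    seed: int = 0,
    n_exons: int = 3,
    exon_lengths: tuple[int, ...] | None = None,
    junction_strength: float = 0.9,
    intron_length: int = 80,
    flank: int = 80,
    strand: str = "+",
    n_reference_junctions: int = 110,
    ceiling_exon: int | None = None,
) -> ToyGeneFixture:
    """Build a deterministic toy-gene fixture.

    ``junction_strength`` in [0, 1] scales how consensus-like the junction
    weight matrices are; 0 produces background-level junctions and a fixture
    flagged unusable for calibration.  ``ceiling_exon`` (1-based) optionally
    configures a 0.50 prior ceiling over that exon and its proximal splice
    windows.
    """
    if n_exons < 2:
        raise ValueError("need at least 2 exons")
    if exon_lengths is None:
        exon_lengths = tuple([36, 45] * ((n_exons + 1) // 2))[:n_exons]
        total = sum(exon_lengths)
        if total % 3:
            exon_lengths = exon_lengths[:-1] + (exon_lengths[-1] + 3 - total % 3,)
    if len(exon_lengths) != n_exons:
        raise ValueError("exon_lengths does not match n_exons")
    if min(exon_lengths) < 24:
        raise ValueError("exon lengths must be >= 24 to host junction windows")
    if intron_length < 40:
        raise ValueError("introns must be >= 40 to separate junction windows")

    rng = np.random.default_rng(seed)
    donor_model = _build_matrix(
        _DONOR_CONSENSUS, _DONOR_TARGETS, junction_strength, SiteType.DONOR
    )
    acceptor_model = _build_matrix(
        _ACCEPTOR_CONSENSUS, _ACCEPTOR_TARGETS, junction_strength, SiteType.ACCEPTOR
    )

    # -- assemble the plus-oriented sequence --------------------------------
    parts: list[str] = []
    exon_bounds: list[tuple[int, int]] = []  # oriented 0-based half-open
    pos = 0

    def random_seq(n: int) -> str:
        return "".join(rng.choice(list(BASES), size=n))

    parts.append(random_seq(flank))
    pos += flank
    for i, length in enumerate(exon_lengths):
        exon_bounds.append((pos, pos + length))
        parts.append(random_seq(length))
        pos += length
        if i < n_exons - 1:
            parts.append(random_seq(intron_length))
            pos += intron_length
    parts.append(random_seq(flank))
    seq = list("".join(parts))

    # overwrite junction windows with the consensus k-mers
    for i, (s, e) in enumerate(exon_bounds):
        if i < n_exons - 1:
            seq[e - 3 : e + 6] = _DONOR_CONSENSUS
        if i > 0:
            seq[s - 20 : s + 3] = _ACCEPTOR_CONSENSUS

    # -- reference junction statistics --------------------------------------
    donor_stats = acceptor_stats = None
    usable = junction_strength > 0
    if usable:
        donor_scores = [
            _matrix_score(donor_model, km)
            for km in _sample_junction_kmers(
                donor_model, _DONOR_CONSENSUS, _DONOR_TARGETS,
                n_reference_junctions, rng,
            )
        ]
        acceptor_scores = [
            _matrix_score(acceptor_model, km)
            for km in _sample_junction_kmers(
                acceptor_model, _ACCEPTOR_CONSENSUS, _ACCEPTOR_TARGETS,
                n_reference_junctions, rng,
            )
        ]
        donor_stats = reference_stats(donor_scores, SiteType.DONOR)
        acceptor_stats = reference_stats(acceptor_scores, SiteType.ACCEPTOR)

    # -- spike 1: de novo donor inside exon 2 (or exon 1 for 2-exon genes) --
    truth: list[SpikedVariant] = []
    spike_exon = 1 if n_exons >= 3 else 0
    s_e, e_e = exon_bounds[spike_exon]
    junction = e_e - 13  # deleted span 13 bp -> frameshift
    window_lo = junction - 3
    planted = _DONOR_CONSENSUS[:6] + "T" + _DONOR_CONSENSUS[7:]  # one mismatch
    seq[window_lo : window_lo + 9] = planted
    denovo_pos = window_lo + 6  # the mismatched base
    denovo_ref, denovo_alt = "T", _DONOR_CONSENSUS[6]

    reference = "".join(seq)

    if usable:
        mutated_local = (
            reference[: denovo_pos] + denovo_alt + reference[denovo_pos + 1 :]
        )
        frame_scores = [
            _matrix_score(donor_model, mutated_local[s : s + 9])
            for s in range(denovo_pos - 8, denovo_pos + 1)
        ]
        best = max(frame_scores)
        planted_score = _matrix_score(donor_model, _DONOR_CONSENSUS)
        if not np.isclose(best, planted_score) or frame_scores.count(best) != 1:
            raise RuntimeError("de novo donor spike failed generation-time check")
        z_dn = (planted_score - donor_stats.mean) / donor_stats.sd
        if z_dn < 0:
            raise RuntimeError("planted de novo donor does not reach z >= 0")

    # -- spike 2: canonical-dinucleotide disruption of exon 1's donor -------
    d_exon = 0
    d_s, d_end = exon_bounds[d_exon]
    gt_pos = d_end  # first intronic base (+1 G of the GT)
    nat_ref, nat_alt = "G", "A"
    if usable:
        wt_window = reference[d_end - 3 : d_end + 6]
        mut_window = wt_window[:3] + nat_alt + wt_window[4:]
        z_ref = (_matrix_score(donor_model, wt_window) - donor_stats.mean) / donor_stats.sd
        z_alt = (_matrix_score(donor_model, mut_window) - donor_stats.mean) / donor_stats.sd
        if not (z_alt < -2 and z_ref - z_alt >= 0.5):
            raise RuntimeError("canonical disruption spike failed generation-time check")

    # -- spike 3: verified-neutral exonic SNV -------------------------------
    neutral = None
    candidates: list[int] = []
    for lo, hi in exon_bounds:
        for cand in range(lo + 6, hi - 6):
            if window_lo - 9 <= cand < window_lo + 18:  # keep clear of the spike
                continue
            candidates.append(cand)
    if usable:
        for cand in candidates:
            ref_b = reference[cand]
            for alt_b in BASES:
                if alt_b == ref_b:
                    continue
                mut = reference[:cand] + alt_b + reference[cand + 1 :]
                zs = [
                    (_matrix_score(donor_model, mut[s : s + 9]) - donor_stats.mean)
                    / donor_stats.sd
                    for s in range(cand - 8, cand + 1)
                ]
                if max(zs) < -2:
                    neutral = (cand, ref_b, alt_b)
                    break
            if neutral:
                break
        if neutral is None:
            raise RuntimeError("no verifiable neutral exonic SNV found")
    else:
        cand = candidates[0]
        ref_b = reference[cand]
        neutral = (cand, ref_b, next(b for b in BASES if b != ref_b))

    # -- gene model -----------------------------------------------------------
    contig = f"toy{seed}"
    key_domains = [KeyDomain("toy_domain", 5, 10)]
    special_regions = []
    if ceiling_exon is not None:
        special_regions.append(
            SpecialRegion(
                label=f"exon{ceiling_exon}_ceiling",
                exons=(ceiling_exon,),
                ceiling=0.50,
                include_flanks=True,
                channels="all",
            )
        )
    minus = strand == "-"
    L = len(reference)

    def to_genomic(opos: int) -> int:
        return L - opos if minus else opos + 1

    if minus:
        # the model's genomic reference is the reverse complement of the
        # oriented assembly, so oriented coordinates map to descending
        # genomic positions
        from .gene_model import reverse_complement

        genomic_ref = reverse_complement(reference)
        exons_g = [
            (to_genomic(e - 1), to_genomic(s)) for s, e in exon_bounds
        ]
        cds_start = to_genomic(0 + exon_bounds[0][0])
        cds_end = to_genomic(exon_bounds[-1][1] - 1)
        cds_start, cds_end = min(cds_start, cds_end), max(cds_start, cds_end)
    else:
        genomic_ref = reference
        exons_g = [(s + 1, e) for s, e in exon_bounds]
        cds_start = exon_bounds[0][0] + 1
        cds_end = exon_bounds[-1][1]

    gene = GeneModel(
        gene_id=f"TOY{seed}",
        contig=contig,
        strand=strand,
        exons=exons_g,
        cds_start=cds_start,
        cds_end=cds_end,
        key_domains=key_domains,
        special_regions=special_regions,
    )

    fixture = ToyGeneFixture(
        seed=seed,
        contig=contig,
        reference=genomic_ref,
        gene=gene,
        donor_model=donor_model,
        acceptor_model=acceptor_model,
        donor_stats=donor_stats,
        acceptor_stats=acceptor_stats,
        truth=[],
        calibration_usable=usable,
    )

    og = fixture.oriented()

    # map fixture-local oriented coordinates into the OrientedGene frame
    shift = og.genomic_to_oriented(to_genomic(0))

    def record_for(opos: int, ref_b: str, alt_b: str) -> VariantRecord:
        from .gene_model import OrientedVariant

        return og.deorient_variant(OrientedVariant(opos + shift, ref_b, alt_b))

    from .hgvs import format_hgvs_c

    v1 = record_for(denovo_pos, denovo_ref, denovo_alt)
    truth.append(
        SpikedVariant(
            hgvs_c=format_hgvs_c(v1, og),
            variant=v1,
            channel="denovo_donor",
            expected_category="increased",
            expected_prior=0.64,
            note="completes a planted near-consensus donor 9-mer; 13 bp "
            "frameshifting deletion to the native donor",
        )
    )
    v2 = record_for(gt_pos, nat_ref, nat_alt)
    truth.append(
        SpikedVariant(
            hgvs_c=format_hgvs_c(v2, og),
            variant=v2,
            channel="native_donor",
            expected_category="high",
            expected_prior=0.97,
            note="disrupts the canonical +1 G of the native donor",
        )
    )
    v3 = record_for(*neutral)
    truth.append(
        SpikedVariant(
            hgvs_c=format_hgvs_c(v3, og),
            variant=v3,
            channel="neutral",
            expected_category="weak_null_low",
            expected_prior=0.02,
            note="verified: no variant-containing donor frame reaches z >= -2",
        )
    )
    fixture.truth = truth
    return fixture
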