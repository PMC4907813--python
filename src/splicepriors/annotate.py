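"""Per-variant splice assessment, VCF annotation and bulk SNV prior tables.

Every in-scope variant is assessed on three channels:

* **native damage** — fixed-frame scoring of any junction window the variant
  overlaps, z-standardized and categorized (improved/minimal/moderate/high);
* **de novo donor** — the sliding-window scan, categorized with the
  promotion rule and gated on the mRNA consequence (frameshift / key-domain
  loss) before a prior applies;
* **de novo acceptor** — best scan score and z only (report-only channel: no
  evidence of risk was found for de novo acceptors, so no prior is derived).

The channel priors, an optional externally supplied missense prior, the
initiator-codon override and any configured region ceilings are combined by
:func:`splicepriors.calibration.combine_priors` (max rule).  Exonic variants
within 3 bp of an exon end keep their native-junction analysis but are
excluded from the de novo donor prior, mirroring the calibration's exclusion
of near-junction substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from .calibration import (
    DeNovoCategory,
    JunctionStats,
    NativeDamageCategory,
    PriorConfig,
    PriorResult,
    classify_denovo_donor,
    classify_native,
    combine_priors,
    native_prior as native_prior_of,
    denovo_prior as denovo_prior_of,
    zscore,
)
from .gene_model import (
    ACCEPTOR_FLANK,
    DONOR_FLANK,
    OrientedGene,
    OrientedVariant,
    Region,
    VariantRecord,
)
from .hgvs import format_hgvs_c
from .splice_fitness import BASES, SiteType, SpliceFitnessModel
from .window_scan import (
    DeNovoConsequence,
    denovo_consequence,
    scan_denovo,
    score_native_junction,
)

__all__ = [
    "NativeChannel",
    "DeNovoDonorChannel",
    "AnnotationRecord",
    "assess_variant",
    "annotate_vcf",
    "score_all_possible_snvs",
]

# distance from an exon end within which a variant keeps native analysis but
# gets no de novo-donor prior
_DENOVO_EXON_END_EXCLUSION = 3


@dataclass(frozen=True)
class NativeChannel:
    exon_index: int
    site_type: SiteType
    ref_score: float
    alt_score: float
    z_ref: float
    z_alt: float
    category: NativeDamageCategory
    prior: float
    protection_applied: bool


@dataclass(frozen=True)
class DeNovoDonorChannel:
    best_score: float
    z: float
    category: DeNovoCategory
    consequence: DeNovoConsequence | None
    prior: float | None  # None when the variant is excluded from this prior


@dataclass(frozen=True)
class AnnotationRecord:
    variant: VariantRecord
    hgvs_c: str | None
    region: Region
    native: NativeChannel | None
    denovo_donor: DeNovoDonorChannel | None
    denovo_acceptor: tuple[float, float] | None  # (best score, z)
    priors: PriorResult | None

    @property
    def in_scope(self) -> bool:
        return self.region is not Region.OUT_OF_SCOPE


def _applicable_ceilings(
    gene: OrientedGene, ov: OrientedVariant
) -> list[tuple[str, float, str]]:
    out = []
    v_lo, v_hi = ov.start, max(ov.end, ov.start + 1)
    for region in gene.model.special_regions:
        for exon_no in region.exons:
            s, e = gene.exons[exon_no - 1]
            lo = s - ACCEPTOR_FLANK if region.include_flanks else s
            hi = e + DONOR_FLANK if region.include_flanks else e
            if v_lo < hi and v_hi > lo:
                out.append((region.label, region.ceiling, region.channels))
                break
    return out


def _in_initiator_codon(gene: OrientedGene, ov: OrientedVariant) -> bool:
    try:
        init = {gene.cdna_to_oriented(c) for c in (1, 2, 3)}
    except ValueError:
        return False
    v_lo, v_hi = ov.start, max(ov.end, ov.start + 1)
    return any(v_lo <= p < v_hi for p in init)


def assess_variant(
    gene: OrientedGene,
    variant: VariantRecord | OrientedVariant,
    models: dict[SiteType, SpliceFitnessModel],
    stats: dict[SiteType, JunctionStats],
    config: PriorConfig | None = None,
    missense_prior: float | None = None,
) -> AnnotationRecord:
    """Full three-channel splice assessment of one variant."""
    config = config or PriorConfig()
    if isinstance(variant, OrientedVariant):
        ov = variant
        record = gene.deorient_variant(ov)
    else:
        record = variant
        ov = gene.orient_variant(variant)
    region = gene.region_of(ov.start, max(ov.end, ov.start + 1))
    try:
        hgvs = format_hgvs_c(record, gene)
    except Exception:
        hgvs = None
    if region is Region.OUT_OF_SCOPE:
        return AnnotationRecord(record, hgvs, region, None, None, None, None)

    rules: list[str] = []

    # -- native channel ------------------------------------------------------
    native: NativeChannel | None = None
    for exon_index, site_type, _window in gene.junction_windows():
        scored = score_native_junction(gene, exon_index, site_type, models[site_type], ov)
        if scored is None:
            continue
        ref_score, alt_score = scored
        st_stats = stats[site_type]
        z_ref = zscore(ref_score, st_stats)
        z_alt = zscore(alt_score, st_stats)
        category = classify_native(site_type, z_ref, z_alt, config.protection_rule)
        unprotected = classify_native(site_type, z_ref, z_alt, None)
        channel = NativeChannel(
            exon_index=exon_index,
            site_type=site_type,
            ref_score=ref_score,
            alt_score=alt_score,
            z_ref=z_ref,
            z_alt=z_alt,
            category=category,
            prior=native_prior_of(category, config),
            protection_applied=category is not unprotected,
        )
        if native is None or channel.prior > native.prior:
            native = channel
    if native is not None and native.protection_applied:
        rules.append("protection")

    # -- de novo donor channel ----------------------------------------------
    scan_d = scan_denovo(gene, ov, models[SiteType.DONOR])
    z_dn = zscore(scan_d.best_score, stats[SiteType.DONOR])
    exon_index = gene.exon_of(ov.start)
    z_wt = None
    if exon_index is not None and exon_index < len(gene.exons) - 1:
        wt_kmer = gene.native_kmer(exon_index, SiteType.DONOR)
        z_wt = zscore(models[SiteType.DONOR].score(wt_kmer), stats[SiteType.DONOR])
    category_d = classify_denovo_donor(z_dn, z_wt if z_wt is not None else z_dn)
    if category_d.promoted:
        rules.append("promotion")
    consequence = denovo_consequence(gene, scan_d.implied_junction)
    eligible = False
    if exon_index is not None:
        s, e = gene.exons[exon_index]
        near_end = (
            ov.start - s < _DENOVO_EXON_END_EXCLUSION
            or e - max(ov.end, ov.start + 1) < _DENOVO_EXON_END_EXCLUSION
        )
        eligible = not near_end
    dn_prior = denovo_prior_of(category_d, consequence, config) if eligible else None
    denovo_channel = DeNovoDonorChannel(
        best_score=scan_d.best_score,
        z=z_dn,
        category=category_d,
        consequence=consequence,
        prior=dn_prior,
    )

    # -- de novo acceptor (report-only) --------------------------------------
    scan_a = scan_denovo(gene, ov, models[SiteType.ACCEPTOR])
    z_da = zscore(scan_a.best_score, stats[SiteType.ACCEPTOR])
    acceptor_report = (scan_a.best_score, z_da)

    # -- combine -------------------------------------------------------------
    native_p = native.prior if native is not None else None
    components_present = any(
        p is not None for p in (native_p, dn_prior, missense_prior)
    )
    if not components_present:
        # terminal-exon flank or near-end exonic position with no junction
        # window: the splice channel floors at the baseline exonic prior
        dn_for_combine = config.baseline_exonic_prior
        rules.append("baseline_floor")
    else:
        dn_for_combine = dn_prior
    priors = combine_priors(
        native=native_p,
        denovo=dn_for_combine,
        missense=missense_prior,
        config=config,
        in_initiator_codon=_in_initiator_codon(gene, ov),
        ceilings=_applicable_ceilings(gene, ov),
        native_category=native.category if native else None,
        denovo_category=category_d,
        extra_rules=rules,
    )
    return AnnotationRecord(
        variant=record,
        hgvs_c=hgvs,
        region=region,
        native=native,
        denovo_donor=denovo_channel,
        denovo_acceptor=acceptor_report,
        priors=priors,
    )


# ---------------------------------------------------------------------------
# VCF annotation
# ---------------------------------------------------------------------------

_INFO_FIELDS = [
    ("SPLC_SCOPE", 1, "String", "Splice-assessment scope (in_scope/out_of_scope)"),
    ("SPLC_HGVSC", 1, "String", "Normalized HGVS c. expression"),
    ("SPLC_NAT_CAT", 1, "String", "Native junction damage category"),
    ("SPLC_NAT_ZREF", 1, "Float", "Wild-type junction z-score"),
    ("SPLC_NAT_ZALT", 1, "Float", "Variant junction z-score"),
    ("SPLC_NAT_PRIOR", 1, "Float", "Native damage prior probability"),
    ("SPLC_DNV_DON_Z", 1, "Float", "Best de novo donor frame z-score"),
    ("SPLC_DNV_DON_CAT", 1, "String", "De novo donor category"),
    ("SPLC_DNV_DON_PRIOR", 1, "Float", "De novo donor prior probability"),
    ("SPLC_DNV_ACC_Z", 1, "Float", "Best de novo acceptor frame z-score (report only)"),
    ("SPLC_PRIOR", 1, "Float", "Selected combined prior probability"),
    ("SPLC_RULES", ".", "String", "Applied special rules"),
]


def annotate_vcf(
    vcf_in: str | Path,
    vcf_out: str | Path,
    gene: OrientedGene,
    models: dict[SiteType, SpliceFitnessModel],
    stats: dict[SiteType, JunctionStats],
    config: PriorConfig | None = None,
    missense_priors: dict[str, float] | None = None,
) -> int:
    """Annotate a VCF with splice-assessment INFO tags.

    Records outside the gene's contig or analysed region pass through with a
    scope flag.  Missense priors are looked up by "CHROM:POS:REF:ALT" keys.
    Floating tags are fixed at 3 decimals.  Returns the number of in-scope
    records annotated.
    """
    missense_priors = missense_priors or {}
    n_annotated = 0
    with pysam.VariantFile(str(vcf_in)) as vcf:
        header = vcf.header.copy()
        for tag, number, vtype, desc in _INFO_FIELDS:
            if tag not in header.info:
                header.info.add(tag, number, vtype, desc)
        with pysam.VariantFile(str(vcf_out), "w", header=header) as out:
            for rec in vcf:
                new = out.new_record(
                    contig=rec.contig,
                    start=rec.start,
                    stop=rec.stop,
                    alleles=rec.alleles,
                    id=rec.id,
                    qual=rec.qual,
                    filter=rec.filter,
                    info=dict(rec.info),
                )
                if rec.contig != gene.model.contig or rec.alts is None:
                    new.info["SPLC_SCOPE"] = "out_of_scope"
                    out.write(new)
                    continue
                variant = VariantRecord(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                )
                key = f"{rec.contig}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
                ann = assess_variant(
                    gene, variant, models, stats, config,
                    missense_prior=missense_priors.get(key),
                )
                _write_info(new, ann)
                if ann.in_scope:
                    n_annotated += 1
                out.write(new)
    return n_annotated


def _round3(x: float) -> float:
    return float(f"{x:.3f}")


def _write_info(rec, ann: AnnotationRecord) -> None:
    rec.info["SPLC_SCOPE"] = "in_scope" if ann.in_scope else "out_of_scope"
    if ann.hgvs_c:
        rec.info["SPLC_HGVSC"] = ann.hgvs_c.replace(";", ",")
    if ann.native is not None:
        rec.info["SPLC_NAT_CAT"] = ann.native.category.value
        rec.info["SPLC_NAT_ZREF"] = _round3(ann.native.z_ref)
        rec.info["SPLC_NAT_ZALT"] = _round3(ann.native.z_alt)
        rec.info["SPLC_NAT_PRIOR"] = _round3(ann.native.prior)
    if ann.denovo_donor is not None:
        rec.info["SPLC_DNV_DON_Z"] = _round3(ann.denovo_donor.z)
        rec.info["SPLC_DNV_DON_CAT"] = ann.denovo_donor.category.value.label
        if ann.denovo_donor.prior is not None:
            rec.info["SPLC_DNV_DON_PRIOR"] = _round3(ann.denovo_donor.prior)
    if ann.denovo_acceptor is not None:
        rec.info["SPLC_DNV_ACC_Z"] = _round3(ann.denovo_acceptor[1])
    if ann.priors is not None:
        rec.info["SPLC_PRIOR"] = _round3(ann.priors.selected_prior)
        if ann.priors.applied_rules:
            rec.info["SPLC_RULES"] = ",".join(ann.priors.applied_rules)


# ---------------------------------------------------------------------------
# Bulk all-possible-SNV table
# ---------------------------------------------------------------------------


def score_all_possible_snvs(
    gene: OrientedGene,
    models: dict[SiteType, SpliceFitnessModel],
    stats: dict[SiteType, JunctionStats],
    config: PriorConfig | None = None,
) -> pd.DataFrame:
    """Priors for every possible SNV of the in-scope region.

    Exactly 3 rows per in-scope base (exons plus the -20..+6 flanks), ordered
    by transcript coordinate then alt allele A<C<G<T (transcript strand).
    """
    rows = []
    for lo, hi in gene.in_scope_intervals():
        for opos in range(lo, hi):
            ref = gene.seq[opos]
            for alt in BASES:
                if alt == ref:
                    continue
                ov = OrientedVariant(opos, ref, alt)
                ann = assess_variant(gene, ov, models, stats, config)
                c, off = gene.oriented_to_cdna(opos)
                rows.append(
                    {
                        "gene": gene.model.gene_id,
                        "contig": gene.model.contig,
                        "genomic_pos": ann.variant.pos,
                        "genomic_ref": ann.variant.ref,
                        "genomic_alt": ann.variant.alt,
                        "hgvs_c": ann.hgvs_c,
                        "region": ann.region.value,
                        "native_category": (
                            ann.native.category.value if ann.native else "NA"
                        ),
                        "native_z_ref": (
                            round(ann.native.z_ref, 3) if ann.native else None
                        ),
                        "native_z_alt": (
                            round(ann.native.z_alt, 3) if ann.native else None
                        ),
                        "native_prior": (
                            ann.native.prior if ann.native else None
                        ),
                        "denovo_donor_z": round(ann.denovo_donor.z, 3),
                        "denovo_donor_category": ann.denovo_donor.category.value.label,
                        "denovo_donor_prior": ann.denovo_donor.prior,
                        "denovo_acceptor_z": round(ann.denovo_acceptor[1], 3),
                        "selected_prior": ann.priors.selected_prior,
                        "applied_rules": ";".join(ann.priors.applied_rules),
                    }
                )
    return pd.DataFrame(rows)
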