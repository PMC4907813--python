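"""Sliding-window de novo scan, native junction scoring, and consequences."""

import numpy as np
import pytest

from splicepriors import (
    FrameEffect,
    GeneModel,
    OrientedGene,
    OrientedVariant,
    SiteType,
    denovo_consequence,
    generate_toy_gene,
    scan_denovo,
    score_native_junction,
)
from splicepriors.gene_model import apply_variant
from splicepriors.window_scan import ContextError, scan_denovo_sequence


def brute_force_scan(gene, ov, model):
    """Independent enumeration of every k-mer containing the variant."""
    k = model.site_type.k
    joff = model.site_type.junction_offset
    mutated, cmap = apply_variant(gene.seq, ov)
    a, b = cmap.edited_interval
    b = max(b, a + 1)
    natives = (
        gene.donor_junctions()
        if model.site_type is SiteType.DONOR
        else gene.acceptor_junctions()
    )
    natives_mut = {cmap.forward_boundary(j) for j in natives}
    best = None
    for s in range(a - k + 1, b):
        if s + joff in natives_mut:
            continue
        score = model.score(mutated[s : s + k])
        offset = max(a - s, 0)
        if best is None or score > best[0] or (score == best[0] and offset < best[1]):
            best = (score, offset)
    return best


class TestScanDenovo:
    def test_matches_brute_force_on_random_variants(self, toy, og):
        rng = np.random.default_rng(123)
        intervals = og.in_scope_intervals()
        for _ in range(100):
            lo, hi = intervals[rng.integers(len(intervals))]
            pos = int(rng.integers(lo, hi))
            ref = og.seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            ov = OrientedVariant(pos, ref, alt)
            for st in SiteType:
                result = scan_denovo(og, ov, toy.models[st])
                expected = brute_force_scan(og, ov, toy.models[st])
                assert result.best_score == pytest.approx(expected[0])
                assert result.best_frame_offset == expected[1]

    def test_snv_scores_exactly_k_frames(self, toy, og):
        ov = OrientedVariant(200, og.seq[200], "A" if og.seq[200] != "A" else "C")
        result = scan_denovo(og, ov, toy.models[SiteType.DONOR])
        assert len(result.all_frame_scores) == 9
        result = scan_denovo(og, ov, toy.models[SiteType.ACCEPTOR])
        assert len(result.all_frame_scores) == 23

    def test_unique_consensus_frame_is_identified(self, toy, og):
        # the spiked de novo donor variant completes a planted consensus 9-mer
        spike = toy.truth[0]
        ov = og.orient_variant(spike.variant)
        result = scan_denovo(og, ov, toy.models[SiteType.DONOR])
        consensus_score = toy.donor_model.score("CAGGTAAGT")
        assert result.best_score == pytest.approx(consensus_score)
        # the planted mismatch sits at window position 7 (offset 6)
        assert result.best_frame_offset == 6

    def test_native_junction_frames_are_excluded(self, toy, og):
        # an SNV in the intron right after a native donor: the frame that
        # reproduces the native junction must not win the de novo channel
        j = og.exons[0][1]
        pos = j + 3
        ref = og.seq[pos]
        alt = next(b for b in "ACGT" if b != ref)
        result = scan_denovo(og, OrientedVariant(pos, ref, alt), toy.models[SiteType.DONOR])
        assert result.implied_junction != j

    def test_insufficient_context_raises(self, toy):
        with pytest.raises(ContextError):
            scan_denovo_sequence("ACGTACGT", (2, 3), toy.models[SiteType.DONOR])

    def test_indel_scan_covers_all_overlapping_frames(self, toy, og):
        j = og.exons[0][1]
        anchor = og.seq[j + 1]
        dup = og.seq[j - 6 : j + 2]
        ov = OrientedVariant(j + 1, anchor, anchor + dup)
        result = scan_denovo(og, ov, toy.models[SiteType.DONOR])
        expected = brute_force_scan(og, ov, toy.models[SiteType.DONOR])
        assert result.best_score == pytest.approx(expected[0])
        assert len(result.all_frame_scores) == 9 - 1 + 9  # k-1+alt_len frames


class TestNativeJunction:
    def test_non_overlapping_variant_is_not_applicable(self, toy, og):
        pos = (og.exons[0][0] + og.exons[0][1]) // 2
        ov = OrientedVariant(pos, og.seq[pos], "A" if og.seq[pos] != "A" else "C")
        assert (
            score_native_junction(og, 0, SiteType.DONOR, toy.models[SiteType.DONOR], ov)
            is None
        )

    def test_identity_variant_scores_equal(self, toy, og):
        j = og.exons[0][1]
        ov = OrientedVariant(j, og.seq[j], og.seq[j])
        ref_s, alt_s = score_native_junction(
            og, 0, SiteType.DONOR, toy.models[SiteType.DONOR], ov
        )
        assert ref_s == alt_s

    def test_gt_disruption_lowers_score(self, toy, og):
        j = og.exons[0][1]  # +1 position: the canonical G
        ov = OrientedVariant(j, "G", "A")
        ref_s, alt_s = score_native_junction(
            og, 0, SiteType.DONOR, toy.models[SiteType.DONOR], ov
        )
        assert alt_s < ref_s

    def test_acceptor_window_scoring(self, toy, og):
        s = og.exons[1][0]
        ov = OrientedVariant(s - 1, og.seq[s - 1], "C" if og.seq[s - 1] != "C" else "T")
        scored = score_native_junction(
            og, 1, SiteType.ACCEPTOR, toy.models[SiteType.ACCEPTOR], ov
        )
        assert scored is not None

    def test_strand_symmetry_of_scores(self):
        plus = generate_toy_gene(seed=11, strand="+")
        minus = generate_toy_gene(seed=11, strand="-")
        og_p, og_m = plus.oriented(), minus.oriented()
        for spike_p, spike_m in zip(plus.truth, minus.truth):
            ov_p = og_p.orient_variant(spike_p.variant)
            ov_m = og_m.orient_variant(spike_m.variant)
            r_p = scan_denovo(og_p, ov_p, plus.models[SiteType.DONOR])
            r_m = scan_denovo(og_m, ov_m, minus.models[SiteType.DONOR])
            assert r_p.best_score == pytest.approx(r_m.best_score)
            assert r_p.best_frame_offset == r_m.best_frame_offset


def make_plain_gene(exon_len=150, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=600))
    model = GeneModel(
        gene_id="G",
        contig="c",
        strand="+",
        exons=[(101, 100 + exon_len), (100 + exon_len + 81, 100 + exon_len + 170)],
        cds_start=101,
        cds_end=100 + exon_len + 170,
        key_domains=[],
    )
    return OrientedGene(model, seq)


class TestDeNovoConsequence:
    def test_119bp_deletion_is_frameshift(self):
        og = make_plain_gene()
        exon_end = og.exons[0][1]
        cons = denovo_consequence(og, exon_end - 119)
        assert cons.frame_effect is FrameEffect.FRAMESHIFT
        assert cons.deleted_length == 119

    def test_21bp_deletion_in_frame_no_domain(self):
        og = make_plain_gene()
        exon_end = og.exons[0][1]
        cons = denovo_consequence(og, exon_end - 21)
        assert cons.frame_effect is FrameEffect.IN_FRAME
        assert not cons.hits_key_domain

    def test_21bp_deletion_hitting_domain(self):
        from splicepriors import KeyDomain

        og = make_plain_gene()
        # codons 44..50 end at cDNA 150 == the exon 1 donor: overlaps the span
        og.model.key_domains.append(KeyDomain("d", 44, 50))
        exon_end = og.exons[0][1]
        cons = denovo_consequence(og, exon_end - 21)
        assert cons.frame_effect is FrameEffect.IN_FRAME
        assert cons.hits_key_domain

    def test_intronic_junction_not_applicable(self):
        og = make_plain_gene()
        assert denovo_consequence(og, og.exons[0][1] + 10) is None

    def test_last_exon_not_applicable(self):
        og = make_plain_gene()
        s, e = og.exons[-1]
        assert denovo_consequence(og, (s + e) // 2) is None
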