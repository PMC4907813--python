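"""Z-score standardization, qualitative categories, and prior combination."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from splicepriors import (
    ACCEPTOR_REFERENCE_STATS,
    DONOR_REFERENCE_STATS,
    DeNovoBin,
    DeNovoCategory,
    JunctionStats,
    NativeDamageCategory,
    PriorConfig,
    SiteType,
    classify_denovo_donor,
    classify_native,
    combine_priors,
    denovo_prior,
    midpoint_prior,
    reference_stats,
    zscore,
)
from splicepriors.window_scan import DeNovoConsequence, FrameEffect

DONOR = SiteType.DONOR
ACCEPTOR = SiteType.ACCEPTOR

_SEVERITY = {
    NativeDamageCategory.MINIMAL: 1,
    NativeDamageCategory.MODERATE: 2,
    NativeDamageCategory.HIGH: 3,
}


class TestZscore:
    def test_low_scoring_acceptor_reference_value(self):
        # a wild-type acceptor scoring 3.71 bits standardizes to -1.75
        assert zscore(3.71, ACCEPTOR_REFERENCE_STATS) == pytest.approx(-1.75, abs=0.005)

    def test_score_at_mean_is_zero(self):
        assert zscore(8.02, DONOR_REFERENCE_STATS) == 0.0

    def test_one_sd_above_donor_mean(self):
        assert zscore(10.33, DONOR_REFERENCE_STATS) == pytest.approx(1.0, abs=0.005)


class TestReferenceStats:
    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            reference_stats([8.0, 8.0, 8.0], DONOR)

    def test_two_scores(self):
        s = reference_stats([7.0, 9.0], DONOR)
        assert s.mean == 8.0
        assert s.sd == pytest.approx(np.sqrt(2))
        assert s.n == 2

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            reference_stats([8.0], DONOR)

    def test_recovers_simulated_population(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(8.02, 2.31, size=110)
        s = reference_stats(list(scores), DONOR)
        assert abs(s.mean - 8.02) < 0.5
        assert abs(s.sd - 2.31) < 0.5


class TestClassifyNative:
    @pytest.mark.parametrize(
        "site,z_ref,z_alt,expected",
        [
            (DONOR, 1.0, 1.2, NativeDamageCategory.IMPROVED),
            (DONOR, 0.5, -2.01, NativeDamageCategory.HIGH),
            (DONOR, 1.0, 0.5, NativeDamageCategory.MINIMAL),
            (DONOR, 1.0, -1.0, NativeDamageCategory.MODERATE),
            (ACCEPTOR, 1.0, 0.6, NativeDamageCategory.MINIMAL),
            (ACCEPTOR, 1.0, -1.0, NativeDamageCategory.MODERATE),
            (ACCEPTOR, 1.0, -1.6, NativeDamageCategory.HIGH),
            # boundary values land in moderate (closed bounds)
            (DONOR, 1.0, 0.0, NativeDamageCategory.MODERATE),
            (DONOR, 1.0, -2.0, NativeDamageCategory.MODERATE),
            (ACCEPTOR, 1.0, 0.5, NativeDamageCategory.MODERATE),
            (ACCEPTOR, 1.0, -1.5, NativeDamageCategory.MODERATE),
        ],
    )
    def test_category_bins(self, site, z_ref, z_alt, expected):
        assert classify_native(site, z_ref, z_alt) is expected

    def test_protection_rule_demotes_small_drop(self):
        # low-scoring wild-type acceptor (z -1.75): a 0.25 drop to -2.0 would
        # bin as high but is kept at moderate by the protection rule
        assert (
            classify_native(ACCEPTOR, -1.75, -2.0)
            is NativeDamageCategory.MODERATE
        )

    def test_protection_rule_allows_large_drop(self):
        assert classify_native(ACCEPTOR, -1.75, -2.3) is NativeDamageCategory.HIGH

    def test_protection_rule_donor_threshold(self):
        assert classify_native(DONOR, -1.6, -2.05) is NativeDamageCategory.MODERATE
        assert classify_native(DONOR, -1.4, -2.05) is NativeDamageCategory.HIGH

    @given(
        z_ref=st.floats(-3, 3, allow_nan=False),
        z1=st.floats(-6, 3, allow_nan=False),
        z2=st.floats(-6, 3, allow_nan=False),
        site=st.sampled_from([DONOR, ACCEPTOR]),
    )
    def test_monotone_severity_in_z_alt(self, z_ref, z1, z2, site):
        lo, hi = min(z1, z2), max(z1, z2)
        if hi > z_ref:  # keep to the non-improved branch
            return
        c_lo = classify_native(site, z_ref, lo)
        c_hi = classify_native(site, z_ref, hi)
        assert _SEVERITY[c_lo] >= _SEVERITY[c_hi]


class TestClassifyDeNovo:
    def test_moderate_promoted_to_increased(self):
        # de novo z -0.63 against a weak wild-type donor at z -1.44
        cat = classify_denovo_donor(-0.63, -1.44)
        assert cat.value is DeNovoBin.INCREASED
        assert cat.promoted

    def test_weak_promoted_to_moderate(self):
        cat = classify_denovo_donor(-2.5, -2.6)
        assert cat.value is DeNovoBin.MODERATE
        assert cat.promoted

    def test_no_promotion_below_wild_type(self):
        cat = classify_denovo_donor(-3.0, 1.0)
        assert cat.value is DeNovoBin.WEAK_NULL_LOW
        assert not cat.promoted

    @given(
        z_dn=st.floats(-6, 4, allow_nan=False),
        z_wt=st.floats(-6, 4, allow_nan=False),
    )
    def test_promotion_never_skips_or_demotes(self, z_dn, z_wt):
        raw = classify_denovo_donor(z_dn, z_dn)  # promotion impossible
        final = classify_denovo_donor(z_dn, z_wt)
        assert final.value - raw.value in (0, 1)
        if final.promoted:
            assert final.value - raw.value == 1


def frameshift_consequence():
    return DeNovoConsequence(FrameEffect.FRAMESHIFT, (0, 119), False)


def inframe_consequence(hits=False):
    return DeNovoConsequence(FrameEffect.IN_FRAME, (0, 21), hits)


class TestDeNovoPrior:
    def test_increased_frameshift(self):
        cat = DeNovoCategory(DeNovoBin.INCREASED)
        assert denovo_prior(cat, frameshift_consequence(), PriorConfig()) == 0.64

    def test_increased_in_frame_outside_domains_gets_baseline(self):
        cat = DeNovoCategory(DeNovoBin.INCREASED)
        assert denovo_prior(cat, inframe_consequence(), PriorConfig()) == 0.02

    def test_in_frame_domain_hit_uses_category_prior(self):
        cat = DeNovoCategory(DeNovoBin.MODERATE)
        assert denovo_prior(cat, inframe_consequence(hits=True), PriorConfig()) == 0.30

    def test_weak_frameshift(self):
        cat = DeNovoCategory(DeNovoBin.WEAK_NULL_LOW)
        assert denovo_prior(cat, frameshift_consequence(), PriorConfig()) == 0.02


class TestMidpointPrior:
    @pytest.mark.parametrize(
        "point,ci,expected",
        [
            (0.01, (0.00, 0.04), 0.02),
            (0.00, (0.00, 0.08), 0.04),
            (0.34, (0.15, 0.55), 0.34),
        ],
    )
    def test_reassignment(self, point, ci, expected):
        assert midpoint_prior(point, ci) == pytest.approx(expected)

    def test_malformed_ci_rejected(self):
        with pytest.raises(ValueError):
            midpoint_prior(0.5, (0.6, 0.9))


class TestCombinePriors:
    def test_max_of_splicing_and_missense(self):
        res = combine_priors(denovo=0.64, missense=0.02)
        assert res.selected_prior == 0.64

    def test_splicing_only(self):
        res = combine_priors(native=0.04)
        assert res.selected_prior == 0.04
        assert res.missense_prior is None

    def test_all_channel_ceiling_caps_selected(self):
        res = combine_priors(
            native=0.97, ceilings=[("exon9_10", 0.50, "all")]
        )
        assert res.selected_prior == 0.50
        assert "ceiling:exon9_10" in res.applied_rules

    def test_splice_ceiling_spares_missense(self):
        # a protein-truncation/missense prior is not capped by a splice-only
        # ceiling region
        res = combine_priors(
            native=0.97, missense=0.81, ceilings=[("exon12", 0.50, "splice")]
        )
        assert res.selected_prior == 0.81
        assert "ceiling:exon12" in res.applied_rules

    def test_initiator_met_override(self):
        res = combine_priors(denovo=0.02, in_initiator_codon=True)
        assert res.selected_prior == 0.97
        assert "initiator_met" in res.applied_rules

    def test_no_components_is_error(self):
        with pytest.raises(ValueError):
            combine_priors()

    def test_ceiling_exhaustive_on_fixture_gene(self):
        from splicepriors import generate_toy_gene, score_all_possible_snvs

        fx = generate_toy_gene(seed=3, ceiling_exon=2)
        og = fx.oriented()
        df = score_all_possible_snvs(og, fx.models, fx.stats)
        s, e = og.exons[1]
        in_region = df["hgvs_c"].map(
            lambda h: any(
                og.orient_variant(v).start in range(s - 20, e + 6)
                for v in [__import__("splicepriors").parse_hgvs_c(h, og)]
            )
        )
        assert (df.loc[in_region, "selected_prior"] <= 0.50).all()
        # outside the region the plain max applies: some high priors survive
        assert (df.loc[~in_region, "selected_prior"] > 0.50).any()


class TestPriorConfig:
    def test_defaults_are_calibrated_table_values(self):
        cfg = PriorConfig()
        assert cfg.native_priors[NativeDamageCategory.HIGH] == 0.97
        assert cfg.native_priors[NativeDamageCategory.MODERATE] == 0.34
        assert cfg.denovo_priors[DeNovoBin.INCREASED] == 0.64
        assert cfg.baseline_exonic_prior == 0.02

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(baseline_exonic_prior=0.0)

    def test_json_round_trip(self, tmp_path):
        cfg = PriorConfig(initiator_met_prior=0.96)
        path = tmp_path / "priors.json"
        cfg.to_json(path)
        loaded = PriorConfig.from_json(path)
        assert loaded == cfg
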