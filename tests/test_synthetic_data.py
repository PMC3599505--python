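import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import bivarseg as bv


class TestExpectedLrr:
    @pytest.mark.parametrize(
        "c,w,shift,expected",
        [
            (2, 0.0, 0.0, 0.0),
            (2, 0.7, 0.0, 0.0),
            (4, 0.0, 0.0, 1.0),
            (1, 0.5, 0.0, math.log2(1.5 / 2.0)),
            (3, 0.0, -0.5, math.log2(1.5) - 0.5),
        ],
    )
    def test_mixture_formula(self, c, w, shift, expected):
        assert bv.expected_lrr(c, w, shift) == pytest.approx(expected)

    def test_zero_mixture_copy_floored(self):
        assert bv.expected_lrr(0, 0.0, 0.0, floor=-5.0) == -5.0

    def test_contamination_shrinks_towards_diploid(self):
        for c in (0, 1, 3, 4, 5):
            mags = [abs(bv.expected_lrr(c, w)) for w in (0.0, 0.25, 0.5, 0.75, 1.0)]
            assert all(b <= a + 1e-12 for a, b in zip(mags, mags[1:]))


class TestExpectedBaf:
    @pytest.mark.parametrize(
        "b,c,bn,w,expected",
        [
            (1, 2, 1, 0.0, 0.5),
            (0, 1, 1, 0.5, 1.0 / 3.0),
            (3, 3, 1, 0.0, 1.0),
            (1, 3, 1, 0.25, (0.25 + 0.75) / (0.5 + 2.25)),
        ],
    )
    def test_mixture_formula(self, b, c, bn, w, expected):
        assert bv.expected_baf(b, c, bn, w) == pytest.approx(expected)

    def test_pure_normal_limit(self):
        for bn in (0, 1, 2):
            assert bv.expected_baf(3, 5, bn, 1.0) == pytest.approx(bn / 2.0)

    @given(
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=0, max_value=6),
        st.integers(min_value=0, max_value=2),
        st.floats(min_value=0.0, max_value=0.95),
    )
    def test_allele_relabel_symmetry(self, c, b, bn, w):
        b = min(b, c)
        left = bv.expected_baf(b, c, bn, w)
        right = 1.0 - bv.expected_baf(c - b, c, 2 - bn, w)
        assert left == pytest.approx(right, abs=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            bv.expected_baf(0, 0, 0, 0.0)


class TestGenerateProfile:
    def test_changepoints_are_alteration_boundaries(self):
        cfg = bv.GeneratorConfig(pattern="near_diploid", seed=4)
        specs, truth = bv.generate_profile(cfg)
        expected = sorted(
            [a.start_probe for a in specs] + [a.end_probe for a in specs]
        )
        assert truth.true_changepoints.tolist() == expected
        # state arrays agree with the specs
        for a in specs:
            assert (truth.copy_number[a.start_probe : a.end_probe] == a.copy_number).all()
            assert (truth.n_b_alleles[a.start_probe : a.end_probe] == a.n_b_alleles).all()

    def test_no_alterations_no_changepoints(self):
        cfg = bv.GeneratorConfig(pattern="near_diploid", alteration_lengths=(), n_probes_total=500)
        _, truth = bv.generate_profile(cfg)
        assert truth.true_changepoints.size == 0
        assert (truth.copy_number == 2).all()

    def test_deterministic_given_seed(self):
        cfg = bv.GeneratorConfig(pattern="complex", seed=99)
        s1, t1 = bv.generate_profile(cfg)
        s2, t2 = bv.generate_profile(cfg)
        assert s1 == s2
        assert np.array_equal(t1.genotype, t2.genotype)
        assert np.array_equal(t1.true_changepoints, t2.true_changepoints)

    def test_germline_loh_regions_are_homozygous(self):
        cfg = bv.GeneratorConfig(pattern="loh_enriched", seed=7, het_rate=0.9)
        _, truth = bv.generate_profile(cfg)
        in_germ = truth.loh_type == "germline"
        assert in_germ.any()
        assert not (truth.genotype[in_germ] == "AB").any()

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            bv.generate_profile(bv.GeneratorConfig(pattern="near_diploid", n_probes_total=100))

    def test_every_pattern_lays_out(self):
        for pattern in bv.PATTERNS:
            specs, truth = bv.generate_profile(bv.GeneratorConfig(pattern=pattern, seed=0))
            assert len(specs) > 0
            spans = sorted((a.start_probe, a.end_probe) for a in specs)
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                assert e0 < s1  # disjoint with background between


class TestSimulateSample:
    def test_noiseless_diploid_heterozygote(self):
        cfg = bv.GeneratorConfig(
            pattern="near_diploid", alteration_lengths=(), n_probes_total=200,
            sd_lrr=0.0, sd_baf=0.0, het_rate=1.0, missing_baf_rate=0.0,
        )
        _, truth = bv.generate_profile(cfg)
        track = bv.simulate_sample(truth, cfg)
        np.testing.assert_allclose(track.lrr, 0.0, atol=1e-12)
        np.testing.assert_allclose(track.baf, 0.5, atol=1e-12)

    def test_noiseless_homozygous_baf_at_band_edges(self):
        cfg = bv.GeneratorConfig(
            pattern="near_diploid", alteration_lengths=(), n_probes_total=200,
            sd_lrr=0.0, sd_baf=0.0, het_rate=0.0, missing_baf_rate=0.0,
        )
        _, truth = bv.generate_profile(cfg)
        track = bv.simulate_sample(truth, cfg)
        assert set(np.round(track.baf, 12)) <= {0.0, 1.0}
        assert (track.baf[truth.genotype == "BB"] == 1.0).all()

    def test_noise_levels_match_configuration(self):
        cfg = bv.GeneratorConfig(
            pattern="near_diploid", alteration_lengths=(), n_probes_total=100_000,
            missing_baf_rate=0.0, seed=11,
        )
        _, truth = bv.generate_profile(cfg)
        track = bv.simulate_sample(truth, cfg)
        assert np.std(track.lrr) == pytest.approx(cfg.sd_lrr, rel=0.02)
        # LRR noise ~6x the BAF noise by default
        assert cfg.sd_lrr / cfg.sd_baf == pytest.approx(6.0)

    def test_missingness_rate(self):
        cfg = bv.GeneratorConfig(
            pattern="near_diploid", alteration_lengths=(), n_probes_total=50_000,
            missing_baf_rate=0.1, seed=2,
        )
        _, truth = bv.generate_profile(cfg)
        track = bv.simulate_sample(truth, cfg)
        assert np.isnan(track.baf).mean() == pytest.approx(0.1, abs=0.01)

    def test_bit_reproducible(self):
        cfg = bv.GeneratorConfig(pattern="near_triploid", seed=31, contamination=0.25)
        _, truth = bv.generate_profile(cfg)
        a = bv.simulate_sample(truth, cfg)
        b = bv.simulate_sample(truth, cfg)
        assert np.array_equal(a.lrr, b.lrr)
        assert np.array_equal(a.baf, b.baf, equal_nan=True)


class TestSubclonalAlterations:
    def make(self, cell_fraction):
        cfg = bv.GeneratorConfig(
            pattern="near_diploid", sd_lrr=0.0, sd_baf=0.0,
            het_rate=1.0, missing_baf_rate=0.0, seed=9,
        )
        alt = bv.AlterationSpec(100, 50, 4, 2, cell_fraction=cell_fraction)
        truth = bv.profile_from_alterations([alt], 300, cfg)
        return truth, bv.simulate_sample(truth, cfg)

    def test_partial_cell_fraction_gives_intermediate_lrr(self):
        # a 4-copy gain in half the tumour cells reads as effective 3 copies:
        # the continuous mean levels of intra-tumour heterogeneity
        truth_full, full = self.make(1.0)
        truth_half, half = self.make(0.5)
        inside = slice(100, 150)
        assert np.allclose(full.lrr[inside], 1.0)
        assert np.allclose(half.lrr[inside], np.log2(3 / 2))
        assert np.allclose(half.baf[inside], 0.5)  # balanced stays balanced
        assert np.allclose(half.lrr[:100], 0.0)

    def test_subclonal_boundaries_detectable_via_lrr(self):
        truth, _ = self.make(0.5)
        cfg = bv.GeneratorConfig(pattern="near_diploid", het_rate=1.0, seed=9)
        det = bv.detectable_changepoints(truth, cfg)
        assert det.tolist() == [100, 150]

    def test_informative_flag_tracks_heterozygosity(self):
        truth, _ = self.make(1.0)
        assert np.array_equal(truth.informative, truth.genotype == "AB")

    def test_invalid_cell_fraction_rejected(self):
        with pytest.raises(ValueError):
            bv.AlterationSpec(0, 10, 3, 1, cell_fraction=0.0)


class TestDetectableChangepoints:
    def test_copy_number_changes_always_detectable(self):
        cfg = bv.GeneratorConfig(pattern="near_diploid", seed=1)
        _, truth = bv.generate_profile(cfg)
        det = bv.detectable_changepoints(truth, cfg)
        assert np.array_equal(det, truth.true_changepoints)

    def test_germline_loh_is_invisible(self):
        cfg = bv.GeneratorConfig(pattern="loh_enriched", seed=1, contamination=0.25)
        _, truth = bv.generate_profile(cfg)
        det = set(bv.detectable_changepoints(truth, cfg).tolist())
        for a in truth.alterations:
            if a.loh_type == "germline":
                assert a.start_probe not in det and a.end_probe not in det

    def test_copy_neutral_somatic_loh_needs_contamination(self):
        # in a pure tumour, copy-neutral LOH pushes every heterozygous BAF to
        # 0/1, i.e. into the homozygous band that imBAF discards; with normal
        # admixture the band moves inward and becomes informative
        for w, expect in ((0.0, False), (0.25, True)):
            cfg = bv.GeneratorConfig(pattern="complex", seed=1, contamination=w)
            _, truth = bv.generate_profile(cfg)
            det = set(bv.detectable_changepoints(truth, cfg).tolist())
            cnloh = [a for a in truth.alterations
                     if a.loh_type == "somatic" and a.copy_number == 2]
            assert cnloh
            assert all((a.start_probe in det) == expect for a in cnloh)
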