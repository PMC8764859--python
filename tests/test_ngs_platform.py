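"""NGS caller: QC gates, GC normalization, CNV classification, segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgtmosaic import (BiopsyTruth, CellKaryotype, CnEvent, NgsParams,
                       call_ngs, classify_cnv, expected_copy_number,
                       gc_normalize, ngs_qc, render_ngs, segment_cnv,
                       simulate_embryo)


def tri(chrom="21"):
    return CnEvent(chrom=chrom, scope="whole", direction="gain")


def mono(chrom="21"):
    return CnEvent(chrom=chrom, scope="whole", direction="loss")


class TestNgsQc:
    def test_default_fixture_passes(self, default_noise_embryo):
        _, _, ngs = default_noise_embryo
        qc = ngs_qc(ngs)
        assert qc.passed and qc.failures == ()
        assert qc.total_reads >= 700_000
        assert qc.sd < 3.5

    def test_low_map_ratio_fails_with_reason(self, genome, flat_weights,
                                             disomic_truth):
        sig = render_ngs(disomic_truth, flat_weights, genome,
                         NgsParams(map_ratio_mean=75.0, map_ratio_sd=0.0),
                         seed=1)
        qc = ngs_qc(sig)
        assert not qc.passed and "map_ratio" in qc.failures

    def test_gc_imbalance_fails(self, genome, flat_weights, disomic_truth):
        sig = render_ngs(disomic_truth, flat_weights, genome,
                         NgsParams(gc_mean=0.36, gc_sd=0.01), seed=2)
        qc = ngs_qc(sig)
        assert qc.gc_content < 39
        assert not qc.passed and "gc_content" in qc.failures

    def test_read_shortfall_fails(self, genome, flat_weights, disomic_truth):
        sig = render_ngs(disomic_truth, flat_weights, genome,
                         NgsParams(total_reads=400_000), seed=3)
        qc = ngs_qc(sig)
        assert not qc.passed and "total_reads" in qc.failures

    def test_empty_signal_raises(self, genome, flat_weights, disomic_truth):
        sig = render_ngs(disomic_truth, flat_weights, genome, NgsParams(), seed=4)
        sig.df = sig.df.iloc[0:0]
        with pytest.raises(ValueError):
            ngs_qc(sig)


class TestGcNormalize:
    def test_flat_counts_give_unit_ratio(self, genome, flat_weights,
                                         disomic_truth, noiseless_ngs_params):
        sig = render_ngs(disomic_truth, flat_weights, genome,
                         noiseless_ngs_params, seed=5)
        norm = gc_normalize(sig)
        assert np.allclose(norm["ratio"], 1.0, atol=1e-9)

    def test_quadratic_gc_curve_removed(self, genome, flat_weights,
                                        disomic_truth):
        params = NgsParams(deterministic=True, gc_coeffs=(1.0, 0.5, -8.0))
        sig = render_ngs(disomic_truth, flat_weights, genome, params, seed=6)
        norm = gc_normalize(sig)
        auto = norm[~norm["chrom"].isin(["X", "Y"])]
        assert np.quantile(np.abs(auto["ratio"] - 1.0), 0.90) < 0.02
        assert np.median(np.abs(auto["ratio"] - 1.0)) < 0.01

    def test_trisomy_ratio_recovered(self, genome, flat_weights,
                                     noiseless_ngs_params):
        truth = BiopsyTruth.from_fraction(tri(), 1.0, 10)
        sig = render_ngs(truth, flat_weights, genome, noiseless_ngs_params, seed=7)
        norm = gc_normalize(sig)
        on = norm[norm["chrom"] == "21"]["ratio"]
        assert np.allclose(on, 1.5, atol=1e-6)

    def test_too_few_bins_raises(self, genome, flat_weights, disomic_truth,
                                 noiseless_ngs_params):
        sig = render_ngs(disomic_truth, flat_weights, genome,
                         noiseless_ngs_params, seed=8)
        sig.df = sig.df.head(10)
        with pytest.raises(ValueError):
            gc_normalize(sig)


class TestClassifyCnv:
    @pytest.mark.parametrize("value,kind,direction,level", [
        (2.0, "euploid", None, None),
        (2.2, "mosaic", "gain", 20),   # boundary belongs to mosaic
        (1.8, "mosaic", "loss", 20),
        (1.5, "mosaic", "loss", 50),
        (2.5, "mosaic", "gain", 50),
        (2.8, "mosaic", "gain", 80),
        (1.2, "mosaic", "loss", 80),
        (3.0, "aneuploid", "gain", None),
        (1.0, "aneuploid", "loss", None),
        (0.0, "aneuploid", "loss", None),
        (1.81, "euploid", None, None),
        (2.19, "euploid", None, None),
    ])
    def test_examples(self, value, kind, direction, level):
        c = classify_cnv(value)
        assert (c.kind, c.direction, c.level_percent) == (kind, direction, level)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            classify_cnv(-0.1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(v=st.floats(min_value=0.0, max_value=5.0,
                       allow_nan=False, allow_infinity=False))
    def test_partition_and_monotone_ordering(self, v):
        order = {("aneuploid", "loss"): 0, ("mosaic", "loss"): 1,
                 ("euploid", None): 2, ("mosaic", "gain"): 3,
                 ("aneuploid", "gain"): 4}
        c = classify_cnv(v)
        assert (c.kind, c.direction) in order
        c_hi = classify_cnv(min(v + 0.7, 5.0))
        assert order[(c_hi.kind, c_hi.direction)] >= order[(c.kind, c.direction)]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(v=st.floats(min_value=1.2, max_value=2.8,
                       allow_nan=False, allow_infinity=False))
    def test_mosaic_level_identity(self, v):
        c = classify_cnv(v)
        if c.kind == "mosaic":
            assert c.level_percent == int(round(abs(v - 2.0) * 100))


class TestSegmentCnv:
    def test_disomy_one_segment_per_arm_at_two(self, genome, flat_weights,
                                               disomic_truth,
                                               noiseless_ngs_params):
        sig = render_ngs(disomic_truth, flat_weights, genome,
                         noiseless_ngs_params, seed=9)
        segs = segment_cnv(gc_normalize(sig), genome)
        by_chrom_arm = {(s.chrom, s.scope) for s in segs}
        assert all(s.cnv_value == pytest.approx(2.0, abs=1e-9) for s in segs)
        assert ("21", "p") in by_chrom_arm and ("21", "q") in by_chrom_arm

    def test_three_mb_deletion_below_floor(self, genome, flat_weights,
                                           noiseless_ngs_params):
        seg = CnEvent(chrom="5", scope="segment", direction="loss",
                      start_bp=90_000_001, end_bp=93_000_000)
        truth = BiopsyTruth.from_fraction(seg, 1.0, 10)
        sig = render_ngs(truth, flat_weights, genome, noiseless_ngs_params, seed=10)
        d = call_ngs(sig, genome)
        assert all(e.chrom != "5" for e in d.events)

    def test_five_mb_deletion_detected(self, genome, flat_weights,
                                       noiseless_ngs_params):
        seg = CnEvent(chrom="5", scope="segment", direction="loss",
                      start_bp=90_000_001, end_bp=95_000_000)
        truth = BiopsyTruth.from_fraction(seg, 1.0, 10)
        sig = render_ngs(truth, flat_weights, genome, noiseless_ngs_params, seed=11)
        events = [e for e in call_ngs(sig, genome).events if e.chrom == "5"]
        assert len(events) == 1
        assert events[0].scope == "segment" and not events[0].mosaic


class TestCallNgs:
    def test_noiseless_oracle_equivalence(self, genome, flat_weights,
                                          noiseless_ngs_params):
        """Recovered CNV equals the analytic mixture copy number to 1e-6."""
        for fraction in (0.3, 0.6):
            truth = BiopsyTruth.from_fraction(tri("4"), fraction, 10)
            sig = render_ngs(truth, flat_weights, genome,
                             noiseless_ngs_params, seed=12)
            events = [e for e in call_ngs(sig, genome).events if e.chrom == "4"]
            assert len(events) == 1
            expected = expected_copy_number(truth, genome, "4")
            # cnv_value is rounded to 2 decimals on the event; check segments
            segs = [s for s in segment_cnv(gc_normalize(sig), genome)
                    if s.chrom == "4"]
            for s in segs:
                assert s.cnv_value == pytest.approx(expected, abs=1e-6)

    def test_noiseless_disomy_euploid(self, genome, flat_weights,
                                      disomic_truth, noiseless_ngs_params):
        sig = render_ngs(disomic_truth, flat_weights, genome,
                         noiseless_ngs_params, seed=13)
        d = call_ngs(sig, genome)
        assert d.events == [] and d.overall_class == "euploid"

    def test_full_trisomy_aneuploid_gain(self, genome, flat_weights,
                                         noiseless_ngs_params):
        truth = BiopsyTruth.from_fraction(tri(), 1.0, 10)
        sig = render_ngs(truth, flat_weights, genome, noiseless_ngs_params, seed=14)
        d = call_ngs(sig, genome)
        assert d.overall_class == "aneuploid"
        (e,) = d.events
        assert e.chrom == "21" and e.scope == "whole" and e.direction == "gain"
        assert e.cnv_value == pytest.approx(3.0, abs=0.01)

    def test_detection_window_noiseless_limits(self, genome, flat_weights,
                                               noiseless_ngs_params):
        """Fraction 0.1 -> CNV 2.1 euploid; 0.9 -> CNV 2.9 aneuploid."""
        low = BiopsyTruth.from_fraction(tri("4"), 0.1, 10)
        sig = render_ngs(low, flat_weights, genome, noiseless_ngs_params, seed=15)
        assert call_ngs(sig, genome).events == []
        high = BiopsyTruth.from_fraction(tri("4"), 0.9, 10)
        sig = render_ngs(high, flat_weights, genome, noiseless_ngs_params, seed=16)
        (e,) = call_ngs(sig, genome).events
        assert not e.mosaic and e.direction == "gain"

    def test_complementary_mixture_called_twenty_percent_mosaic(
            self, genome, flat_weights, noiseless_ngs_params):
        """40% monosomy + 60% trisomy reads as a 20% mosaic gain."""
        mix = BiopsyTruth(((CellKaryotype.with_event(mono("4"), 1), 0.4),
                           (CellKaryotype.with_event(tri("4"), 3), 0.6)), 10)
        sig = render_ngs(mix, flat_weights, genome, noiseless_ngs_params, seed=17)
        (e,) = call_ngs(sig, genome).events
        assert e.mosaic and e.direction == "gain" and e.level_percent == 20

    def test_confusable_mixtures_identical_calls_at_matched_seeds(
            self, genome_xx):
        mix1 = BiopsyTruth(((CellKaryotype.with_event(mono("4"), 1), 0.4),
                            (CellKaryotype.with_event(tri("4"), 3), 0.6)), 10)
        mix2 = BiopsyTruth(((CellKaryotype.disomic(), 0.8),
                            (CellKaryotype.with_event(tri("4"), 3), 0.2)), 10)
        for seed in (1, 2, 3):
            _, a = simulate_embryo(mix1, genome_xx, seed=seed)
            _, b = simulate_embryo(mix2, genome_xx, seed=seed)
            ka = [(e.chrom, e.scope, e.mosaic, e.direction, e.level_percent)
                  for e in call_ngs(a, genome_xx).events]
            kb = [(e.chrom, e.scope, e.mosaic, e.direction, e.level_percent)
                  for e in call_ngs(b, genome_xx).events]
            assert ka == kb

    def test_mosaic_events_carry_level_and_cnv(self, genome, flat_weights,
                                               noiseless_ngs_params):
        truth = BiopsyTruth.from_fraction(tri("4"), 0.4, 10)
        sig = render_ngs(truth, flat_weights, genome, noiseless_ngs_params, seed=18)
        (e,) = call_ngs(sig, genome).events
        assert e.mosaic and e.level_percent == 40
        assert e.cnv_value == pytest.approx(2.4, abs=0.01)

    def test_qc_failure_flags_unreliable(self, genome, flat_weights,
                                         disomic_truth):
        sig = render_ngs(disomic_truth, flat_weights, genome,
                         NgsParams(map_ratio_mean=70.0, map_ratio_sd=0.0),
                         seed=19)
        assert call_ngs(sig, genome).unreliable
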