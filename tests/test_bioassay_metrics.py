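"""Bioassay outcome formulas: SFI, viability, Oi, G-ratio, calcium, MNCV."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from magnetodose.bioassay_metrics import (
    CalciumTrace,
    FiberRecord,
    FootprintRecord,
    ViabilityRecord,
    calcium_metrics,
    fg_ratio,
    fold_angle,
    g_ratio,
    median_iqr,
    mncv,
    orientation_index,
    sfi,
    viability_percent,
)

positive = st.floats(0.5, 100.0)


def identity_footprint(**overrides):
    base = dict(EPL=40.0, NPL=40.0, ETS=20.0, NTS=20.0, EIT=12.0, NIT=12.0)
    base.update(overrides)
    return FootprintRecord(**base)


class TestSFI:
    def test_identity_scores_baseline(self):
        """Equal limbs score the formula's −8.8 offset."""
        assert sfi(identity_footprint()) == pytest.approx(-8.8)

    def test_hand_computed_example(self):
        rec = FootprintRecord(EPL=2.4, NPL=2.0, ETS=1.0, NTS=2.0, EIT=0.8, NIT=1.5)
        assert sfi(rec) == pytest.approx(-77.42, abs=0.005)

    def test_collapsed_toe_spread_limit(self):
        rec = identity_footprint(ETS=1e-9)
        assert sfi(rec) == pytest.approx(-8.8 - 109.5, abs=1e-6)

    @given(scale=st.floats(0.1, 10.0), epl=positive, ets=positive, eit=positive)
    def test_scale_invariance(self, scale, epl, ets, eit):
        """The score depends only on E/N ratios, not absolute lengths."""
        rec = FootprintRecord(EPL=epl, NPL=40.0, ETS=ets, NTS=20.0, EIT=eit, NIT=12.0)
        scaled = FootprintRecord(**{k: getattr(rec, k) * scale
                                    for k in ("EPL", "NPL", "ETS", "NTS", "EIT", "NIT")})
        assert sfi(scaled) == pytest.approx(sfi(rec), rel=1e-9, abs=1e-9)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            identity_footprint(NTS=0.0)


class TestViability:
    def test_identity_is_100_percent(self):
        rec = ViabilityRecord(A_sample=1.05 + 0.10 - 0.05, A_control=1.05,
                              A_blank=0.05, A_drug=0.10)
        assert viability_percent(rec) == pytest.approx(100.0)

    def test_direct_arithmetic(self):
        rec = ViabilityRecord(A_sample=0.95, A_control=1.05, A_blank=0.05, A_drug=0.10)
        assert viability_percent(rec) == pytest.approx(85.0)

    def test_sample_equal_drug_is_zero(self):
        rec = ViabilityRecord(A_sample=0.10, A_control=1.05, A_blank=0.05, A_drug=0.10)
        assert viability_percent(rec) == pytest.approx(0.0)

    def test_negative_viability_warns_but_reports(self):
        rec = ViabilityRecord(A_sample=0.05, A_control=1.05, A_blank=0.05, A_drug=0.10)
        with pytest.warns(UserWarning):
            assert viability_percent(rec) == pytest.approx(-5.0)

    def test_blank_and_drug_corrections_matter(self):
        """The corrected formula must differ from the naive A_sample/A_control
        ratio — guards against dropping the blank/drug corrections. (The
        corrected form is shift-invariant, the naive one is not.)"""
        rec = ViabilityRecord(0.95, 1.05, 0.05, 0.10)
        naive = 100.0 * rec.A_sample / rec.A_control
        assert viability_percent(rec) != pytest.approx(naive)
        shifted = ViabilityRecord(1.15, 1.25, 0.25, 0.30)
        assert viability_percent(shifted) == pytest.approx(viability_percent(rec))

    def test_control_below_blank_rejected(self):
        with pytest.raises(ValueError):
            ViabilityRecord(A_sample=0.5, A_control=0.04, A_blank=0.05, A_drug=0.1)


class TestOrientationIndex:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, 1.0),
        (math.pi / 2, 0.0),
        (math.pi / 4, math.sqrt(0.5)),
    ])
    def test_reference_angles(self, theta, expected):
        assert orientation_index(theta) == pytest.approx(expected, abs=1e-12)

    @given(theta=st.floats(-10.0, 10.0))
    def test_folding_idempotent_and_bounded(self, theta):
        folded = fold_angle(theta)
        assert 0.0 <= folded <= math.pi / 2 + 1e-12
        assert fold_angle(folded) == pytest.approx(folded, abs=1e-12)
        assert 0.0 <= orientation_index(theta) <= 1.0

    def test_monotone_decreasing_on_quadrant(self):
        thetas = np.linspace(0, math.pi / 2, 100)
        ois = [orientation_index(t) for t in thetas]
        assert all(b < a for a, b in zip(ois, ois[1:]))


class TestGRatio:
    def test_unmyelinated_limit(self):
        assert g_ratio(FiberRecord(1.0, 1.0)) == 1.0

    def test_typical_fiber(self):
        assert g_ratio(FiberRecord(0.7, 1.0)) == pytest.approx(0.70)

    def test_axon_exceeding_fiber_rejected(self):
        with pytest.raises(ValueError):
            FiberRecord(axon_diameter_um=1.2, fiber_diameter_um=1.0)

    def test_zero_axon_rejected(self):
        with pytest.raises(ValueError):
            FiberRecord(axon_diameter_um=0.0, fiber_diameter_um=1.0)


def step_trace(baseline, post, onset=50.0, total=650.0, dt=1.0):
    t = np.arange(0.0, total + dt / 2, dt)
    f = np.where(t < onset, baseline, post)
    return CalciumTrace(tuple(t), tuple(f), stimulation_onset_s=onset)


class TestCalciumMetrics:
    def test_flat_trace(self):
        m = calcium_metrics(step_trace(100.0, 100.0))
        assert m["dF_over_F0_percent"] == pytest.approx(0.0)
        assert m["Fmax_over_F0"] == pytest.approx(1.0)

    def test_step_to_plateau(self):
        """Baseline 100, post-onset 185 → ΔF/F₀ = 85%, F_max/F₀ = 1.85."""
        m = calcium_metrics(step_trace(100.0, 185.0))
        assert m["dF_over_F0_percent"] == pytest.approx(85.0)
        assert m["Fmax_over_F0"] == pytest.approx(1.85)

    def test_suppression_is_negative(self):
        m = calcium_metrics(step_trace(100.0, 90.0))
        assert m["dF_over_F0_percent"] == pytest.approx(-10.0)

    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_under_intensity_rescaling(self, scale):
        base = calcium_metrics(step_trace(100.0, 185.0))
        tr = step_trace(100.0 * scale, 185.0 * scale)
        scaled = calcium_metrics(tr)
        assert scaled["dF_over_F0_percent"] == pytest.approx(
            base["dF_over_F0_percent"], rel=1e-9)
        assert scaled["Fmax_over_F0"] == pytest.approx(base["Fmax_over_F0"], rel=1e-9)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            calcium_metrics(step_trace(0.0, 10.0))

    def test_onset_outside_range_rejected(self):
        with pytest.raises(ValueError):
            CalciumTrace((0.0, 1.0, 2.0), (1.0, 1.0, 1.0), stimulation_onset_s=5.0)


class TestMNCV:
    def test_direct_example(self):
        """30 mm with a 1 ms latency difference → 30 m/s."""
        assert mncv(30.0, 2.0, 1.0) == pytest.approx(30.0)

    def test_roundtrip_through_constructed_latencies(self):
        """A velocity implies (distance, latencies) that reproduce it."""
        v = 34.17
        distance = 30.0
        dt = distance / v
        assert mncv(distance, 1.0 + dt, 1.0) == pytest.approx(v, rel=1e-9)

    def test_equal_latencies_rejected(self):
        with pytest.raises(ValueError):
            mncv(30.0, 1.0, 1.0)


class TestFGRatio:
    def test_equal_amounts(self):
        assert fg_ratio(0.5, 0.5) == 1.0

    def test_printed_style_example(self):
        assert fg_ratio(0.105, 0.283) == pytest.approx(0.371, abs=1e-3)

    def test_zero_numerator(self):
        assert fg_ratio(0.0, 0.3) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fg_ratio(0.1, 0.0)


class TestAggregation:
    def test_median_iqr(self):
        s = median_iqr([1.0, 2.0, 3.0, 4.0, 5.0])
        assert s["median"] == 3.0 and s["q1"] == 2.0 and s["q3"] == 4.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])
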