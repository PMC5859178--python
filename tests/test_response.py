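"""Tests for per-pulse response statistics, binning, and curve fits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from guvpore.errors import (
    InsufficientDataError,
    InvalidFieldError,
    WindowEmptyError,
)
from guvpore.response import (
    AreaDecayFit,
    PulseEvent,
    SplineDecayFit,
    bin_and_average,
    classify_contrast_loss,
    compute_response,
    fit_area_decay,
    fit_sigmoid,
)
from guvpore.segmentation import FrameGeometry


def geom(area: float, ff: float = 1.0) -> FrameGeometry:
    perim = math.sqrt(4.0 * math.pi * area / ff)
    return FrameGeometry(area_um2=area, perimeter_um=perim, centroid_um=(0.0, 0.0),
                         form_factor=ff)


def pulse(pre=(0, 5), frame=5, post=(6, 26), e=200.0, pid=0) -> PulseEvent:
    return PulseEvent(field_strength=e, duration_us=500.0, pulse_frame=frame,
                      pre_window=pre, post_window=post, pulse_id=pid)


class TestComputeResponse:
    def test_constant_area_movie_is_identity(self):
        frames = [geom(1000.0, 0.99)] * 26
        resp = compute_response(frames, pulse())
        assert resp.a_norm == pytest.approx(1.0, abs=1e-12)
        assert resp.ff_final == pytest.approx(0.99, abs=1e-12)

    def test_thirty_percent_shrinkage_arithmetic(self):
        """A_i = 1256.6, A_f = 879.6 um^2 -> A_norm = 0.700."""
        frames = [geom(1256.6)] * 6 + [geom(879.6)] * 20
        resp = compute_response(frames, pulse())
        assert resp.a_norm == pytest.approx(0.700, abs=1e-3)
        assert resp.a_norm == resp.a_f_um2 / resp.a_i_um2

    def test_buckling_keeps_area_but_lowers_ff(self):
        """Area-conserving buckling: A_norm ~ 1 while FF_final < 1, the
        signature of a vesicle losing volume but no lipid."""
        frames = [geom(1000.0, 1.0)] * 6 + [geom(1000.0, 0.90)] * 20
        resp = compute_response(frames, pulse())
        assert resp.a_norm == pytest.approx(1.0, abs=1e-9)
        assert resp.ff_final == pytest.approx(0.90, abs=1e-9)

    def test_final_state_uses_last_quartile(self):
        """Frames early in the post window (still decaying) do not bias A_f."""
        frames = [geom(1000.0)] * 6 + [geom(900.0)] * 15 + [geom(800.0)] * 5
        resp = compute_response(frames, pulse())
        assert resp.a_f_um2 == pytest.approx(800.0)

    def test_gap_frames_skipped(self):
        frames = [geom(1000.0), None, geom(1000.0), None, geom(1000.0)] + [None] * 16 + [geom(700.0)] * 5
        resp = compute_response(frames, pulse())
        assert resp.a_norm == pytest.approx(0.7)

    def test_all_gap_window_raises(self):
        frames = [None] * 5 + [geom(1000.0)] * 21
        with pytest.raises(WindowEmptyError):
            compute_response(frames, pulse())

    def test_window_ordering_validated(self):
        with pytest.raises(ValueError):
            pulse(pre=(0, 8), frame=5)
        with pytest.raises(ValueError):
            PulseEvent(200.0, 500.0, 5, (0, 5), (3, 10))

    def test_negative_field_rejected(self):
        with pytest.raises(InvalidFieldError):
            pulse(e=-10.0)


class TestClassifyContrastLoss:
    def test_constant_contrast_is_none(self):
        trace = np.full(30, 0.5)
        cls, drop = classify_contrast_loss(trace, [pulse()])
        assert cls == "none"
        assert drop == pytest.approx(0.0, abs=1e-12)

    def test_single_window_collapse_is_complete(self):
        trace = np.concatenate([np.full(6, 0.5), np.full(24, 0.02)])
        cls, drop = classify_contrast_loss(trace, [pulse()])
        assert cls == "complete"
        assert drop > 0.9

    def test_even_decline_is_gradual(self):
        """0.5 -> 0.3 spread evenly over ten pulses: a 40% cumulative drop
        with no single-window collapse."""
        n_pulses, block = 10, 26
        trace = np.linspace(0.5, 0.3, n_pulses * block)
        pulses = [
            pulse(pre=(k * block, k * block + 5), frame=k * block + 5,
                  post=(k * block + 6, (k + 1) * block), pid=k)
            for k in range(n_pulses)
        ]
        cls, drop = classify_contrast_loss(trace, pulses)
        assert cls == "gradual"
        assert drop == pytest.approx(0.4, abs=0.02)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            classify_contrast_loss([0.5], [pulse()])

    def test_nan_gaps_tolerated(self):
        trace = np.full(30, 0.5)
        trace[[3, 11, 19]] = np.nan
        cls, _ = classify_contrast_loss(trace, [pulse()])
        assert cls == "none"


class TestBinAndAverage:
    def test_single_bin_mean(self):
        bins = bin_and_average([10.0, 20.0, 25.0], [1.0, 0.9, 0.8], 30.0)
        assert len(bins) == 1
        assert (bins[0].bin_lower, bins[0].bin_upper) == (0.0, 30.0)
        assert bins[0].n == 3
        assert bins[0].mean == pytest.approx(0.9)

    def test_singleton_bin_sd_zero(self):
        bins = bin_and_average([45.0], [0.95], 30.0)
        assert bins[0].sd == 0.0 and bins[0].n == 1

    def test_sample_sd(self):
        bins = bin_and_average([10.0, 12.0], [0.9, 1.1], 30.0)
        assert bins[0].sd == pytest.approx(math.sqrt(0.02), rel=1e-9)  # ~0.1414

    def test_empty_bins_omitted(self):
        bins = bin_and_average([10.0, 100.0], [1.0, 0.8], 30.0)
        assert [b.bin_lower for b in bins] == [0.0, 90.0]

    def test_negative_field_rejected(self):
        with pytest.raises(InvalidFieldError):
            bin_and_average([-5.0], [1.0])

    @given(
        st.lists(
            st.tuples(st.floats(0.0, 500.0), st.floats(0.5, 1.2)),
            min_size=1, max_size=30,
        ),
        st.lists(
            st.tuples(st.floats(0.0, 500.0), st.floats(0.5, 1.2)),
            min_size=1, max_size=30,
        ),
    )
    def test_binning_is_associative_over_pooling(self, set_a, set_b):
        """Binning the concatenation equals pooling the per-set bin contents."""
        ea, ya = zip(*set_a)
        eb, yb = zip(*set_b)
        merged = bin_and_average(list(ea) + list(eb), list(ya) + list(yb))
        for b in merged:
            sel = [y for e, y in set_a + set_b if b.bin_lower <= e < b.bin_upper]
            assert b.n == len(sel)
            assert b.mean == pytest.approx(np.mean(sel), rel=1e-9, abs=1e-9)


class TestFitSigmoid:
    E = np.linspace(0.0, 400.0, 25)

    def logistic(self, e, u=1.0, l=0.7, e50=200.0, w=40.0):
        return u - (u - l) / (1.0 + np.exp(-(np.asarray(e) - e50) / w))

    def test_noiseless_recovery_exact(self):
        fit = fit_sigmoid(self.E, self.logistic(self.E))
        assert fit.upper == pytest.approx(1.0, rel=1e-6)
        assert fit.lower == pytest.approx(0.7, rel=1e-6)
        assert fit.e50 == pytest.approx(200.0, rel=1e-6)
        assert fit.width == pytest.approx(40.0, rel=1e-6)
        assert fit.residual_ss < 1e-12

    def test_constant_data_degenerates_gracefully(self):
        fit = fit_sigmoid(self.E, np.ones_like(self.E))
        assert fit.upper == pytest.approx(1.0)
        assert fit.lower == pytest.approx(1.0)
        assert fit.width > 0

    def test_unit_rescaling_equivariance(self):
        """Relabelling E in different units rescales e50 and width alike."""
        y = self.logistic(self.E)
        fit_vmm = fit_sigmoid(self.E, y)
        fit_vcm = fit_sigmoid(self.E * 10.0, y)  # e.g. V/cm axis
        assert fit_vcm.e50 == pytest.approx(10.0 * fit_vmm.e50, rel=1e-6)
        assert fit_vcm.width == pytest.approx(10.0 * fit_vmm.width, rel=1e-6)
        assert fit_vcm.upper == pytest.approx(fit_vmm.upper, rel=1e-9)

    def test_prediction_roundtrip(self):
        fit = fit_sigmoid(self.E, self.logistic(self.E))
        assert np.allclose(fit.predict(self.E), self.logistic(self.E), atol=1e-8)

    def test_needs_four_distinct_fields(self):
        with pytest.raises(ValueError):
            fit_sigmoid([0.0, 100.0, 100.0, 200.0], [1.0, 0.9, 0.9, 0.8])

    def test_noisy_replicates_recover_midpoint(self):
        """Median |E50 error| over seeded noisy replicates stays below 10 V/mm
        (a third of a bin) at sigma = 0.03."""
        rng = np.random.default_rng(123)
        y = self.logistic(self.E)
        errors = [
            abs(fit_sigmoid(self.E, y + rng.normal(0.0, 0.03, self.E.size)).e50 - 200.0)
            for _ in range(40)
        ]
        assert np.median(errors) < 10.0


class TestFitAreaDecay:
    T = np.linspace(0.0, 10.0, 40)

    def test_noiseless_exponential_recovery(self):
        a = 900.0 + 300.0 * np.exp(-self.T / 2.5)
        fit = fit_area_decay(self.T, a)
        assert isinstance(fit, AreaDecayFit)
        assert fit.a_inf == pytest.approx(900.0, rel=1e-8)
        assert fit.delta_a == pytest.approx(300.0, rel=1e-8)
        assert fit.tau == pytest.approx(2.5, rel=1e-8)
        assert not fit.tau_at_bound

    def test_constant_area_gives_zero_amplitude(self):
        fit = fit_area_decay(self.T, np.full_like(self.T, 1000.0))
        assert fit.delta_a == 0.0
        assert np.all(fit.derivative(self.T) == 0.0)

    def test_derivative_identity_at_start(self):
        a = 900.0 + 300.0 * np.exp(-self.T / 2.5)
        fit = fit_area_decay(self.T, a)
        assert fit.derivative(fit.t0) == pytest.approx(-fit.delta_a / fit.tau, rel=1e-12)

    def test_time_offset_invariance(self):
        """Shifting the clock changes nothing but the stored origin."""
        a = 900.0 + 300.0 * np.exp(-self.T / 2.5)
        fit = fit_area_decay(self.T + 100.0, a)
        assert fit.tau == pytest.approx(2.5, rel=1e-6)
        assert fit.derivative(100.0) == pytest.approx(-300.0 / 2.5, rel=1e-6)

    def test_spline_alternative_matches_derivative(self):
        a = 900.0 + 300.0 * np.exp(-self.T / 2.5)
        fit = fit_area_decay(self.T, a, method="spline")
        assert isinstance(fit, SplineDecayFit)
        # compare derivatives mid-series where the spline is well conditioned
        assert fit.derivative(5.0) == pytest.approx(-300.0 / 2.5 * math.exp(-2.0), rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_area_decay([0.0, 1.0, 2.0], [3.0, 2.0, 1.0])

    def test_gaps_dropped(self):
        a = 900.0 + 300.0 * np.exp(-self.T / 2.5)
        a[5] = np.nan
        fit = fit_area_decay(self.T, a)
        assert fit.tau == pytest.approx(2.5, rel=1e-6)
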