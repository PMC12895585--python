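"""Preprocessing chain: OD, Beer-Lambert, filtering, motion correction,
hemodynamic separation, ROI aggregation."""

import numpy as np
import pytest

from fnirsfc.montage import build_standard_montage
from fnirsfc.preprocess import (
    HemoTimeSeries,
    PreprocessParams,
    RoiTimeSeries,
    aggregate_rois,
    bandpass,
    forward_mbll,
    hemodynamic_separation,
    intensity_to_od,
    load_default_extinction,
    mbll,
    wavelet_motion_correct,
)

DPF = {695: 6.0, 830: 6.0}
EXT = load_default_extinction()


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        od = intensity_to_od(np.full((3, 100), 7.5))
        assert np.allclose(od, 0.0)

    def test_global_rescaling_leaves_od_changes_invariant(self, rng):
        i = rng.uniform(0.5, 1.5, size=(2, 200))
        od1 = intensity_to_od(i)
        od2 = intensity_to_od(0.5 * i)
        assert np.allclose(od1 - od1.mean(-1, keepdims=True),
                           od2 - od2.mean(-1, keepdims=True), atol=1e-12)

    def test_tenfold_attenuation_gives_unit_od(self):
        i = np.ones((1, 100))
        i[0, 50] = 0.1
        od = intensity_to_od(i)
        # relative to the mean, but the spot value dominates: OD at the
        # dip is -log10(0.1/mean) = 1 - log10(1/mean)
        expected = -np.log10(0.1 / i.mean())
        assert od[0, 50] == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_intensity_names_channel_and_sample(self):
        i = np.ones((2, 10))
        i[1, 3] = 0.0
        with pytest.raises(ValueError, match="channel row 1, sample 3"):
            intensity_to_od(i)


class TestMbll:
    def test_zero_od_gives_zero_concentrations(self):
        od = {695: np.zeros((2, 50)), 830: np.zeros((2, 50))}
        dHbO, dHbR = mbll(od, DPF, EXT, 3.0)
        assert np.allclose(dHbO, 0) and np.allclose(dHbR, 0)

    def test_forward_inverse_round_trip(self, rng):
        dHbO = rng.normal(0, 1e-3, size=(4, 300))
        dHbR = rng.normal(0, 5e-4, size=(4, 300))
        od = forward_mbll(dHbO, dHbR, DPF, EXT, 3.0)
        rHbO, rHbR = mbll(od, DPF, EXT, 3.0)
        assert np.allclose(rHbO, dHbO, atol=1e-15)
        assert np.allclose(rHbR, dHbR, atol=1e-15)

    def test_doubling_dpf_halves_concentrations(self, rng):
        dHbO = rng.normal(0, 1e-3, size=(1, 100))
        dHbR = rng.normal(0, 1e-3, size=(1, 100))
        od = forward_mbll(dHbO, dHbR, DPF, EXT, 3.0)
        double = {lam: 2 * v for lam, v in DPF.items()}
        hHbO, hHbR = mbll(od, double, EXT, 3.0)
        assert np.allclose(hHbO, dHbO / 2)
        assert np.allclose(hHbR, dHbR / 2)

    def test_singular_extinction_is_config_error(self):
        bad = {695: {"HbO": 1.0, "HbR": 2.0}, 830: {"HbO": 1.0, "HbR": 2.0}}
        with pytest.raises(ValueError, match="singular"):
            mbll({695: np.zeros((1, 5)), 830: np.zeros((1, 5))}, DPF, bad, 3.0)


class TestBandpass:
    def _amplitude(self, y, f_hz, t):
        mid = slice(200, len(t) - 200)
        return 2 * np.mean(y[mid] * np.cos(2 * np.pi * f_hz * t[mid]))

    def test_cardiac_frequency_attenuated_20db(self):
        t = np.arange(3000) / 10.0
        y = bandpass(np.cos(2 * np.pi * 1.0 * t), 10.0)
        rms = np.sqrt(2) * y[200:-200].std()
        assert 20 * np.log10(rms) < -20.0

    def test_in_band_sinusoid_preserved_within_5pct(self):
        t = np.arange(3000) / 10.0
        y = bandpass(np.cos(2 * np.pi * 0.05 * t), 10.0)
        assert self._amplitude(y, 0.05, t) == pytest.approx(1.0, abs=0.05)

    def test_dc_removed(self):
        y = bandpass(np.full(2000, 5.0), 10.0)
        assert np.abs(y[200:-200]).max() < 1e-6

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(100), 10.0, low_hz=0.01, high_hz=6.0)


class TestWaveletMotionCorrection:
    def test_clean_low_frequency_signal_nearly_unchanged(self):
        t = np.arange(1500) / 10.0
        clean = np.sin(2 * np.pi * 0.05 * t) + 0.5 * np.sin(2 * np.pi * 0.11 * t)
        out = wavelet_motion_correct(clean)[0]
        assert np.corrcoef(clean, out)[0, 1] >= 0.99

    def test_spike_suppressed_by_half_or_more(self):
        t = np.arange(1500) / 10.0
        clean = np.sin(2 * np.pi * 0.05 * t)
        spiky = clean.copy()
        spiky[700] += 8 * clean.std()
        out = wavelet_motion_correct(spiky)[0]
        dev_before = np.abs(spiky - clean).max()
        dev_after = np.abs(out - clean).max()
        assert dev_after <= 0.5 * dev_before

    def test_zero_signal_maps_to_zero(self):
        out = wavelet_motion_correct(np.zeros((3, 512)))
        assert np.allclose(out, 0.0)

    def test_too_short_signal_is_an_error(self):
        with pytest.raises(ValueError, match="shorter"):
            wavelet_motion_correct(np.zeros(5))


class TestHemodynamicSeparation:
    def _hemo(self, dHbO, dHbR):
        return HemoTimeSeries(np.atleast_2d(dHbO), np.atleast_2d(dHbR),
                              [1], 10.0)

    def test_pure_functional_input_is_a_fixed_point(self, rng):
        f = rng.normal(size=(1, 200))
        out = hemodynamic_separation(self._hemo(f, -0.6 * f), k=-0.6)
        assert np.allclose(out.dHbO, f, atol=1e-12)
        assert np.allclose(out.dHbR, -0.6 * f, atol=1e-12)

    def test_pure_systemic_input_vanishes(self, rng):
        s = rng.normal(size=(1, 200))
        out = hemodynamic_separation(self._hemo(s, s), k=-0.6, systemic_ratio=1.0)
        assert np.allclose(out.dHbO, 0.0, atol=1e-12)

    def test_linearity(self, rng):
        o = rng.normal(size=(1, 100))
        r = rng.normal(size=(1, 100))
        one = hemodynamic_separation(self._hemo(o, r))
        scaled = hemodynamic_separation(self._hemo(3 * o, 3 * r))
        assert np.allclose(scaled.dHbO, 3 * one.dHbO, atol=1e-12)

    def test_nonnegative_k_is_config_error(self, rng):
        h = self._hemo(rng.normal(size=(1, 10)), rng.normal(size=(1, 10)))
        with pytest.raises(ValueError, match="negative"):
            hemodynamic_separation(h, k=0.5)


class TestRoiAggregation:
    def test_single_channel_roi_equals_that_channel(self, rng):
        m = build_standard_montage()
        one_per_roi = []
        seen = set()
        for ch in m.channels:
            roi = m.roi_map[ch.id]
            if roi not in seen:
                seen.add(roi)
                one_per_roi.append(ch.id)
        sub = m.restrict(one_per_roi)
        data = rng.normal(size=(6, 100))
        hemo = HemoTimeSeries(data, data, sub.channel_ids, 10.0)
        roi_ts = aggregate_rois(hemo, sub)
        for r, roi in enumerate(roi_ts.roi_order):
            i = sub.channel_ids.index(sub.roi_channels(roi)[0])
            assert np.allclose(roi_ts.traces[r], data[i])

    def test_duplicated_channel_doubles_trace_but_not_correlations(self, rng):
        from fnirsfc.connectivity import static_fc

        m = build_standard_montage()
        data = rng.normal(size=(52, 400))
        hemo = HemoTimeSeries(data, data, m.channel_ids, 10.0)
        base = aggregate_rois(hemo, m)
        doubled = RoiTimeSeries(base.traces * np.array([2, 1, 1, 1, 1, 1])[:, None],
                                base.roi_order, 10.0)
        assert np.allclose(static_fc(base).z, static_fc(doubled).z, atol=1e-12)

    def test_46_channels_aggregate_to_6x1500(self, retained_montage, rng):
        data = rng.normal(size=(46, 1500))
        hemo = HemoTimeSeries(data, data, retained_montage.channel_ids, 10.0)
        roi_ts = aggregate_rois(hemo, retained_montage)
        assert roi_ts.traces.shape == (6, 1500)

    def test_mean_mode_divides_by_channel_count(self, retained_montage, rng):
        data = rng.normal(size=(46, 100))
        hemo = HemoTimeSeries(data, data, retained_montage.channel_ids, 10.0)
        s = aggregate_rois(hemo, retained_montage, mode="sum")
        m = aggregate_rois(hemo, retained_montage, mode="mean")
        counts = np.array(
            [len(retained_montage.roi_channels(r)) for r in retained_montage.roi_order]
        )
        assert np.allclose(s.traces, m.traces * counts[:, None])


def test_pipeline_scaling_invariance_of_correlations(latent_cohort, retained_montage):
    """Scaling the raw concentrations by c scales ROI traces by c and
    leaves all downstream correlations unchanged (up to the wavelet
    nonlinearity, which is scale-equivariant for exact scalings)."""
    from fnirsfc.connectivity import static_fc

    ts = latent_cohort[0]
    scaled = RoiTimeSeries(3.7 * ts.traces, ts.roi_order, ts.sampling_rate)
    assert np.allclose(static_fc(ts).z, static_fc(scaled).z, atol=1e-10)
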