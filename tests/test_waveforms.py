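"""Waveform categorization: preprocessing, extrema, BPI, categories, units."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polarspike import waveforms as wf
from polarspike.synth.templates import _lobes_b, _lobes_n, eval_lobes

from conftest import gaussian_wave, mean_waveform, upsampled


class TestSummarize:
    def test_noiseless_copies_mean_is_template_sd_zero(self):
        tpl = gaussian_wave(-80.0)
        m = wf.summarize_waveforms(np.tile(tpl, (1000, 1)))
        np.testing.assert_allclose(m.mean, tpl)
        np.testing.assert_allclose(m.sd, 0.0, atol=1e-9)
        assert m.n_spikes == 1000

    def test_noise_sd_recovered(self):
        rng = np.random.default_rng(0)
        snips = gaussian_wave(-80.0) + rng.normal(0, 10.0, size=(1000, 32))
        m = wf.summarize_waveforms(snips)
        assert np.all(np.abs(m.sd - 10.0) < 1.0)  # within 10%

    def test_single_spike(self):
        tpl = gaussian_wave(50.0)
        m = wf.summarize_waveforms(tpl[None, :])
        np.testing.assert_allclose(m.mean, tpl)
        np.testing.assert_allclose(m.sd, 0.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            wf.summarize_waveforms(np.empty((0, 32)))


class TestPreprocess:
    def test_constant_waveform_maps_to_zero(self):
        u = upsampled(np.full(32, 37.0))
        np.testing.assert_allclose(u.mean128, 0.0, atol=1e-12)
        assert u.mean128.size == 128
        assert u.fs == 80000.0

    def test_baseline_offset_removed(self):
        u0 = upsampled(gaussian_wave(-100.0))
        u1 = upsampled(gaussian_wave(-100.0) + 20.0)
        np.testing.assert_allclose(u0.mean128, u1.mean128, atol=1e-9)

    def test_sinusoid_extrema_within_1pct(self):
        # one full 1 kHz cycle (20 samples at 20 kHz) embedded after a
        # flat start so the baseline window stays neutral
        x = np.zeros(32)
        k = np.arange(20)
        x[3:23] = 60.0 * np.sin(2 * np.pi * k / 20)
        u = upsampled(x)
        assert abs(u.mean128.max() - 60.0) < 0.6
        assert abs(u.mean128.min() + 60.0) < 0.6

    def test_sd_never_negative_after_spline(self):
        sd = np.zeros(32)
        sd[10] = 5.0  # spiky SD invites spline undershoot
        u = wf.preprocess_waveform(mean_waveform(gaussian_wave(-50.0), sd=sd))
        assert np.all(u.sd128 >= 0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            wf.preprocess_waveform(mean_waveform(np.array([1.0, 2.0])))


class TestExtrema:
    def test_negative_lobe(self):
        e = wf.find_extrema(upsampled(gaussian_wave(-100.0)))
        assert e.n < -99.0
        assert 0 <= e.p < 1.0
        assert abs(e.t_n - 15 * 4) <= 1

    def test_analytic_biphasic_indices(self):
        t = np.arange(32) / 20000.0
        lobes = _lobes_b(100.0, 1e-4, 15 / 20000.0, 0.8)
        u = upsampled(eval_lobes(lobes, t))
        e = wf.find_extrema(u)
        dense = np.arange(0, 32 / 20000.0, 1e-7)
        v = eval_lobes(lobes, dense)
        # within one upsampled sample (12.5 us)
        assert abs(e.t_n / 80000.0 - dense[np.argmin(v)]) <= 12.6e-6
        assert abs(e.t_p / 80000.0 - dense[np.argmax(v)]) <= 12.6e-6

    def test_monotone_ramp_uses_endpoints(self):
        e = wf.find_extrema(upsampled(np.linspace(0, 31, 32)))
        assert e.t_n < e.t_p
        assert e.t_p == 127

    def test_constant_raises(self):
        u = wf.UpsampledWaveform(mean128=np.zeros(128), sd128=np.zeros(128))
        with pytest.raises(wf.NoExtremaError):
            wf.find_extrema(u)


class TestBPI:
    @pytest.mark.parametrize(
        "p,n,expected",
        [(0.0, -100.0, -1.0), (100.0, 0.0, 1.0), (60.0, -60.0, 0.0), (3.0, -1.0, 0.5)],
    )
    def test_anchor_values(self, p, n, expected):
        e = wf.ExtremaResult(p=p, t_p=10, n=n, t_n=90)
        assert wf.compute_bpi(e) == pytest.approx(expected)

    def test_undefined_raises(self):
        with pytest.raises(wf.UndefinedBPIError):
            wf.compute_bpi(wf.ExtremaResult(p=0.0, t_p=0, n=0.0, t_n=0))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-200, 200, allow_nan=False), min_size=32, max_size=32))
    def test_bounds_for_any_waveform(self, vals):
        v = np.asarray(vals)
        if np.ptp(v) == 0:
            return
        u = upsampled(v)
        try:
            bpi = wf.compute_bpi(wf.find_extrema(u))
        except (wf.NoExtremaError, wf.UndefinedBPIError):
            return
        assert -1.0 <= bpi <= 1.0


def _biphasic(p_amp, n_amp, peak_first=True, sd=1.0):
    """Peak and trough Gaussian lobes with controllable order, sd in uV."""
    t = np.arange(32)
    pk, tr = (10, 21) if peak_first else (21, 10)
    m = p_amp * np.exp(-0.5 * ((t - pk) / 1.8) ** 2) - n_amp * np.exp(-0.5 * ((t - tr) / 1.8) ** 2)
    return upsampled(m, sd=sd)


class TestCategorize:
    def test_b_spike_just_above_thresholds(self):
        # peak 1.3 SD before trough 1.1 SD, symmetric amplitudes -> BPI ~ 0
        cat = wf.categorize_waveform(_biphasic(1.3, 1.1, sd=1.0))
        assert cat.label == wf.B
        assert -0.6 < cat.bpi < 0.8

    def test_low_bpi_biphasic_is_n(self):
        # trough dominates: BPI < -0.6 excludes B; trough clears 1.75 SD -> N
        cat = wf.categorize_waveform(_biphasic(2.0, 12.0, sd=1.0))
        assert cat.bpi < -0.6
        assert cat.label == wf.N

    def test_p_needs_1_75_sd(self):
        # peak only 1.5 SD (trough-then-peak so B cannot fire)
        cat = wf.categorize_waveform(_biphasic(1.5, 0.0, peak_first=False, sd=1.0))
        assert cat.label == wf.UNCATEGORIZED
        cat2 = wf.categorize_waveform(_biphasic(1.8, 0.0, peak_first=False, sd=1.0))
        assert cat2.label == wf.P

    def test_all_zero_uncategorized(self):
        u = wf.UpsampledWaveform(mean128=np.zeros(128), sd128=np.ones(128))
        assert wf.categorize_waveform(u).label == wf.UNCATEGORIZED

    def test_alternate_preset_stricter_pn(self):
        th = wf.CategoryThresholds.preset("alternate")
        cat = wf.categorize_waveform(_biphasic(1.9, 0.0, peak_first=False, sd=1.0), th)
        assert cat.label == wf.UNCATEGORIZED  # needs 2 SD under alternate

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.1, 1000.0))
    def test_scale_invariance(self, scale):
        base = _biphasic(1.3, 1.1, sd=1.0)
        scaled = wf.UpsampledWaveform(mean128=base.mean128 * scale, sd128=base.sd128 * scale)
        c0, c1 = wf.categorize_waveform(base), wf.categorize_waveform(scaled)
        assert c0.label == c1.label
        assert c0.bpi == pytest.approx(c1.bpi, abs=1e-9)


def _make_unit(chan_waves: dict, shank=0) -> wf.Unit:
    return wf.Unit(
        unit_id=0,
        shank=shank,
        spike_times=np.array([0.0]),
        waveforms={ch: mean_waveform(m, channel=ch) for ch, m in chan_waves.items()},
    )


class TestClassifyUnit:
    def test_single_n_channel_is_sm_nunit(self):
        u = wf.classify_unit(_make_unit({0: gaussian_wave(-100.0)}))
        assert (u.modality, u.unit_type, u.main_channel) == (wf.SM, wf.NUNIT, 0)

    def test_n_plus_p_channel_is_mm_nunit(self):
        u = wf.classify_unit(
            _make_unit({0: gaussian_wave(-100.0), 1: gaussian_wave(60.0)})
        )
        assert u.modality == wf.MM
        assert u.unit_type == wf.NUNIT  # N on the larger-magnitude channel
        assert u.main_channel == 0

    def test_magnitude_tie_breaks_to_lowest_channel(self):
        w = gaussian_wave(-100.0)
        u = wf.classify_unit(_make_unit({3: w.copy(), 1: w.copy()}))
        assert u.main_channel == 1

    def test_no_categorized_channels_unclassified(self):
        u = wf.classify_unit(_make_unit({0: np.zeros(32)}))
        assert u.unit_type == wf.UNCLASSIFIED


class TestCellType:
    def test_two_separated_clusters_fully_recovered(self):
        rng = np.random.default_rng(1)
        units = []
        truth = {}
        for i in range(40):
            narrow = i < 20
            sigma = 1.0 if narrow else 2.4  # samples at 20 kHz
            u = _make_unit({0: gaussian_wave(-100.0, sigma=sigma)})
            u.unit_id = i
            wf.classify_unit(u)
            units.append(u)
            truth[i] = wf.INT if narrow else wf.PYR
        labels, post = wf.classify_celltype(units, random_state=0)
        assert all(labels[i] == truth[i] for i in truth)
        assert all(u.unit_type in (wf.PYR, wf.INT) for u in units)

    def test_punits_left_untouched(self):
        p_unit = _make_unit({0: gaussian_wave(80.0)})
        p_unit.unit_id = 99
        wf.classify_unit(p_unit)
        assert p_unit.unit_type == wf.PUNIT
        wf.classify_celltype([p_unit])
        assert p_unit.unit_type == wf.PUNIT

    def test_fewer_than_two_units_unchanged(self):
        u = wf.classify_unit(_make_unit({0: gaussian_wave(-100.0)}))
        labels, _ = wf.classify_celltype([u])
        assert labels == {}
        assert u.unit_type == wf.NUNIT


class TestSpikeWidth:
    def test_full_cycle_1khz_sinusoid_width_1ms(self):
        t = np.arange(32) / 20000.0
        x = np.sin(2 * np.pi * 1000.0 * t)
        x[:3] = 0  # keep the baseline window neutral
        w = wf.spike_width(upsampled(50.0 * np.sin(2 * np.pi * 1000.0 * t)))
        assert w == pytest.approx(1.0, abs=0.02)

    def test_matches_dense_dft_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            sigma = rng.uniform(1.0, 2.2)
            ratio = rng.uniform(0.5, 1.0)
            u = upsampled(
                gaussian_wave(ratio * 100, center=10, sigma=sigma)
                - gaussian_wave(100, center=10 + 3 * sigma, sigma=sigma)
            )
            width = wf.spike_width(u)
            # independent oracle: dense explicit DFT over the search band
            freqs = np.arange(100.0, 3000.0, 1.0)
            t = np.arange(128) / 80000.0
            mags = np.abs(np.exp(-2j * np.pi * np.outer(freqs, t)) @ u.mean128)
            oracle = 1e3 / freqs[np.argmax(mags)]
            assert width == pytest.approx(oracle, rel=0.01)

    def test_narrow_b_narrower_than_wide_n(self):
        t = np.arange(32) / 20000.0
        b = upsampled(eval_lobes(_lobes_b(100, 0.8e-4, 15 / 20000.0, 0.8), t))
        n = upsampled(eval_lobes(_lobes_n(100, 1.5e-4, 15 / 20000.0), t))
        assert wf.spike_width(b) < wf.spike_width(n)

    def test_zero_waveform_undefined(self):
        with pytest.raises(ValueError):
            wf.spike_width(wf.UpsampledWaveform(np.zeros(128), np.zeros(128)))


class TestSpatialSpan:
    def _unit_with_labels(self, labels: dict, probe):
        u = _make_unit({ch: gaussian_wave(-50.0) for ch in labels})
        u.categories = {ch: wf.WaveformCategory(lab, 0.0) for ch, lab in labels.items()}
        return u

    def test_single_channel_counts_one_spacing(self, probe8):
        u = self._unit_with_labels({3: wf.N}, probe8)
        assert wf.spatial_span(u, probe8) == 20.0

    def test_six_contiguous_at_15um(self):
        from polarspike import make_probe

        probe = make_probe(1, 8, 15.0)
        u = self._unit_with_labels({i: wf.N for i in range(1, 7)}, probe)
        assert wf.spatial_span(u, probe) == 90.0

    def test_gap_takes_longest_run(self, probe8):
        u = self._unit_with_labels(
            {0: wf.N, 1: wf.N, 2: wf.N, 4: wf.P, 5: wf.P}, probe8
        )
        assert wf.spatial_span(u, probe8) == 3 * 20.0
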