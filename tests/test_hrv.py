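"""HRV metrics: cleaning, closed-form values, spectra, z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvnet import hrv, simulate


def series_of(intervals):
    return hrv.RRISeries.from_intervals(np.asarray(intervals, dtype=float))


class TestCleanRR:
    def test_clean_series_unchanged(self):
        s = series_of([800.0] * 50)
        out = hrv.clean_rr(s)
        assert out.n_replaced == 0
        np.testing.assert_array_equal(out.intervals, s.intervals)

    def test_doubled_interval_replaced_by_neighbours(self):
        intervals = [800.0] * 20
        intervals[10] = 1600.0
        out = hrv.clean_rr(series_of(intervals))
        assert out.n_replaced == 1
        assert out.cleaned_flags[10]
        assert out.intervals[10] == pytest.approx(800.0)

    def test_minimum_length_constant_series(self):
        out = hrv.clean_rr(series_of([800.0, 800.0, 800.0]))
        assert out.n_replaced == 0

    def test_heavy_contamination_sets_quality_flag(self):
        base = np.full(40, 800.0)
        base[::3] = 1600.0  # isolated spikes, ~1/3 of intervals
        with pytest.warns(UserWarning, match="ectopic"):
            out = hrv.clean_rr(series_of(base))
        assert not out.quality_ok

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hrv.clean_rr(series_of([800.0, 800.0]))


class TestTimeDomain:
    @pytest.mark.parametrize(
        "intervals, vc, rmssd",
        [
            ([800.0, 800.0, 800.0], 0.0, 0.0),
            ([800.0, 820.0], 0.0174594267, 20.0),
            ([750.0, 800.0, 850.0], 0.0625, 50.0),
        ],
    )
    def test_hand_computed_values(self, intervals, vc, rmssd):
        got_vc, got_rmssd = hrv.time_domain(series_of(intervals))
        assert got_vc == pytest.approx(vc, abs=1e-8)
        assert got_rmssd == pytest.approx(rmssd, abs=1e-8)

    def test_single_interval_rejected(self):
        with pytest.raises(ValueError):
            hrv.time_domain(series_of([800.0]))

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=0.5, max_value=2.0))
    def test_scale_equivariance(self, scale):
        base = np.array([750.0, 790.0, 820.0, 805.0, 760.0, 810.0])
        vc0, rmssd0 = hrv.time_domain(series_of(base))
        vc1, rmssd1 = hrv.time_domain(series_of(base * scale))
        assert vc1 == pytest.approx(vc0, rel=1e-9)
        assert rmssd1 == pytest.approx(rmssd0 * scale, rel=1e-9)


class TestSpectrum:
    def test_constant_series_has_no_power(self):
        s = series_of([800.0] * 100)
        spec = hrv.rr_psd(s)
        assert hrv.band_power(spec, (0.01, 0.49)) < 1e-12

    def test_sinusoid_total_power_matches_parseval(self):
        gen = simulate.RRGenSpec(lf_amp=40.0, duration=300.0, seed=0)
        spec = hrv.rr_psd(simulate.gen_rr_series(gen))
        total = spec.density.sum() * spec.df
        assert total == pytest.approx(40.0**2 / 2, rel=0.05)

    def test_frequency_resolution_bounded_by_duration(self):
        s = simulate.gen_rr_series(simulate.RRGenSpec(noise_sd=10.0, duration=300.0))
        spec = hrv.rr_psd(s)
        assert spec.df <= 1.0 / 290.0  # duration in beats spans ~the recording

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            hrv.rr_psd(series_of([800.0] * 10))


class TestBandPower:
    def test_flat_density_rectangle(self):
        freqs = np.arange(0, 0.5, 1.0 / 300.0)
        spec = hrv.Spectrum(freqs=freqs, density=np.ones_like(freqs))
        assert hrv.band_power(spec, (0.04, 0.14)) == pytest.approx(0.10, abs=1e-12)

    def test_two_sinusoid_lf_hf_ratio(self):
        gen = simulate.RRGenSpec(lf_amp=40.0, hf_amp=20.0, duration=300.0, seed=0)
        spec = hrv.rr_psd(simulate.gen_rr_series(gen))
        ratio = hrv.band_power(spec, hrv.LF_BAND) / hrv.band_power(spec, hrv.HF_BAND)
        assert ratio == pytest.approx(4.0, rel=0.10)

    @settings(max_examples=25, derandomize=True)
    @given(split=st.floats(min_value=0.06, max_value=0.12))
    def test_additive_over_disjoint_bands(self, split):
        rng = np.random.default_rng(1)
        freqs = np.arange(0, 0.5, 1.0 / 300.0)
        spec = hrv.Spectrum(freqs=freqs, density=rng.uniform(0, 5, freqs.size))
        whole = hrv.band_power(spec, (0.04, 0.14))
        parts = hrv.band_power(spec, (0.04, split)) + hrv.band_power(
            spec, (split, 0.14)
        )
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_empty_band_rejected(self):
        freqs = np.arange(0, 0.5, 0.01)
        spec = hrv.Spectrum(freqs=freqs, density=np.ones_like(freqs))
        with pytest.raises(ValueError):
            hrv.band_power(spec, (0.14, 0.14))


class TestZScores:
    @pytest.fixture()
    def norms(self):
        means = {m: 10.0 for m in hrv.METRIC_NAMES}
        sds = {m: 2.0 for m in hrv.METRIC_NAMES}
        return hrv.ControlNorms(means=means, sds=sds, n_controls=20)

    def metrics_at(self, value):
        return hrv.HRVMetrics(
            vc=value, rmssd=value, lf_power=value, hf_power=value,
            mean_rr=800.0, n_beats=300,
        )

    def test_mean_gives_zero_not_abnormal(self, norms):
        panel = hrv.zscore_panel(self.metrics_at(10.0), norms)
        assert all(z == 0.0 for z in panel.z.values())
        assert not panel.any_abnormal()

    def test_exactly_minus_one_sd_not_abnormal(self, norms):
        panel = hrv.zscore_panel(self.metrics_at(8.0), norms)
        assert all(z == -1.0 for z in panel.z.values())
        assert not panel.any_abnormal()  # strict inequality

    def test_two_sd_reduction_abnormal(self, norms):
        panel = hrv.zscore_panel(self.metrics_at(6.0), norms)
        assert panel.any_abnormal()
        assert all(panel.abnormal.values())

    def test_elevation_never_abnormal(self, norms):
        panel = hrv.zscore_panel(self.metrics_at(30.0), norms)
        assert not panel.any_abnormal()

    def test_control_cohort_self_z_is_standardized(self):
        rng = np.random.default_rng(3)
        cohort = [
            hrv.HRVMetrics(
                vc=rng.normal(0.05, 0.01),
                rmssd=rng.normal(40, 10),
                lf_power=rng.normal(600, 150),
                hf_power=rng.normal(300, 80),
                mean_rr=800.0,
                n_beats=300,
            )
            for _ in range(20)
        ]
        norms = hrv.ControlNorms.from_cohort(cohort)
        panels = [hrv.zscore_panel(m, norms) for m in cohort]
        for metric in hrv.METRIC_NAMES:
            zs = np.array([p.z[metric] for p in panels])
            assert zs.mean() == pytest.approx(0.0, abs=1e-10)
            assert zs.std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_degenerate_sd_rejected(self):
        with pytest.raises(ValueError):
            hrv.ControlNorms(
                means={m: 1.0 for m in hrv.METRIC_NAMES},
                sds={m: 0.0 for m in hrv.METRIC_NAMES},
                n_controls=5,
            )
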