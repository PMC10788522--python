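"""Time-resolved PDC: filtering, DEKF estimation, PDC math, profiles."""

import numpy as np
import pytest

from hrvnet import simulate, tpdc
from hrvnet.lesions import AtlasLabels, LesionMap
from hrvnet.tpdc import (
    SEVEN_NETWORKS,
    FilterParams,
    MultichannelTimeSeries,
    TVMVARModel,
    band_time_average,
    bandpass,
    connectivity_profile,
    default_freq_grid,
    extract_seed_and_networks,
    fit_dekf,
    pdc_from_coeffs,
    select_order,
    var_ls_fit,
)


def sinusoid_ts(freq, n=2000, fs=1.0):
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * freq * t)
    return MultichannelTimeSeries(data=np.stack([x, x]), sample_rate=fs)


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        ts = sinusoid_ts(0.05)
        out = bandpass(ts, 0.01, 0.1)
        mid = slice(200, 1800)  # away from filter edge effects
        ratio = out.data[0, mid].std() / ts.data[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_sinusoid_attenuated(self):
        ts = sinusoid_ts(0.3)
        out = bandpass(ts, 0.01, 0.1)
        mid = slice(200, 1800)
        assert out.data[0, mid].std() < 0.1 * ts.data[0, mid].std()

    def test_zero_signal_stays_zero(self):
        ts = MultichannelTimeSeries(data=np.zeros((2, 500)))
        out = bandpass(ts, 0.01, 0.1)
        assert np.allclose(out.data, 0.0)

    def test_band_outside_nyquist_rejected(self):
        ts = sinusoid_ts(0.05)
        with pytest.raises(ValueError):
            bandpass(ts, 0.01, 0.6)


class TestExtractSeedAndNetworks:
    def make_inputs(self, vol):
        pattern = np.zeros(vol.shape[:3])
        pattern[0, 0, 0] = 1.0
        parc = simulate.gen_atlas(vol.shape[:3], 7)
        return LesionMap(values=pattern), parc

    def test_single_voxel_pattern_returns_that_voxel(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(7, 2, 1, 50))
        pattern, parc = self.make_inputs(vol)
        ts = extract_seed_and_networks(vol, pattern, parc)
        np.testing.assert_allclose(ts.data[0], vol[0, 0, 0])
        assert ts.channel_names[0] == "seed"
        assert tuple(ts.channel_names[1:]) == SEVEN_NETWORKS

    def test_antisymmetric_pair_pools_to_zero(self):
        vol = np.zeros((7, 2, 1, 30))
        s = np.sin(np.arange(30) / 3.0)
        vol[0, 0, 0] = s
        vol[0, 1, 0] = -s
        pattern = np.zeros((7, 2, 1))
        pattern[0, 0, 0] = 1.0
        pattern[0, 1, 0] = 1.0
        parc = simulate.gen_atlas((7, 2, 1), 7)
        ts = extract_seed_and_networks(vol, LesionMap(values=pattern), parc)
        np.testing.assert_allclose(ts.data[0], 0.0, atol=1e-12)

    def test_uniform_volume_gives_identical_channels(self):
        vol = np.broadcast_to(
            np.sin(np.arange(40) / 5.0), (7, 2, 1, 40)
        ).copy()
        pattern, parc = self.make_inputs(vol)
        ts = extract_seed_and_networks(vol, pattern, parc)
        for k in range(1, 8):
            np.testing.assert_allclose(ts.data[k], ts.data[0])

    def test_empty_seed_rejected(self):
        vol = np.zeros((7, 2, 1, 30))
        parc = simulate.gen_atlas((7, 2, 1), 7)
        with pytest.raises(ValueError, match="active"):
            extract_seed_and_networks(vol, LesionMap(values=np.zeros((7, 2, 1))), parc)


class TestSelectOrder:
    def test_var2_data_selects_two_or_three(self, var2_coeffs):
        a1, a2 = var2_coeffs
        hits = 0
        for seed in range(20):
            ts, _ = simulate.gen_mvar_network(
                simulate.CouplingSpec(
                    n_channels=2, order=2, coeff_matrices=[a1, a2],
                    n_samples=2000, seed=seed,
                )
            )
            if select_order(ts, range(1, 9)) in (2, 3):
                hits += 1
        assert hits >= 16  # >= 80 % of 20 seeds

    def test_white_noise_prefers_order_one(self):
        picks = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            picks.append(
                select_order(
                    MultichannelTimeSeries(data=rng.normal(size=(2, 2000))),
                    range(1, 9),
                )
            )
        assert np.bincount(picks).argmax() == 1

    def test_candidates_truncated_with_warning(self):
        rng = np.random.default_rng(0)
        ts = MultichannelTimeSeries(data=rng.normal(size=(2, 40)))
        with pytest.warns(UserWarning, match="truncated"):
            order = select_order(ts, range(1, 20))
        assert order >= 1


class TestFitDEKF:
    def test_constant_var2_recovery_vs_truth_and_ls(self, var2_coeffs):
        a1, a2 = var2_coeffs
        ts, _ = simulate.gen_mvar_network(
            simulate.CouplingSpec(
                n_channels=2, order=2, coeff_matrices=[a1, a2],
                n_samples=2000, seed=0,
            )
        )
        model = fit_dekf(ts, order=2)
        est = model.time_average()
        truth = np.stack([a1, a2])
        assert np.sqrt(np.mean((est - truth) ** 2)) < 0.1
        ls, _, _ = var_ls_fit(ts.data, 2)
        assert np.sqrt(np.mean((est - ls) ** 2)) < 0.05

    def test_uncoupled_noise_gives_near_zero_cross_terms(self):
        rng = np.random.default_rng(1)
        ts = MultichannelTimeSeries(data=rng.normal(size=(2, 2000)))
        model = fit_dekf(ts, order=1)
        off = model.coeffs[:, 0, [0, 1], [1, 0]]
        # the random-walk prior lets the instantaneous estimate wander, but
        # it hovers around zero: the time average stays within +-0.1 and
        # the trajectory never strays far
        assert np.abs(off.mean(axis=0)).max() < 0.1
        assert np.abs(off).max() < 0.35
        assert np.mean(np.abs(off) < 0.2) > 0.9

    def test_tracks_scheduled_coefficient_switch(self):
        zero = np.zeros((2, 2))
        on = np.array([[0.0, 0.0], [0.5, 0.0]])
        n = 4000
        ts, _ = simulate.gen_mvar_network(
            simulate.CouplingSpec(
                n_channels=2, order=1,
                coeff_matrices=[(0, [zero]), (n // 2, [on])],
                n_samples=n, seed=2,
            )
        )
        model = fit_dekf(ts, order=1)
        traj = model.coeffs[:, 0, 1, 0]
        offset = model.burn_in_dropped + 1  # trajectory index -> sample index
        crossing = np.argmax(traj > 0.25) + offset
        assert abs(crossing - n // 2) < 0.15 * n

    def test_burn_in_discarded(self):
        rng = np.random.default_rng(3)
        ts = MultichannelTimeSeries(data=rng.normal(size=(2, 1000)))
        model = fit_dekf(ts, order=2, params=FilterParams(burn_in=0.25))
        assert model.burn_in_dropped == int(0.25 * (1000 - 2))
        assert model.coeffs.shape[0] == (1000 - 2) - model.burn_in_dropped


class TestPDC:
    def brute_force_pdc(self, coeff_mats, freq):
        """Independent complex-arithmetic oracle for squared PDC."""
        p = len(coeff_mats)
        c = coeff_mats[0].shape[0]
        abar = np.eye(c, dtype=complex)
        for r, A in enumerate(coeff_mats, start=1):
            abar = abar - A * np.exp(-2j * np.pi * freq * r)
        out = np.empty((c, c))
        for i in range(c):
            for j in range(c):
                out[i, j] = abs(abar[i, j]) ** 2 / sum(
                    abs(abar[k, j]) ** 2 for k in range(c)
                )
        return out

    def model_from(self, mats, n_time=3):
        arr = np.broadcast_to(
            np.stack(mats), (n_time, len(mats), *mats[0].shape)
        ).copy()
        return TVMVARModel(
            order=len(mats), coeffs=arr, innovation_cov=np.eye(mats[0].shape[0])
        )

    def test_identity_case_all_diagonal(self):
        model = self.model_from([np.zeros((3, 3))])
        pdc = pdc_from_coeffs(model)
        diag = pdc.values[:, :, [0, 1, 2], [0, 1, 2]]
        assert np.allclose(diag, 1.0)
        off = pdc.values.sum() - diag.sum()
        assert off == pytest.approx(0.0, abs=1e-12)

    def test_unidirectional_coupling_matches_brute_force(self):
        a1 = np.array([[0.3, 0.0], [0.5, 0.3]])
        model = self.model_from([a1])
        grid = default_freq_grid(10)
        pdc = pdc_from_coeffs(model, freq_grid=grid)
        for fi, f in enumerate(grid):
            expected = self.brute_force_pdc([a1], f)
            np.testing.assert_allclose(pdc.values[0, fi], expected, atol=1e-12)
        assert np.all(pdc.values[:, :, 1, 0] > 0)
        assert np.allclose(pdc.values[:, :, 0, 1], 0.0)

    def test_column_sums_exactly_one(self, var2_coeffs):
        a1, a2 = var2_coeffs
        ts, _ = simulate.gen_mvar_network(
            simulate.CouplingSpec(
                n_channels=2, order=2, coeff_matrices=[a1, a2],
                n_samples=1000, seed=4,
            )
        )
        pdc = pdc_from_coeffs(fit_dekf(ts, order=2))
        sums = pdc.values.sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)

    def test_common_rescaling_leaves_pdc_unchanged(self, var2_coeffs):
        a1, a2 = var2_coeffs
        ts, _ = simulate.gen_mvar_network(
            simulate.CouplingSpec(
                n_channels=2, order=2, coeff_matrices=[a1, a2],
                n_samples=1500, seed=5,
            )
        )
        scaled = MultichannelTimeSeries(data=ts.data * 7.5)
        m1 = band_time_average(pdc_from_coeffs(fit_dekf(ts, order=2)))
        m2 = band_time_average(pdc_from_coeffs(fit_dekf(scaled, order=2)))
        np.testing.assert_allclose(m1, m2, atol=0.02)


class TestBandTimeAverage:
    def tensor(self, values, freqs):
        return tpdc.PDCTensor(values=values, freqs=np.asarray(freqs))

    def test_constant_tensor_returns_constant(self):
        values = np.full((5, 8, 2, 2), 0.37)
        freqs = np.linspace(0.01, 0.4, 8)
        out = band_time_average(self.tensor(values, freqs), band=(0.0, 0.5))
        np.testing.assert_allclose(out, 0.37)

    def test_band_masking_distinguishes_in_band_content(self):
        freqs = np.linspace(0.01, 0.4, 10)
        in_band = freqs <= 0.08
        values = np.zeros((3, 10, 2, 2))
        values[:, in_band] = 1.0
        masked = band_time_average(self.tensor(values, freqs), band=(0.0, 0.08))
        full = band_time_average(self.tensor(values, freqs), band=(0.0, 0.5))
        assert masked == pytest.approx(1.0)
        assert full[0, 0] < 1.0

    def test_empty_band_intersection_rejected(self):
        values = np.zeros((2, 4, 2, 2))
        with pytest.raises(ValueError):
            band_time_average(
                self.tensor(values, [0.1, 0.2, 0.3, 0.4]), band=(0.45, 0.49)
            )


class TestConnectivityProfile:
    def test_coupled_network_has_maximal_forward_value(self):
        a1 = np.zeros((8, 8))
        np.fill_diagonal(a1, 0.3)
        a1[6, 0] = 0.5  # seed drives channel 6 (Limbic)
        ts, _ = simulate.gen_mvar_network(
            simulate.CouplingSpec(
                n_channels=8, order=1, coeff_matrices=[a1],
                n_samples=1500, seed=6,
            )
        )
        ts = MultichannelTimeSeries(
            data=ts.data, channel_names=["seed", *SEVEN_NETWORKS]
        )
        profile = connectivity_profile(ts, order=2, time_stride=5)
        values = profile.forward
        assert max(values, key=values.get) == "Limbic"
        assert profile.significant_forward["Limbic"]

    def test_wrong_channel_count_rejected(self):
        rng = np.random.default_rng(0)
        ts = MultichannelTimeSeries(data=rng.normal(size=(3, 500)))
        with pytest.raises(ValueError, match="8 channels"):
            connectivity_profile(ts)
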