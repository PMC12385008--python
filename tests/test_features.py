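"""Feature extractor vs independent brute-force oracles."""

import math

import numpy as np
import pytest

from eegstress.data import MultiChannelRecording
from eegstress.features import (
    FEATURES_PER_CHANNEL,
    MEFExtractor,
    N_SK_BINS,
    channel_features,
    extract_mef,
    feature_names,
    hjorth_parameters,
    instantaneous_bandwidth,
    instantaneous_mean_frequency,
    lbp_codes,
    lgp_codes,
    lndp_codes,
    spectral_features,
    texture_features,
    time_domain_features,
    wpt_subband_features,
)

# -- independent oracle implementations (plain python / direct formulas) ----


def oracle_time_domain(x):
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    med = float(np.median(x))
    skw = 0.0
    if var > 0:
        skw = (sum((v - mean) ** 3 for v in x) / n) / sd**3
    signs = [1 if v >= 0 else -1 for v in x]
    zcr = sum(signs[i] != signs[i - 1] for i in range(1, n)) / (n - 1)
    act = sum((v - mean) ** 2 for v in x) / (n - 1)
    dx = [x[i + 1] - x[i] for i in range(n - 1)]
    mob = cmp_ = 0.0
    if act > 0:
        mdx = sum(dx) / len(dx)
        act_dx = sum((v - mdx) ** 2 for v in dx) / (len(dx) - 1)
        mob = math.sqrt(act_dx / act)
        if mob > 0:
            ddx = [dx[i + 1] - dx[i] for i in range(len(dx) - 1)]
            mddx = sum(ddx) / len(ddx)
            act_ddx = sum((v - mddx) ** 2 for v in ddx) / (len(ddx) - 1)
            mob_dx = math.sqrt(act_ddx / act_dx) if act_dx > 0 else 0.0
            cmp_ = mob_dx / mob
    rms = math.sqrt(sum(v**2 for v in x) / n)
    if max(x) == min(x):
        sne = 0.0
    else:
        counts, _ = np.histogram(x, bins=64)
        sne = -sum(
            (c / n) * math.log(c / n) for c in counts if c > 0
        )
    ll = sum(abs(x[i] - x[i - 1]) for i in range(1, n))
    ne = sum(x[i] ** 2 - x[i + 1] * x[i - 1] for i in range(1, n - 1))
    return np.array([mean, sd, var, med, skw, zcr, act, mob, cmp_, rms, sne, ll, ne])


class TestTimeDomain:
    def test_against_oracle_on_random_signals(self, rng):
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(16, 256)))
            got = time_domain_features(x)
            want = oracle_time_domain(x)
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-9)

    def test_small_example(self):
        got = time_domain_features([1, 2, 3, 4, 5])
        mean, sd, var, med = got[0], got[1], got[2], got[3]
        act, mob = got[6], got[7]
        rms = got[9]
        assert mean == 3 and med == 3
        assert abs(rms - math.sqrt(11)) < 1e-12
        assert act == 2.5
        assert mob == 0.0  # first difference is constant
        assert abs(var - 2.0) < 1e-12 and abs(sd - math.sqrt(2)) < 1e-12

    def test_constant_signal_degenerates_to_zero(self):
        got = time_domain_features(np.full(32, 7.0))
        names = ("sd", "variance", "zcr", "shannon_entropy", "line_length")
        idx = {"sd": 1, "variance": 2, "zcr": 5, "shannon_entropy": 10, "line_length": 11}
        for nm in names:
            assert got[idx[nm]] == 0.0, nm
        assert got[12] == pytest.approx(7**2 * 30 - 7 * 7 * 30)  # nonlinear energy

    def test_alternating_nonlinear_energy_and_line_length(self):
        got = time_domain_features([0, 1, 0, 1])
        assert got[12] == 0.0  # (1-0) + (0-1)
        assert got[11] == 3.0  # |1|+|−1|+|1|

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_domain_features([1.0, 2.0])

    def test_scaling_behavior(self, rng):
        x = rng.normal(size=128)
        a = 3.7
        f1, f2 = time_domain_features(x), time_domain_features(a * x)
        for i in (0, 1, 9, 11):  # mean, sd, rms, line length scale linearly
            assert f2[i] == pytest.approx(a * f1[i], rel=1e-9)
        for i in (5, 7, 8):  # zcr, mobility, complexity scale-invariant
            assert f2[i] == pytest.approx(f1[i], rel=1e-9)


class TestHjorth:
    def test_constant_convention(self):
        assert hjorth_parameters(np.ones(16)) == (0.0, 0.0, 0.0)

    def test_alternating_signal_matches_oracle(self):
        x = np.tile([1.0, -1.0], 32)
        got = hjorth_parameters(x)
        want = oracle_time_domain(x)[[6, 7, 8]]
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_white_noise_complexity_exceeds_one(self):
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=512)
            _, _, cmp_ = hjorth_parameters(x)
            assert cmp_ > 1.0


class TestWptSubbands:
    def test_feature_count(self, rng):
        out = wpt_subband_features(rng.normal(size=512))
        assert out.shape == (224,)

    def test_zero_signal(self):
        out = wpt_subband_features(np.zeros(256))
        energies = out[2::7]
        entropies = out[6::7]
        assert np.all(energies == 0) and np.all(entropies == 0)

    def test_energy_conservation(self, rng):
        """Orthogonal packet tree: subband energies sum to signal energy."""
        for _ in range(10):
            x = rng.normal(size=1024)
            out = wpt_subband_features(x)
            total = out[2::7].sum()
            assert abs(total - np.sum(x**2)) / np.sum(x**2) < 1e-3

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            wpt_subband_features(np.zeros(16))


class TestSpectral:
    def test_single_bin_psd(self):
        freqs = np.array([5.0, 10.0, 15.0])
        psd = np.array([0.0, 2.3, 0.0])
        assert instantaneous_mean_frequency(freqs, psd) == pytest.approx(10.0)
        assert instantaneous_bandwidth(freqs, psd) == pytest.approx(0.0)

    def test_two_equal_bins(self):
        freqs = np.array([8.0, 12.0])
        psd = np.array([1.0, 1.0])
        assert instantaneous_mean_frequency(freqs, psd) == pytest.approx(10.0)
        assert instantaneous_bandwidth(freqs, psd) == pytest.approx(4.0)

    def test_energy_of_padded_sequence(self):
        x = np.zeros(512)
        x[:3] = [1, 2, 2]
        out = spectral_features(x, fs=128.0)
        assert out[0] == pytest.approx(9.0)

    def test_output_length_and_zero_convention(self):
        out = spectral_features(np.zeros(512), fs=128.0)
        assert out.shape == (3 + N_SK_BINS,)
        assert np.all(out == 0)

    def test_welch_iwmf_locates_tone(self):
        fs = 128.0
        t = np.arange(4096) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        out = spectral_features(x, fs)
        assert abs(out[1] - 10.0) < 0.5  # IWMF near the tone
        assert out[2] < 2.0  # narrow bandwidth

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            spectral_features(np.zeros(100), fs=128.0)


class TestTexture:
    def test_histograms_normalized(self, rng):
        out = texture_features(rng.normal(size=300))
        for k in range(3):
            assert out[k * 10 : (k + 1) * 10].sum() == pytest.approx(1.0, abs=1e-12)

    def test_ramp_gives_single_lbp_code(self):
        x = np.arange(50.0)
        codes = lbp_codes(x)
        assert np.unique(codes).size == 1
        assert codes[0] == 15  # four left-neighbor bits set: 1+2+4+8
        hist = texture_features(x)[:10]
        assert np.count_nonzero(hist) == 1

    def test_constant_signal_gives_zero_codes(self):
        x = np.full(40, 2.5)
        for fn in (lbp_codes, lgp_codes, lndp_codes):
            assert np.all(fn(x) == 0)
        out = texture_features(x)
        for k in range(3):
            np.testing.assert_array_equal(
                out[k * 10 : (k + 1) * 10], [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
            )

    def test_lbp_oracle_small_window(self):
        # center x[4]=0; left neighbors -4..-1, right 1..4, bit=1 iff diff<0
        x = np.array([1.0, -2.0, 3.0, -4.0, 0.0, 5.0, -6.0, 7.0, -8.0, 9.0])
        diffs = [x[0], x[1], x[2], x[3], x[5], x[6], x[7], x[8]]
        want = sum((d < 0) << i for i, d in enumerate(diffs))
        assert lbp_codes(x)[0] == want

    def test_scale_invariance(self, rng):
        x = rng.normal(size=200)
        np.testing.assert_array_equal(lbp_codes(x), lbp_codes(4.2 * x))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            texture_features(np.zeros(9))


class TestAssembly:
    def test_one_channel_is_527(self, rng):
        x = rng.normal(size=1024)
        assert channel_features(x, 128.0).shape == (FEATURES_PER_CHANNEL,)
        assert FEATURES_PER_CHANNEL == 527

    def test_names_match_values(self, rng):
        rec = MultiChannelRecording(rng.normal(size=(2, 1024)), 128.0, ["Fp1", "Fp2"])
        values, names = extract_mef(rec)
        assert len(values) == len(names) == 2 * 527
        assert names[0] == "Fp1.time.mean"
        assert names[527] == "Fp2.time.mean"

    def test_fifteen_channels(self, rng):
        rec = MultiChannelRecording(rng.normal(size=(15, 1024)), 128.0)
        values, _ = extract_mef(rec)
        assert values.shape == (15 * 527,)

    def test_channel_permutation_permutes_blocks(self, rng):
        rec = MultiChannelRecording(rng.normal(size=(3, 1024)), 128.0)
        v01, _ = extract_mef(rec, [0, 1])
        v10, _ = extract_mef(rec, [1, 0])
        np.testing.assert_array_equal(v01[:527], v10[527:])
        np.testing.assert_array_equal(v01[527:], v10[:527])

    def test_bad_channel_index(self, rng):
        rec = MultiChannelRecording(rng.normal(size=(2, 1024)), 128.0)
        with pytest.raises(ValueError):
            extract_mef(rec, [5])

    def test_extractor_dataframe(self, small_trialset):
        table = MEFExtractor(channels=[0, 1]).transform(small_trialset[:3])
        assert table.shape == (3, 2 * 527)
        assert table.columns[0] == "ch00.time.mean"
        assert np.isfinite(table.to_numpy()).all()
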