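"""Synthetic generation, labeling rule and file round-trips."""

import numpy as np
import pytest
from scipy.signal import periodogram

from eegstress.data import (
    CALM,
    STRESS,
    UNLABELED,
    EEG_BANDS,
    MultiChannelRecording,
    SynthSpec,
    TrialSet,
    generate_synthetic_dataset,
    label_trial,
    read_recording,
    write_recording,
)


class TestLabelRule:
    @pytest.mark.parametrize(
        "arousal,valence,expected",
        [
            (3, 5, CALM),
            (6, 2, STRESS),
            (4.5, 7, UNLABELED),
            (0, 4.5, CALM),
            (9, 0, STRESS),
            # boundary values are strict -> unlabeled
            (4, 5, UNLABELED),
            (5, 2, UNLABELED),
            (6, 3, UNLABELED),
            (3, 4, UNLABELED),
            (3, 6, UNLABELED),
        ],
    )
    def test_examples(self, arousal, valence, expected):
        assert label_trial(arousal, valence) == expected

    @pytest.mark.parametrize("arousal,valence", [(-0.1, 5), (4, 9.2), (np.nan, 5)])
    def test_out_of_range_ratings_rejected(self, arousal, valence):
        with pytest.raises(ValueError):
            label_trial(arousal, valence)

    def test_partition_over_rating_grid(self):
        """Every rating pair maps to exactly one of the three outcomes and
        the calm and stress regions never overlap (grid scan at step 0.1)."""
        grid = np.round(np.arange(0, 9.01, 0.1), 10)
        seen = set()
        for a in grid:
            for v in grid:
                lab = label_trial(a, v)
                seen.add(lab)
                calm = a < 4 and 4 < v < 6
                stress = a > 5 and v < 3
                assert not (calm and stress)
                assert lab == (CALM if calm else STRESS if stress else UNLABELED)
        assert seen == {CALM, STRESS, UNLABELED}


class TestRecordingContainers:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MultiChannelRecording(np.zeros((2, 1)), 128.0)
        with pytest.raises(ValueError):
            MultiChannelRecording(np.full((1, 4), np.nan), 128.0)
        with pytest.raises(ValueError):
            MultiChannelRecording(np.zeros((2, 4)), -1.0)
        with pytest.raises(ValueError):
            MultiChannelRecording(np.zeros((2, 4)), 128.0, ["only-one"])

    def test_trialset_label_consistency_checked(self):
        rec = MultiChannelRecording(np.zeros((1, 4)), 128.0)
        with pytest.raises(ValueError):
            TrialSet([rec], arousal=[3.0], valence=[5.0], labels=[STRESS])


class TestSyntheticGenerator:
    def test_sample_count_and_classes(self):
        spec = SynthSpec(n_trials_per_class=2, n_channels=3, duration_s=60.0, fs=128.0)
        ts = generate_synthetic_dataset(spec)
        assert len(ts) == 4
        assert all(t.n_samples == 7680 for t in ts.trials)
        assert ts.labels == [CALM, CALM, STRESS, STRESS]
        for a, v, lab in zip(ts.arousal, ts.valence, ts.labels):
            assert label_trial(a, v) == lab

    def test_seed_determinism(self):
        spec = SynthSpec(n_trials_per_class=3, n_channels=4, duration_s=2.0, seed=11)
        a = generate_synthetic_dataset(spec)
        b = generate_synthetic_dataset(spec)
        for ta, tb in zip(a.trials, b.trials):
            np.testing.assert_array_equal(ta.data, tb.data)
        np.testing.assert_array_equal(a.arousal, b.arousal)
        np.testing.assert_array_equal(a.valence, b.valence)

    def test_identical_profiles_give_equal_band_power(self):
        """With no noise and the same band profile for both classes, the mean
        per-channel band powers agree within 5% (periodogram oracle)."""
        profile = {"delta": 10.0, "theta": 8.0, "alpha": 20.0, "beta": 6.0, "gamma": 3.0}
        spec = SynthSpec(
            n_trials_per_class=20,
            n_channels=2,
            duration_s=10.0,
            informative_channels=(0, 1),
            band_power_profile={CALM: profile, STRESS: profile},
            noise_sd=0.0,
            seed=3,
        )
        ts = generate_synthetic_dataset(spec)
        labels = ts.label_array()

        def band_powers(subset):
            powers = []
            for rec in subset.trials:
                # hann window: boxcar leakage from strong neighboring bands
                # would otherwise contaminate the weak bands
                f, p = periodogram(rec.data, fs=rec.fs, axis=1, window="hann")
                powers.append(
                    [
                        p[:, (f >= lo) & (f < hi)].sum(axis=1)
                        for lo, hi in EEG_BANDS.values()
                    ]
                )
            return np.mean(powers, axis=0)

        p_calm = band_powers(ts[labels == CALM])
        p_stress = band_powers(ts[labels == STRESS])
        assert np.all(np.abs(p_calm - p_stress) / p_calm < 0.05)

    def test_stress_elevates_beta_power(self):
        """Mean beta power on informative channels is higher for stress in
        >= 95% of seeded replicates (default profiles, low noise)."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            spec = SynthSpec(
                n_trials_per_class=4,
                n_channels=4,
                duration_s=4.0,
                informative_channels=(0, 1),
                noise_sd=1.0,
                seed=seed,
            )
            ts = generate_synthetic_dataset(spec)
            labels = ts.label_array()
            lo, hi = EEG_BANDS["beta"]

            def beta(subset):
                vals = []
                for rec in subset.trials:
                    f, p = periodogram(rec.data[:2], fs=rec.fs, axis=1)
                    vals.append(p[:, (f >= lo) & (f < hi)].sum())
                return np.mean(vals)

            wins += beta(ts[labels == STRESS]) > beta(ts[labels == CALM])
        assert wins >= 0.95 * n_rep

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_trials_per_class=0),
            dict(n_channels=0),
            dict(duration_s=-1),
            dict(fs=50.0),  # below twice the top band edge
            dict(informative_channels=(9,)),
            dict(noise_sd=-1.0),
        ],
    )
    def test_invalid_spec_rejected(self, bad):
        kwargs = {"n_channels": 4, **bad}
        with pytest.raises(ValueError):
            generate_synthetic_dataset(SynthSpec(**kwargs))


class TestFileIO:
    def test_tiny_csv(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("1,2,3,4\n5,6,7,8\n")
        ts = read_recording(path)
        assert ts.trials[0].n_channels == 2
        assert ts.trials[0].n_samples == 4
        assert ts.labels == [UNLABELED]

    def test_round_trip(self, tmp_path, sine_recording):
        path = tmp_path / "trial.csv"
        write_recording(sine_recording, path, arousal=6.0, valence=2.0)
        ts = read_recording(path)
        np.testing.assert_allclose(ts.trials[0].data, sine_recording.data, atol=1e-12)
        assert ts.trials[0].fs == sine_recording.fs
        assert ts.labels == [STRESS]

    def test_malformed_csv_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1,2,3\n4,oops,6\n")
        with pytest.raises(ValueError, match="line 2"):
            read_recording(path)

    def test_ragged_csv_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("1,2,3\n4,5\n")
        with pytest.raises(ValueError, match="line 2"):
            read_recording(path)

    @pytest.mark.parametrize("dialect", ["pickle", "npz"])
    def test_subject_container_geometry(self, tmp_path, dialect):
        """A 40-trial container yields 40 trials x 32 EEG channels x 8064
        samples; peripheral rows are dropped and ratings become labels."""
        rng = np.random.default_rng(0)
        data = rng.normal(size=(40, 40, 8064))
        ratings = np.column_stack(
            [
                rng.uniform(0, 9, 40),  # valence
                rng.uniform(0, 9, 40),  # arousal
                rng.uniform(0, 9, 40),
                rng.uniform(0, 9, 40),
            ]
        )
        if dialect == "pickle":
            import pickle

            path = tmp_path / "s01.dat"
            path.write_bytes(pickle.dumps({"data": data, "labels": ratings}))
        else:
            path = tmp_path / "s01.npz"
            np.savez(path, data=data, labels=ratings)
        ts = read_recording(path, format="deap_container")
        assert len(ts) == 40
        assert all(t.n_channels == 32 for t in ts.trials)
        assert all(t.n_samples == 8064 for t in ts.trials)
        for lab, a, v in zip(ts.labels, ts.arousal, ts.valence):
            assert lab == label_trial(a, v)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_recording("/nonexistent/file.csv")
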