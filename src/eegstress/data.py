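"""EEG containers, synthetic trial generation, file I/O and affect-rating labels.

The central containers are :class:`MultiChannelRecording` (one channels x
samples matrix with its sampling rate) and :class:`TrialSet` (a list of
recordings with per-trial arousal/valence ratings and calm/stress labels).

The synthetic generator emulates the geometry of affect-elicitation EEG
corpora: 128 Hz sampling, 60 s trials, band-limited oscillatory content in
the five canonical EEG bands, two classes that differ in band power (alpha
suppression plus beta/gamma elevation under stress), additive Gaussian
sensor noise, and 0-9 self-assessment ratings of arousal and valence that
are consistent with the calm/stress labelling rule.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EEG_BANDS",
    "CALM",
    "STRESS",
    "UNLABELED",
    "MultiChannelRecording",
    "TrialSet",
    "SynthSpec",
    "generate_synthetic_dataset",
    "label_trial",
    "read_recording",
    "write_recording",
]

#: Canonical EEG frequency bands in Hz. Gamma is capped at 45 Hz, the upper
#: edge of the analysis band-pass, rather than the physiological ~100 Hz.
EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

CALM = "calm"
STRESS = "stress"
UNLABELED = "unlabeled"


@dataclass
class MultiChannelRecording:
    """One multi-channel EEG recording.

    Parameters
    ----------
    data : ndarray of shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str, optional
        10-20 system labels where known; auto-named ``ch00`` ... otherwise.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[1] < 2:
            raise ValueError("n_samples must be >= 2")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "MultiChannelRecording":
        return MultiChannelRecording(data, self.fs, list(self.channel_names))


class TrialSet:
    """A collection of trials with optional affect ratings and labels.

    Arousal/valence are NaN where unknown; labels are one of
    ``"calm"``, ``"stress"``, ``"unlabeled"``.
    """

    def __init__(
        self,
        trials: Sequence[MultiChannelRecording],
        arousal: Sequence[float] | None = None,
        valence: Sequence[float] | None = None,
        labels: Sequence[str] | None = None,
    ) -> None:
        self.trials = list(trials)
        n = len(self.trials)
        self.arousal = (
            np.full(n, np.nan) if arousal is None else np.asarray(arousal, dtype=float)
        )
        self.valence = (
            np.full(n, np.nan) if valence is None else np.asarray(valence, dtype=float)
        )
        if labels is None:
            labels = [
                label_trial(a, v) if np.isfinite(a) and np.isfinite(v) else UNLABELED
                for a, v in zip(self.arousal, self.valence)
            ]
        self.labels = list(labels)
        if not (len(self.arousal) == len(self.valence) == len(self.labels) == n):
            raise ValueError("trials, ratings and labels must share length")
        for lab, a, v in zip(self.labels, self.arousal, self.valence):
            if lab not in (CALM, STRESS, UNLABELED):
                raise ValueError(f"unknown label {lab!r}")
            if np.isfinite(a) and np.isfinite(v) and lab != label_trial(a, v):
                raise ValueError("label inconsistent with ratings")

    def __len__(self) -> int:
        return len(self.trials)

    def __getitem__(self, idx) -> "TrialSet":
        if isinstance(idx, (slice, int)):
            idx = np.arange(len(self))[idx]
        idx = np.atleast_1d(np.asarray(idx))
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return TrialSet(
            [self.trials[i] for i in idx],
            self.arousal[idx],
            self.valence[idx],
            [self.labels[i] for i in idx],
        )

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    def stack(self) -> np.ndarray:
        """All trials as one (n_trials, n_channels, n_samples) array."""
        return np.stack([t.data for t in self.trials])

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


def label_trial(arousal: float, valence: float) -> str:
    """Map a 0-9 arousal/valence rating pair to calm / stress / unlabeled.

    Calm requires low arousal with mid valence (arl < 4 and 4 < val < 6);
    stress requires high arousal with low valence (arl > 5 and val < 3).
    The inequalities are strict, so boundary ratings are unlabeled.
    """
    arousal = float(arousal)
    valence = float(valence)
    for name, r in (("arousal", arousal), ("valence", valence)):
        if not np.isfinite(r) or not 0.0 <= r <= 9.0:
            raise ValueError(f"{name} rating {r!r} outside [0, 9]")
    if arousal < 4.0 and 4.0 < valence < 6.0:
        return CALM
    if arousal > 5.0 and valence < 3.0:
        return STRESS
    return UNLABELED


# -- synthetic generation ---------------------------------------------------

#: Default per-band sinusoid amplitudes (microvolts RMS-of-band proxy) for
#: the two classes: the stress profile suppresses alpha and elevates
#: beta/gamma relative to calm, the signature the classifier is meant to read.
DEFAULT_BAND_PROFILES: dict[str, dict[str, float]] = {
    CALM: {"delta": 20.0, "theta": 15.0, "alpha": 40.0, "beta": 10.0, "gamma": 5.0},
    STRESS: {"delta": 20.0, "theta": 15.0, "alpha": 15.0, "beta": 25.0, "gamma": 12.0},
}

#: Class-independent background carried by non-informative channels. It is a
#: single shared source per trial (a volume-conduction analogue), so
#: non-informative channels are mutually correlated while informative
#: channels, which draw independent per-channel phases, are not.
DEFAULT_BACKGROUND_PROFILE: dict[str, float] = {
    "delta": 20.0,
    "theta": 15.0,
    "alpha": 25.0,
    "beta": 15.0,
    "gamma": 8.0,
}


@dataclass
class SynthSpec:
    """Specification for one synthetic two-class trial set."""

    n_trials_per_class: int = 20
    n_channels: int = 8
    duration_s: float = 60.0
    fs: float = 128.0
    informative_channels: tuple[int, ...] | None = None  # default: first half
    band_power_profile: dict[str, dict[str, float]] | None = None
    background_profile: dict[str, float] | None = None
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        chans = set(self.informative())
        if not chans <= set(range(self.n_channels)):
            raise ValueError("informative_channels out of range for n_channels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        hi = max(b[1] for b in EEG_BANDS.values())
        if self.fs < 2 * hi:
            raise ValueError(f"fs must be >= {2 * hi} Hz (twice the top band edge)")
        for prof in self.profiles().values():
            if any(p < 0 for p in prof.values()):
                raise ValueError("band_power_profile entries must be >= 0")

    def informative(self) -> tuple[int, ...]:
        if self.informative_channels is None:
            return tuple(range((self.n_channels + 1) // 2))
        return tuple(self.informative_channels)

    def profiles(self) -> dict[str, dict[str, float]]:
        prof = self.band_power_profile or DEFAULT_BAND_PROFILES
        return {c: dict(prof[c]) for c in (CALM, STRESS)}

    def background(self) -> dict[str, float]:
        return dict(self.background_profile or DEFAULT_BACKGROUND_PROFILE)


def _band_mixture(
    profile: dict[str, float], t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sum of one sinusoid per band: random in-band frequency, random phase.

    Frequencies are drawn 0.5 Hz inside the band edges (where the band is
    wide enough) so each band's power is attributable to that band alone.
    """
    x = np.zeros_like(t)
    for band, amp in profile.items():
        lo, hi = EEG_BANDS[band]
        margin = min(0.5, (hi - lo) / 4.0)
        f = rng.uniform(lo + margin, hi - margin)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += amp * np.sin(2.0 * np.pi * f * t + phase)
    return x


def generate_synthetic_dataset(spec: SynthSpec) -> TrialSet:
    """Generate a seeded two-class synthetic EEG trial set.

    Informative channels carry the class band-power profile with independent
    per-channel phases/frequencies; remaining channels carry one shared
    class-independent background source. White Gaussian noise is added
    everywhere. Ratings are drawn inside the calm/stress label regions so
    the label rule fires on every trial. Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.fs * spec.duration_s))
    t = np.arange(n_samples) / spec.fs
    informative = set(spec.informative())
    profiles = spec.profiles()
    background = spec.background()

    trials: list[MultiChannelRecording] = []
    arousal: list[float] = []
    valence: list[float] = []
    labels: list[str] = []
    for cls in (CALM, STRESS):
        for _ in range(spec.n_trials_per_class):
            bg = _band_mixture(background, t, rng)
            data = np.empty((spec.n_channels, n_samples))
            for ch in range(spec.n_channels):
                if ch in informative:
                    data[ch] = _band_mixture(profiles[cls], t, rng)
                else:
                    data[ch] = bg
            data += rng.normal(0.0, spec.noise_sd, size=data.shape)
            trials.append(MultiChannelRecording(data, spec.fs))
            if cls == CALM:
                arousal.append(rng.uniform(1.0, 3.9))
                valence.append(rng.uniform(4.1, 5.9))
            else:
                arousal.append(rng.uniform(5.1, 8.0))
                valence.append(rng.uniform(0.5, 2.9))
            labels.append(cls)
    return TrialSet(trials, arousal, valence, labels)


# -- file I/O ---------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording(
    rec: MultiChannelRecording,
    path: str | Path,
    arousal: float | None = None,
    valence: float | None = None,
) -> None:
    """Write one recording as a channels x samples CSV plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter=",", fmt="%.12g")
    meta = {"fs": rec.fs, "channel_names": rec.channel_names}
    if arousal is not None:
        meta["arousal"] = float(arousal)
    if valence is not None:
        meta["valence"] = float(valence)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_csv_recording(path: Path) -> TrialSet:
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                row = [float(tok) for tok in line.split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}: parse error at line {lineno}: {exc}") from exc
            if rows and len(row) != len(rows[0]):
                raise ValueError(
                    f"{path}: line {lineno} has {len(row)} fields, expected {len(rows[0])}"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty file")
    meta_path = _sidecar_path(path)
    fs = 128.0
    names: list[str] = []
    arousal = valence = float("nan")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        fs = float(meta.get("fs", fs))
        names = list(meta.get("channel_names", []))
        arousal = float(meta.get("arousal", arousal))
        valence = float(meta.get("valence", valence))
    rec = MultiChannelRecording(np.asarray(rows), fs, names)
    return TrialSet([rec], [arousal], [valence])


#: EEG rows retained from a 40-row affective-corpus container; rows 32-39
#: are peripheral (EOG/EMG/GSR/...) and dropped.
N_DEAP_EEG_CHANNELS = 32


def _read_deap_container(path: Path) -> TrialSet:
    """Read one per-subject container: (40, 40, 8064) data + (40, 4) ratings.

    Accepts both distribution dialects: the pickled-dict form (``.dat`` /
    ``.pkl``, keys ``data``/``labels``) and the array-container form
    (``.npz`` with the same keys, or a MATLAB ``.mat`` file).
    """
    suffix = path.suffix.lower()
    if suffix == ".npz":
        with np.load(path) as archive:
            data, ratings = archive["data"], archive["labels"]
    elif suffix == ".mat":
        from scipy.io import loadmat

        blob = loadmat(path)
        data, ratings = blob["data"], blob["labels"]
    else:
        with open(path, "rb") as fh:
            blob = pickle.load(fh, encoding="latin1")
        data, ratings = blob["data"], blob["labels"]
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D trials x channels x samples block")
    data = data[:, :N_DEAP_EEG_CHANNELS, :]
    ratings = np.asarray(ratings, dtype=float)
    trials = [MultiChannelRecording(trial, 128.0) for trial in data]
    if ratings.size == 0:
        return TrialSet(trials)
    # ratings block columns: valence, arousal, dominance, liking
    valence = np.clip(ratings[:, 0], 0.0, 9.0)
    arousal = np.clip(ratings[:, 1], 0.0, 9.0)
    return TrialSet(trials, arousal, valence)


def read_recording(path: str | Path, format: str = "csv") -> TrialSet:
    """Read recordings from disk.

    ``format="csv"``: one trial, rows are channels, sidecar JSON supplies
    fs / channel names / optional ratings. ``format="deap_container"``: a
    40-trial per-subject container; the first 32 rows of each trial are kept
    as EEG and the ratings block is mapped to valence/arousal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv_recording(path)
    if format == "deap_container":
        return _read_deap_container(path)
    raise ValueError(f"unknown format {format!r}")
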