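"""Train/test splitting, confusion counts, detection metrics, orchestration.

Stress is the positive class throughout. The six metrics are recall
TP/(TP+FN), precision TP/(TP+FP), their harmonic-mean F1, selectivity
TN/(TN+FP), negative predictive value TN/(TN+FN) and accuracy
(TP+TN)/total. ``run_experiment`` wires the full pipeline: synthesize or
load trials, split, condition, select channels, extract features, train the
hybrid classifier and score the held-out trials.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data import (
    CALM,
    STRESS,
    SynthSpec,
    TrialSet,
    generate_synthetic_dataset,
    read_recording,
)
from .features import MEFExtractor
from .network import HybridStressClassifier
from .preprocessing import FIRBandpass, WaveletPacketDenoiser
from .selection import CrowSearchChannelSelector

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "compute_metrics",
    "split_trials",
    "run_experiment",
]


@dataclass
class ConfusionCounts:
    """Binary confusion counts with stress as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("all confusion counts are zero")

    @classmethod
    def from_predictions(
        cls, y_true, y_pred, positive: str = STRESS
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t, pos_p = y_true == positive, y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


@dataclass
class MetricReport:
    recall: float
    precision: float
    f1: float
    selectivity: float
    npv: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """The six detection metrics from binary confusion counts."""
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    if np.isnan(recall) or np.isnan(precision) or recall + precision == 0:
        f1 = float("nan") if np.isnan(recall) or np.isnan(precision) else 0.0
    else:
        f1 = 2.0 * recall * precision / (recall + precision)
    return MetricReport(
        recall=recall,
        precision=precision,
        f1=f1,
        selectivity=_ratio(c.tn, c.tn + c.fp, "selectivity"),
        npv=_ratio(c.tn, c.tn + c.fn, "NPV"),
        accuracy=(c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn),
    )


def split_trials(
    trials: TrialSet, ratio: float = 0.7, seed: int | None = None
) -> tuple[TrialSet, TrialSet]:
    """Stratified train/test split of a labelled trial set.

    ``ratio`` is the training fraction. Within each class the test size is
    floor(n_class * (1 - ratio)); the remainder trains. Deterministic given
    ``seed``; the two parts are disjoint and exhaustive.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be strictly between 0 and 1")
    labels = trials.label_array()
    classes = [c for c in (CALM, STRESS) if c in labels]
    if len(classes) < 2:
        raise ValueError("both calm and stress trials are required for a split")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} needs at least 2 trials")
        rng.shuffle(idx)
        n_test = int(np.floor(idx.size * (1.0 - ratio)))
        if n_test == 0:
            raise ValueError(f"split ratio {ratio} leaves no test trials for {cls!r}")
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return trials[np.sort(train_idx)], trials[np.sort(test_idx)]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _SeededEnsemble:
    """Average of the class probabilities of seeded training replicates.

    Short training runs of the hybrid network occasionally settle in a bad
    basin; a small deep ensemble (members differ only in their random
    state) averages such a member away. Exposes the subset of the
    classifier API the pipeline needs.
    """

    def __init__(self, members: list[HybridStressClassifier]):
        self.members = members
        self.classes_ = members[0].classes_
        self.loss_trace_ = members[0].loss_trace_

    def predict_proba(self, X) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _fit_classifier(x: np.ndarray, y: np.ndarray, kwargs: dict, seed: int, ensemble: int):
    if ensemble <= 1:
        return HybridStressClassifier(random_state=seed, **kwargs).fit(x, y)
    members = [
        HybridStressClassifier(
            random_state=(seed + 1000 * r) % (2**31), **kwargs
        ).fit(x, y)
        for r in range(ensemble)
    ]
    return _SeededEnsemble(members)


def run_experiment(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full stress-detection pipeline from a config mapping.

    Config keys (all optional unless noted):

    * ``synthetic``: kwargs for :class:`SynthSpec` — or ``data``: a mapping
      ``{path, format}`` for :func:`read_recording`;
    * ``seed``: master seed (default 0), used for synthesis, splitting,
      selection and training;
    * ``preprocess``: bool (default True) — FIR band-pass + packet denoise;
    * ``k``: channels to select (default 15, clipped rule NOT applied — a
      ``k`` larger than the channel count is a config error);
    * ``selector`` / ``classifier``: kwarg overrides for the selector and
      classifier;
    * ``split_ratio``: training fraction (default 0.7);
    * ``ensemble``: seeded training replicates whose predicted class
      probabilities are averaged (default 3; 1 trains a single model).

    Returns a dict with the metric report, confusion counts, selected
    channels, fitness trace, loss trace and per-trial test predictions;
    writes the same artifacts under ``out_dir`` when given.
    """
    seed = int(config.get("seed", 0))
    with _stage("data"):
        if "data" in config:
            src = config["data"]
            trials = read_recording(src["path"], src.get("format", "csv"))
        else:
            spec_kwargs = dict(config.get("synthetic", {}))
            spec_kwargs.setdefault("seed", seed)
            spec = SynthSpec(**spec_kwargs)
            trials = generate_synthetic_dataset(spec)

    with _stage("split"):
        train, test = split_trials(trials, config.get("split_ratio", 0.7), seed)

    if config.get("preprocess", True):
        with _stage("preprocess"):
            fir = FIRBandpass()
            den = WaveletPacketDenoiser()
            train = den.transform(fir.transform(train))
            test = den.transform(fir.transform(test))

    with _stage("select"):
        selector = CrowSearchChannelSelector(
            k=int(config.get("k", 15)),
            random_state=seed,
            **config.get("selector", {}),
        )
        selector.fit(train)
        channels = selector.selected_channels_

    with _stage("extract"):
        extractor = MEFExtractor(channels=[int(c) for c in channels])
        x_train = extractor.transform(train)
        x_test = extractor.transform(test)

    with _stage("train"):
        clf = _fit_classifier(
            x_train.to_numpy(),
            train.label_array().astype(str),
            config.get("classifier", {}),
            seed,
            ensemble=int(config.get("ensemble", 3)),
        )

    with _stage("evaluate"):
        y_pred = clf.predict(x_test.to_numpy())
        counts = ConfusionCounts.from_predictions(test.label_array(), y_pred)
        report = compute_metrics(counts)

    result = {
        "metrics": report.as_dict(),
        "confusion": asdict(counts),
        "channels": [int(c) for c in channels],
        "fitness_trace": selector.fitness_trace_.tolist(),
        "loss_trace": clf.loss_trace_.tolist(),
        "test_labels": list(test.label_array()),
        "test_predictions": list(y_pred),
        "seed": seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        x_train.to_csv(out_dir / "features_train.csv", index=False)
        x_test.to_csv(out_dir / "features_test.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(result, indent=1))
    return result
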