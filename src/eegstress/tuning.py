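"""Employee optimization algorithm (EOA) for hyper-parameter tuning.

A population of "employees" lives in the unit cube; each member decodes to
one hyper-parameter setting (log-uniformly for learning rate and weight
decay, linearly for momentum). Fitness is the error returned by a
user-supplied objective (for the stress classifier: validation error of a
short truncated training run). Each iteration an elite fraction passes
unchanged (the reward policy); the rest move either against a random peer
(exploration) or against the best member (exploitation), with greedy
acceptance so a member only changes when its error improves. The
exploration probability anneals linearly from 1 to 0 across iterations.

The printed update rules step away from the reference member for positive
step factors; greedy acceptance still yields monotone progress. The
``toward_reference`` switch flips the sign to attraction-style updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["EOAParams", "eoa_step", "eoa_optimize", "decode_member", "tune_classifier"]

#: (low, high, scale) decode bounds for the three tuned hyper-parameters.
DEFAULT_BOUNDS: tuple[tuple[float, float, str], ...] = (
    (1e-4, 1e-1, "log"),  # learning rate
    (1e-6, 1e-2, "log"),  # weight decay
    (0.5, 0.99, "linear"),  # momentum
)


@dataclass
class EOAParams:
    n_employees: int = 20
    iter_max: int = 100
    elite_frac: float = 0.1
    toward_reference: bool = False
    seed: int | None = None
    bounds: Sequence[tuple[float, float, str]] = field(default_factory=lambda: DEFAULT_BOUNDS)


def decode_member(
    member: np.ndarray, bounds: Sequence[tuple[float, float, str]]
) -> np.ndarray:
    """Map unit-cube genes to hyper-parameter values."""
    out = np.empty(len(bounds))
    for i, (lo, hi, scale) in enumerate(bounds):
        g = float(np.clip(member[i], 0.0, 1.0))
        if scale == "log":
            out[i] = lo * (hi / lo) ** g
        elif scale == "linear":
            out[i] = lo + g * (hi - lo)
        else:
            raise ValueError(f"unknown scale {scale!r}")
    return out


def eoa_step(
    member: np.ndarray,
    reference: np.ndarray,
    r: float,
    toward_reference: bool = False,
) -> np.ndarray:
    """One update proposal: step relative to a reference member, clamped.

    The literal rule is ``new = member + r * (member - reference)``; with
    ``toward_reference`` the difference flips sign.
    """
    direction = reference - member if toward_reference else member - reference
    return np.clip(member + r * direction, 0.0, 1.0)


def eoa_optimize(
    objective: Callable[[np.ndarray], float],
    n_vars: int,
    params: EOAParams | None = None,
) -> dict:
    """Minimize ``objective`` over the unit cube with the EOA.

    Returns a dict with ``best_member``, ``best_error``, ``best_decoded``
    (when ``params.bounds`` has ``n_vars`` entries) and the per-iteration
    best-error ``trace`` (non-increasing by elitism and greedy acceptance).
    Non-finite objective values reject the proposing move.
    """
    params = params or EOAParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_employees

    def safe_objective(member: np.ndarray) -> float:
        value = float(objective(member))
        return value if np.isfinite(value) else np.inf

    population = rng.uniform(0.0, 1.0, size=(n, n_vars))
    errors = np.array([safe_objective(m) for m in population])
    trace = []
    n_elite = max(1, int(np.ceil(params.elite_frac * n)))
    for it in range(params.iter_max):
        explore_p = 1.0 - it / max(params.iter_max, 1)
        order = np.argsort(errors, kind="stable")
        best = population[order[0]].copy()
        elite = set(order[:n_elite].tolist())
        for i in range(n):
            if i in elite:
                continue  # reward policy: elites pass unchanged
            if rng.random() < explore_p:
                ref = population[int(rng.integers(n))]
            else:
                ref = best
            proposal = eoa_step(
                population[i], ref, rng.random(), params.toward_reference
            )
            err = safe_objective(proposal)
            if err < errors[i]:
                population[i] = proposal
                errors[i] = err
        trace.append(float(errors.min()))
    best_idx = int(np.argmin(errors))
    result = {
        "best_member": population[best_idx].copy(),
        "best_error": float(errors[best_idx]),
        "trace": np.asarray(trace),
    }
    if len(params.bounds) == n_vars:
        result["best_decoded"] = decode_member(population[best_idx], params.bounds)
    return result


def tune_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    params: EOAParams | None = None,
    surrogate_epochs: int = 5,
    validation_fraction: float = 0.2,
    classifier_kwargs: dict | None = None,
) -> dict:
    """Tune learning rate, weight decay and momentum of the stress classifier.

    Each candidate is scored by the validation error of a truncated
    (``surrogate_epochs``-epoch) training run on an internal stratified
    split; full-length training is left to the caller with the returned
    values. Returns the ``eoa_optimize`` result with the decoded setting
    under ``best_decoded`` ordered (learning_rate, weight_decay, momentum).
    """
    from sklearn.model_selection import train_test_split

    from .network import HybridStressClassifier

    params = params or EOAParams()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    x_tr, x_val, y_tr, y_val = train_test_split(
        features,
        labels,
        test_size=validation_fraction,
        stratify=labels,
        random_state=params.seed,
    )
    kwargs = dict(classifier_kwargs or {})
    kwargs.setdefault("epochs", surrogate_epochs)
    kwargs.setdefault("random_state", params.seed)

    def objective(member: np.ndarray) -> float:
        lr, decay, mom = decode_member(member, params.bounds)
        clf = HybridStressClassifier(
            learning_rate=lr, weight_decay=decay, momentum=mom, **kwargs
        )
        clf.fit(x_tr, y_tr)
        return float(np.mean(clf.predict(x_val) != y_val))

    return eoa_optimize(objective, n_vars=3, params=params)
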