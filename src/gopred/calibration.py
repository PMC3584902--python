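"""Raw-score -> precision calibration.

Each component predictor produces raw scores on its own scale (bit
scores, naive Bayes log-odds, network outputs).  To put them on a common
footing, predictions made on a labelled benchmark are sorted by raw
score, split into equal-size bins, and the per-bin precision
TP / (TP + FP) is fitted with a standard logistic curve

    P(t) = a / (1 + b * exp(-c * t)),

one model per method.  ``estimate_precision`` then maps any raw score to
an estimated precision in [0, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

_A_MIN = 1e-6
_B_MIN = 1e-9


class ScoredOutcome(NamedTuple):
    """One benchmark prediction: its raw score and whether it was correct."""

    raw_score: float
    is_true_positive: bool


class CalibrationError(RuntimeError):
    """Fit failure; carries best-so-far parameters."""

    def __init__(self, message: str, model: "CalibrationModel"):
        super().__init__(message)
        self.model = model


@dataclass
class CalibrationModel:
    """Logistic precision model P(t) = a / (1 + b * exp(-c t)).

    ``a`` is the precision asymptote in (0, 1]; ``b`` > 0 positions the
    curve; ``c`` > 0 makes precision increase with raw score.
    """

    a: float
    b: float
    c: float
    method_tag: str = ""
    rss: float = float("nan")
    converged: bool = True

    def __call__(self, raw_score: float) -> float:
        return estimate_precision(self, raw_score)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def bin_precision(
    outcomes: Sequence[ScoredOutcome], n_bins: int
) -> list[tuple[float, float, int]]:
    """Equal-size score binning with per-bin precision.

    Outcomes are stably sorted by raw score and split into ``n_bins``
    contiguous groups whose sizes differ by at most one; for each bin the
    mean raw score, precision TP/(TP+FP) and bin size are returned, in
    score order.  Ties at bin boundaries follow the stable sort order, so
    identical scores may straddle adjacent bins.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(outcomes) < n_bins:
        raise ValueError(
            f"{len(outcomes)} outcomes cannot fill {n_bins} bins; lower n_bins"
        )
    ordered = sorted(outcomes, key=lambda o: o.raw_score)
    out = []
    for chunk in np.array_split(np.arange(len(ordered)), n_bins):
        group = [ordered[i] for i in chunk]
        tp = sum(o.is_true_positive for o in group)
        score = sum(o.raw_score for o in group) / len(group)
        out.append((score, tp / len(group), len(group)))
    return out


def _logistic(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a / (1.0 + b * np.exp(-c * t))


def fit_logistic(
    points: Sequence[tuple[float, float, float]],
    method_tag: str = "",
) -> CalibrationModel:
    """Weighted least-squares fit of the logistic precision curve.

    ``points`` are (raw score, precision, weight) triples, typically the
    output of :func:`bin_precision` with bin size as weight.  ``a`` is
    bounded to (0, 1] and ``b`` to (0, inf).  On optimizer
    non-convergence a :class:`CalibrationError` is raised carrying the
    best parameters found.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points to fit the logistic")
    t = np.asarray([p[0] for p in points], dtype=float)
    prec = np.asarray([p[1] for p in points], dtype=float)
    w = np.asarray([p[2] for p in points], dtype=float)
    if np.any((prec < 0) | (prec > 1)):
        raise ValueError("precisions must lie in [0, 1]")
    sw = np.sqrt(np.maximum(w, 0.0))

    # init: a = max observed precision; c = 1; b so the curve passes
    # through the median point
    a0 = float(np.clip(prec.max(), 0.05, 1.0))
    c0 = 1.0
    med = len(points) // 2
    t_med, p_med = t[med], max(prec[med], 1e-3)
    b0 = max((a0 / p_med - 1.0) * math.exp(c0 * t_med), _B_MIN)
    # guard against overflow in the initial point
    b0 = min(b0, 1e12)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, log_b, c = theta
        return sw * (_logistic(t, a, math.exp(log_b), c) - prec)

    result = least_squares(
        residuals,
        x0=np.array([a0, math.log(b0), c0]),
        bounds=([_A_MIN, math.log(_B_MIN), -np.inf], [1.0, 50.0, np.inf]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    a, log_b, c = result.x
    model = CalibrationModel(
        a=float(a), b=float(math.exp(log_b)), c=float(c),
        method_tag=method_tag,
        rss=float(np.sum(result.fun**2)),
        converged=bool(result.status > 0),
    )
    if not model.converged:
        raise CalibrationError("logistic fit did not converge", model)
    return model


def estimate_precision(model: CalibrationModel, raw_score: float) -> float:
    """Estimated precision for a raw score, clamped to [0, 1]."""
    if not math.isfinite(raw_score):
        raise ValueError("raw score must be finite")
    z = -model.c * raw_score
    if z > 700:  # exp overflow: deep in the low-score tail
        return 0.0
    return float(min(max(model.a / (1.0 + model.b * math.exp(z)), 0.0), 1.0))


def calibrate(
    outcomes: Sequence[ScoredOutcome],
    n_bins: int = 10,
    method_tag: str = "",
    weighted: bool = True,
) -> CalibrationModel:
    """Bin benchmark outcomes and fit the logistic precision curve."""
    bins = bin_precision(outcomes, n_bins)
    points = [(s, p, n if weighted else 1.0) for s, p, n in bins]
    return fit_logistic(points, method_tag=method_tag)
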