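"""Model-free metacognitive sensitivity: type-2 ROC area and calibration.

The type-2 ROC plots, for increasingly liberal confidence criteria, the
cumulative fraction of correct responses (hits) against the cumulative
fraction of incorrect responses (false alarms).  Confidence is first binned
(``equal_width`` on [0.5, 1] by default, or ``equal_count`` quantile bins),
the criterion sweeps from the most to the least confident bin, anchors
(0, 0) and (1, 1) are attached, and the area is the trapezoidal integral
over the anchored points.  AUC 0.5 means confidence carries no information
about correctness; 1 means perfect separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, UndefinedAUCError

BIN_MODES = ("equal_width", "equal_count")


@dataclass(frozen=True)
class Type2ROC:
    points: tuple  # ((far, hr), ...) with anchors (0,0) and (1,1)
    auc: float
    n_correct: int
    n_incorrect: int
    bin_edges: tuple

    def __post_init__(self):
        pts = tuple((float(x), float(y)) for x, y in self.points)
        object.__setattr__(self, "points", pts)
        xs, ys = zip(*pts)
        if pts[0] != (0.0, 0.0) or pts[-1] != (1.0, 1.0):
            raise DomainError("points must be anchored at (0,0) and (1,1)")
        if np.any(np.diff(xs) < -1e-12) or np.any(np.diff(ys) < -1e-12):
            raise DomainError("ROC points must be non-decreasing in both coordinates")
        if not 0.0 <= self.auc <= 1.0:
            raise DomainError("auc must lie in [0, 1]")


def _validate_inputs(correct, confidence):
    correct = np.asarray(correct, dtype=bool)
    confidence = np.asarray(confidence, dtype=float)
    if correct.shape != confidence.shape or correct.ndim != 1:
        raise DomainError("correct and confidence must be 1-d arrays of equal length")
    if correct.size == 0:
        raise DomainError("at least one trial required")
    return correct, confidence


def bin_confidence(confidences, k: int = 5, mode: str = "equal_width") -> np.ndarray:
    """Assign confidence values to bins 1..k (k = most confident).

    ``equal_width`` partitions [0.5, 1] into k half-open intervals, the top
    bin closed at 1.0.  ``equal_count`` places edges at the i/k empirical
    quantiles; values equal to an edge fall into the lower bin.
    """
    conf = np.asarray(confidences, dtype=float)
    if conf.ndim != 1 or conf.size == 0:
        raise DomainError("confidences must be a non-empty 1-d sequence")
    if k < 2:
        raise DomainError("k must be >= 2")
    if mode == "equal_width":
        edges = np.linspace(0.5, 1.0, k + 1)
        labels = np.searchsorted(edges[1:-1], conf, side="right") + 1
    elif mode == "equal_count":
        interior = np.quantile(conf, np.arange(1, k) / k)
        labels = np.searchsorted(interior, conf, side="left") + 1
    else:
        raise DomainError(f"unknown bin mode {mode!r}; expected one of {BIN_MODES}")
    return labels.astype(int)


def bin_edges(confidences, k: int = 5, mode: str = "equal_width") -> np.ndarray:
    """Edges (length k+1) implied by the binning rule, endpoints included."""
    conf = np.asarray(confidences, dtype=float)
    if mode == "equal_width":
        return np.linspace(0.5, 1.0, k + 1)
    interior = np.quantile(conf, np.arange(1, k) / k)
    return np.concatenate([[conf.min()], interior, [conf.max()]])


def type2_roc(
    correct,
    confidence,
    k: int = 5,
    mode: str = "equal_width",
    *,
    participant_id=None,
) -> Type2ROC:
    """Build the anchored type-2 ROC and its trapezoidal AUC.

    Raises
    ------
    UndefinedAUCError
        If the trial set contains no incorrect (or no correct) responses;
        the hit/false-alarm construction is then degenerate and returning a
        default would silently bias group comparisons.
    """
    correct, confidence = _validate_inputs(correct, confidence)
    n_correct = int(correct.sum())
    n_incorrect = int(correct.size - n_correct)
    if n_correct == 0 or n_incorrect == 0:
        who = f" (participant {participant_id})" if participant_id is not None else ""
        raise UndefinedAUCError(
            f"type-2 AUC undefined with {n_correct} correct and "
            f"{n_incorrect} incorrect trials{who}",
            participant_id=participant_id,
        )

    labels = bin_confidence(confidence, k=k, mode=mode)
    hit_counts = np.bincount(labels[correct], minlength=k + 1)[1:]
    fa_counts = np.bincount(labels[~correct], minlength=k + 1)[1:]
    # sweep from the most confident bin (k) down to bin 1
    cum_hits = np.cumsum(hit_counts[::-1]) / n_correct
    cum_fas = np.cumsum(fa_counts[::-1]) / n_incorrect

    xs = np.concatenate([[0.0], cum_fas])
    ys = np.concatenate([[0.0], cum_hits])
    # the final cumulative point is exactly (1, 1)
    xs[-1], ys[-1] = 1.0, 1.0
    auc = float(np.trapezoid(ys, xs))
    return Type2ROC(
        points=tuple(zip(xs, ys)),
        auc=auc,
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        bin_edges=tuple(bin_edges(confidence, k=k, mode=mode)),
    )


def calibration_metrics(correct, confidence) -> tuple[float, float, float]:
    """Mean confidence, accuracy, and their gap (positive = overconfident)."""
    correct, confidence = _validate_inputs(correct, confidence)
    mean_conf = float(confidence.mean())
    accuracy = float(correct.mean())
    return mean_conf, accuracy, mean_conf - accuracy


def permutation_null_auc(
    correct,
    confidence,
    n_perm: int,
    rng: np.random.Generator,
    k: int = 5,
    mode: str = "equal_width",
) -> np.ndarray:
    """Null AUC distribution from shuffling confidence against correctness.

    Bin labels are computed once (the shuffled multiset of confidences is
    unchanged, hence so are the bin edges) and permuted, which makes each
    permutation O(n + k).
    """
    correct, confidence = _validate_inputs(correct, confidence)
    if n_perm < 0:
        raise DomainError("n_perm must be >= 0")
    if n_perm == 0:
        return np.empty(0)
    n_correct = int(correct.sum())
    n_incorrect = int(correct.size - n_correct)
    if n_correct == 0 or n_incorrect == 0:
        raise UndefinedAUCError(
            "null AUC undefined without both correct and incorrect trials"
        )
    labels = bin_confidence(confidence, k=k, mode=mode)
    out = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        hit = np.bincount(perm[correct], minlength=k + 1)[1:]
        fa = np.bincount(perm[~correct], minlength=k + 1)[1:]
        ys = np.concatenate([[0.0], np.cumsum(hit[::-1]) / n_correct])
        xs = np.concatenate([[0.0], np.cumsum(fa[::-1]) / n_incorrect])
        xs[-1], ys[-1] = 1.0, 1.0
        out[i] = np.trapezoid(ys, xs)
    return out
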