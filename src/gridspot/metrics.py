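"""Detection and localization metrics for point-set predictions.

Predictions and ground truth are matched with the Hungarian method on
the Euclidean distance matrix.  The headline score is the F1 integral:
the F1 score is evaluated at 50 linearly spaced distance cutoffs on
[0, 3] px, integrated with the trapezoidal rule, and normalized by the
maximal area, giving a value in [0, 1] that rewards both detecting spots
and placing them precisely.  Localization precision on its own is the
RMSE over true-positive pairs matched at the 3 px cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "MatchResult",
    "MetricsReport",
    "match_at_cutoff",
    "f1_at_cutoff",
    "f1_score_at",
    "f1_integral",
    "rmse_true_positives",
    "evaluate",
]

DEFAULT_CUTOFF = 3.0
N_CUTOFFS = 50

# cost assigned to pred/truth pairs farther apart than the cutoff; any
# feasible pair (distance <= cutoff <= a few px) is cheaper by orders of
# magnitude, so the assignment maximizes the number of feasible pairs
# first and minimizes total distance among those
_INFEASIBLE = 1e9


@dataclass
class MatchResult:
    """Hungarian assignment between predictions and ground truth at a cutoff.

    ``pairs`` holds (pred_index, truth_index, distance) for every matched
    pair; ``fp``/``fn`` count unmatched predictions/truths.
    """

    pairs: list[tuple[int, int, float]]
    fp: int
    fn: int
    cutoff: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs], dtype=np.float64)


def _as_points(x) -> np.ndarray:
    pts = np.asarray(x, dtype=np.float64)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) coordinates, got shape {pts.shape}")
    return pts


def match_at_cutoff(pred, truth, cutoff: float = DEFAULT_CUTOFF) -> MatchResult:
    """Optimally assign predictions to ground-truth spots within a cutoff.

    Solves the minimum-cost assignment on the Euclidean distance matrix
    with distances above ``cutoff`` replaced by a prohibitive constant,
    then drops infeasible pairs.  The retained pairing is a maximal
    matching under the cutoff with minimal total distance (non-strict
    comparison: distance == cutoff matches).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    p, t = _as_points(pred), _as_points(truth)
    if len(p) == 0 or len(t) == 0:
        return MatchResult([], fp=len(p), fn=len(t), cutoff=cutoff)
    dist = cdist(p, t)
    cost = np.where(dist <= cutoff, dist, _INFEASIBLE)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(i), int(j), float(dist[i, j]))
        for i, j in zip(rows, cols)
        if dist[i, j] <= cutoff
    ]
    return MatchResult(pairs, fp=len(p) - len(pairs), fn=len(t) - len(pairs),
                       cutoff=cutoff)


def f1_at_cutoff(match: MatchResult) -> float:
    """F1 = 2*TP / (2*TP + FP + FN); defined as 0 when all three are 0."""
    denom = 2 * match.tp + match.fp + match.fn
    if denom == 0:
        return 0.0
    return 2.0 * match.tp / denom


def f1_score_at(pred, truth, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Convenience: match at ``cutoff`` and return the F1 score."""
    return f1_at_cutoff(match_at_cutoff(pred, truth, cutoff))


def f1_integral(pred, truth, max_cutoff: float = DEFAULT_CUTOFF,
                n_cutoffs: int = N_CUTOFFS) -> float:
    """Area under the F1-vs-cutoff curve, normalized to [0, 1].

    F1 is evaluated at ``n_cutoffs`` linearly spaced cutoffs on
    [0, max_cutoff] (endpoints included), integrated by the trapezoidal
    rule and divided by ``max_cutoff`` (the maximal area).
    """
    cutoffs = np.linspace(0.0, max_cutoff, n_cutoffs)
    scores = [f1_score_at(pred, truth, c) for c in cutoffs]
    return float(np.trapezoid(scores, cutoffs) / max_cutoff)


def rmse_true_positives(match: MatchResult) -> float:
    """Localization RMSE sqrt(sum(d_i^2)/n) over matched pairs.

    Returns NaN (undefined) when there are no true positives; callers
    exclude such images from aggregates.
    """
    if match.tp == 0:
        return float("nan")
    d = match.distances
    return float(np.sqrt((d * d).sum() / len(d)))


@dataclass
class MetricsReport:
    """Per-image metrics and their aggregates across a set of images."""

    per_image: pd.DataFrame
    f1_integral_mean: float = field(init=False)
    f1_integral_sd: float = field(init=False)
    f1_at_3px_mean: float = field(init=False)
    f1_at_3px_sd: float = field(init=False)
    rmse_mean: float = field(init=False)
    rmse_sd: float = field(init=False)

    def __post_init__(self):
        df = self.per_image
        self.f1_integral_mean, self.f1_integral_sd = _mean_sd(df["f1_integral"])
        self.f1_at_3px_mean, self.f1_at_3px_sd = _mean_sd(df["f1_at_3px"])
        # rmse undefined (NaN) for images without true positives
        self.rmse_mean, self.rmse_sd = _mean_sd(df["rmse"].dropna())

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": [self.f1_integral_mean, self.f1_at_3px_mean,
                         self.rmse_mean],
                "sd": [self.f1_integral_sd, self.f1_at_3px_sd, self.rmse_sd],
            },
            index=["f1_integral", "f1_at_3px", "rmse"],
        )

    def __str__(self) -> str:
        return (
            f"f1_integral {self.f1_integral_mean:.4f} ± {self.f1_integral_sd:.4f}"
            f" | f1@3px {self.f1_at_3px_mean:.4f} ± {self.f1_at_3px_sd:.4f}"
            f" | rmse {self.rmse_mean:.4f} ± {self.rmse_sd:.4f} px"
        )


def _mean_sd(series: pd.Series) -> tuple[float, float]:
    # sample sd (ddof=1); a singleton reports sd 0, an empty series NaN
    if len(series) == 0:
        return float("nan"), float("nan")
    mean = float(series.mean())
    sd = 0.0 if len(series) == 1 else float(series.std(ddof=1))
    return mean, sd


def evaluate(pred_sets, truth_sets, cutoff: float = DEFAULT_CUTOFF) -> MetricsReport:
    """Score a list of per-image predictions against matched ground truth.

    Returns per-image F1 integral, F1 at the 3 px cutoff, and true-positive
    RMSE, plus mean ± sample sd aggregates (RMSE aggregated only over
    images with at least one true positive).
    """
    if len(pred_sets) != len(truth_sets):
        raise ValueError(
            f"length mismatch: {len(pred_sets)} predictions vs "
            f"{len(truth_sets)} ground-truth sets"
        )
    rows = []
    for i, (pred, truth) in enumerate(zip(pred_sets, truth_sets)):
        m = match_at_cutoff(pred, truth, cutoff)
        rows.append(
            {
                "image": i,
                "n_pred": len(_as_points(pred)),
                "n_truth": len(_as_points(truth)),
                "tp": m.tp,
                "f1_integral": f1_integral(pred, truth),
                "f1_at_3px": f1_at_cutoff(m),
                "rmse": rmse_true_positives(m),
            }
        )
    return MetricsReport(pd.DataFrame(rows))
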