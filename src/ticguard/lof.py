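"""Per-user Local Outlier Factor model over motion features.

The detector is calibrated once, on an attack-agnostic recording of the
wearer's ordinary movement (nominally two days), and those calibration
points alone define the neighbourhood structure forever after — later
data are scored but never absorbed, so the model cannot drift toward the
very anomalies it is meant to flag.

Scores follow the canonical density-ratio definition.  With d(p, o) the
Euclidean distance between standardized feature vectors:

* k-distance(o): distance from o to its k-th nearest calibration neighbour
  (ties at the boundary are all included, so a neighbourhood may exceed k);
* reach-dist_k(p, o) = max(k-distance(o), d(p, o));
* lrd_k(p) = 1 / mean reach-dist from p to its neighbours;
* LOF_k(p) = mean over neighbours o of lrd_k(o) / lrd_k(p).

Scores near 1 mean the point sits at its neighbours' density; scores well
above 1 mean isolation.  Each calibration point is scored leaving itself
out of its own neighbourhood.

Degenerate geometry is handled explicitly: if all of p's neighbours
coincide with p, every reachability distance is 0 and lrd is taken as
+inf; ratios inf/inf count as 1 (coincident duplicates are mutually
typical) and finite/inf as 0.

The per-window movement probability P_Movement is the flagged fraction of
a rolling buffer of recent windows — the score-to-probability map the
fusion stage consumes.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InsufficientDataError, NotFittedError
from .motion_features import FEATURE_NAMES, MotionFeatureVector, feature_matrix

DEFAULT_K = 20
DEFAULT_THETA_FLOOR = 1.5
DEFAULT_THETA_PERCENTILE = 99.0
DEFAULT_BUFFER_LEN = 10

_SCHEMA = "ticguard.lof/1"


@dataclass
class LOFModel:
    """Fitted calibration neighbourhood + outlier threshold theta."""

    points: np.ndarray          # (n, d) standardized calibration matrix
    means: np.ndarray           # (d,) standardization means
    scales: np.ndarray          # (d,) standardization scales, all > 0
    k: int
    calibration_scores: np.ndarray  # (n,) leave-one-out LOF of each point
    theta: float                # flag a window iff score > theta
    metric: str = "euclidean"

    # cached neighbourhood quantities for query scoring
    _kdist: np.ndarray = field(default=None, repr=False)
    _lrd: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.points.shape[0]


def _neighbourhoods(D: np.ndarray, k: int):
    """k-distances and tie-inclusive neighbour lists for each row of a
    distance matrix whose diagonal has been set to +inf (self-exclusion)."""
    n = D.shape[0]
    part = np.sort(D, axis=1)
    kdist = part[:, k - 1]
    neighbours = [np.flatnonzero(D[i] <= kdist[i]) for i in range(n)]
    return kdist, neighbours


def _lrd_from_reach(reach_means: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(reach_means > 0, 1.0 / reach_means, np.inf)


def _lof_from_lrds(lrd_p: float, lrd_neighbours: np.ndarray) -> float:
    """Mean lrd ratio with the duplicate-point limit conventions."""
    if np.isinf(lrd_p):
        ratios = np.where(np.isinf(lrd_neighbours), 1.0, 0.0)
        return float(np.mean(ratios))
    return float(np.mean(lrd_neighbours) / lrd_p)


def fit_lof(
    calibration: Sequence[MotionFeatureVector] | np.ndarray,
    k: int | None = None,
    theta_floor: float = DEFAULT_THETA_FLOOR,
    theta_percentile: float = DEFAULT_THETA_PERCENTILE,
) -> LOFModel:
    """Fit the calibration neighbourhood and set the outlier threshold.

    ``k=None`` uses the default neighbour count (20, clipped to ``n - 1``
    for small calibration sets); an explicit ``k`` must satisfy ``n > k``.
    The threshold theta is ``max(theta_floor, P99 of calibration scores)``:
    the percentile adapts the cut to each wearer's own score spread while
    the floor keeps clean, tight calibrations from producing a hair-trigger
    cut just above 1.  Refitting on identical input is bit-reproducible.
    """
    X = calibration if isinstance(calibration, np.ndarray) else feature_matrix(calibration)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"calibration must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite calibration features")
    n = X.shape[0]
    k = min(DEFAULT_K, n - 1) if k is None else int(k)
    if k < 1 or n < k + 1:
        raise InsufficientDataError(
            f"need at least k+1 = {k + 1} calibration vectors, got {n}"
        )

    means = X.mean(axis=0)
    scales = X.std(axis=0)
    zero = scales <= 0
    if np.any(zero):
        warnings.warn(
            f"zero-variance feature(s) {[FEATURE_NAMES[i] for i in np.flatnonzero(zero)]}: "
            "scale set to 1",
            stacklevel=2,
        )
        scales = np.where(zero, 1.0, scales)
    Z = (X - means) / scales

    D = cdist(Z, Z)
    np.fill_diagonal(D, np.inf)
    kdist, neighbours = _neighbourhoods(D, k)
    reach_means = np.array(
        [np.mean(np.maximum(kdist[nb], D[i, nb])) for i, nb in enumerate(neighbours)]
    )
    lrd = _lrd_from_reach(reach_means)
    scores = np.array(
        [_lof_from_lrds(lrd[i], lrd[nb]) for i, nb in enumerate(neighbours)]
    )
    theta = max(theta_floor, float(np.percentile(scores, theta_percentile)))

    return LOFModel(
        points=Z,
        means=means,
        scales=scales,
        k=k,
        calibration_scores=scores,
        theta=theta,
        _kdist=kdist,
        _lrd=lrd,
    )


def _check_fitted(model: LOFModel) -> None:
    if model is None or model.points is None or model._lrd is None:
        raise NotFittedError("LOF model is not fitted")


def lof_score(model: LOFModel, point: MotionFeatureVector | np.ndarray) -> float:
    """Outlier score of one query point against the calibration set."""
    return float(lof_scores(model, np.atleast_2d(_as_row(point)))[0])


def lof_scores(model: LOFModel, X: np.ndarray) -> np.ndarray:
    """Vectorised outlier scores for an (m, d) block of query points."""
    _check_fitted(model)
    X = np.asarray(X, dtype=float)
    Z = (X - model.means) / model.scales
    D = cdist(Z, model.points)
    out = np.empty(len(Z))
    for i in range(len(Z)):
        d = D[i]
        kdist_q = np.sort(d)[model.k - 1]
        nb = np.flatnonzero(d <= kdist_q)
        reach = np.maximum(model._kdist[nb], d[nb])
        lrd_q = _lrd_from_reach(np.array([np.mean(reach)]))[0]
        out[i] = _lof_from_lrds(lrd_q, model._lrd[nb])
    return out


def _as_row(point: MotionFeatureVector | np.ndarray) -> np.ndarray:
    if isinstance(point, MotionFeatureVector):
        return point.as_array()
    return np.asarray(point, dtype=float)


@dataclass
class MovementProbabilityState:
    """Rolling buffer of outlier flags; P_Movement = flagged / buffer size.

    The buffer starts zero-filled so the probability is defined (and low)
    from the very first window.
    """

    buffer_len: int = DEFAULT_BUFFER_LEN
    flags: deque = None

    def __post_init__(self):
        if self.flags is None:
            self.flags = deque([0] * self.buffer_len, maxlen=self.buffer_len)

    @property
    def p_movement(self) -> float:
        return sum(self.flags) / self.buffer_len


def update_movement_probability(
    state: MovementProbabilityState,
    model: LOFModel,
    feature: MotionFeatureVector | np.ndarray,
) -> MovementProbabilityState:
    """Score one window, push its flag, return the updated state."""
    score = lof_score(model, feature)
    state.flags.append(1 if score > model.theta else 0)
    return state


# ---------------------------------------------------------------------------
# serialization — one human-inspectable JSON document


def lof_to_doc(model: LOFModel) -> dict:
    """Serializable JSON document for a fitted model."""
    _check_fitted(model)
    return {
        "schema": _SCHEMA,
        "metric": model.metric,
        "k": model.k,
        "theta": model.theta,
        "feature_names": list(FEATURE_NAMES),
        "means": model.means.tolist(),
        "scales": model.scales.tolist(),
        "points": model.points.tolist(),
        "calibration_scores": model.calibration_scores.tolist(),
    }


def save_lof(model: LOFModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(lof_to_doc(model), indent=1), encoding="utf-8")


def lof_from_doc(doc: dict) -> LOFModel:
    """Rebuild a model (including neighbourhood caches) from its document."""
    if doc.get("schema") != _SCHEMA:
        raise ValueError(f"unexpected schema tag {doc.get('schema')!r}")
    Z = np.asarray(doc["points"], dtype=float)
    D = cdist(Z, Z)
    np.fill_diagonal(D, np.inf)
    kdist, neighbours = _neighbourhoods(D, doc["k"])
    reach_means = np.array(
        [np.mean(np.maximum(kdist[nb], D[i, nb])) for i, nb in enumerate(neighbours)]
    )
    return LOFModel(
        points=Z,
        means=np.asarray(doc["means"], dtype=float),
        scales=np.asarray(doc["scales"], dtype=float),
        k=int(doc["k"]),
        calibration_scores=np.asarray(doc["calibration_scores"], dtype=float),
        theta=float(doc["theta"]),
        metric=doc["metric"],
        _kdist=kdist,
        _lrd=_lrd_from_reach(reach_means),
    )


def load_lof(path: str | Path) -> LOFModel:
    return lof_from_doc(json.loads(Path(path).read_text(encoding="utf-8")))
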