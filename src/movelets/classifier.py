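"""Nearest-movelet classification with majority voting.

Every movelet of the incoming stream is compared exhaustively against all
dictionary movelets and labeled with the activity of its closest match.  Two
interchangeable metrics are supported:

* **L2**: the per-channel Euclidean distance, averaged over channels
  (for magnitude data there is a single channel, so no averaging);
* **correlation**: the per-channel sample Pearson correlation (the n-1
  denominator form), averaged over channels, *maximized* rather than
  minimized.  A channel with zero variance in either movelet contributes 0 —
  "no evidence of a match" — which matters for near-constant gyroscope
  windows during stationary postures.

The per-timepoint prediction is then a majority vote among the movelet
starting at the timepoint and the movelets starting over the following
second: up to h + 1 votes at sampling rate h (11 at 10 Hz), fewer near the
end of the stream.  The majority vote proportion v(t) — the fraction of cast
votes won by the winning label — is retained for downstream uncertainty
quantification.

All tie-breaks are deterministic: the dictionary's activity order first,
then earliest movelet; vote ties prefer the tied label holding the single
best-scoring vote.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dictionary import Dictionary
from .io import InsufficientDataError, SensorStream, ValidationError
from .transforms import Movelet, window_samples

logger = logging.getLogger("movelets")

__all__ = [
    "MatchConfig",
    "MoveletMatch",
    "Classification",
    "dist_l2",
    "sim_corr",
    "match_movelet",
    "classify",
]

METRICS = ("l2", "correlation")
DATA_TYPES = ("triaxial", "magnitude")


@dataclass(frozen=True)
class MatchConfig:
    """Metric and data-type setting for one classification run.

    ``votes_per_point`` overrides the size of the majority-vote window
    (default h + 1: the movelet at the timepoint plus the h movelets
    starting over the following second).
    """

    metric: str = "l2"
    data_type: str = "triaxial"
    votes_per_point: int | None = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValidationError(f"metric must be one of {METRICS}")
        if self.data_type not in DATA_TYPES:
            raise ValidationError(f"data_type must be one of {DATA_TYPES}")
        if self.votes_per_point is not None and self.votes_per_point < 1:
            raise ValidationError("votes_per_point must be >= 1")


@dataclass(frozen=True)
class MoveletMatch:
    """Closest dictionary match for one test movelet.

    ``best_score`` is a distance (minimized) under L2 and a similarity
    (maximized) under correlation.  ``activity_scores`` holds each
    activity's own best score, for diagnostics.
    """

    start_time: float
    start_index: int
    best_activity: str
    best_score: float
    activity_scores: dict[str, float] = field(default_factory=dict)


@dataclass
class Classification:
    """Per-timepoint predicted labels with majority-vote diagnostics.

    One entry per timepoint that has at least one movelet starting at it
    (the final n - 1 samples of the stream get no prediction).  Optional
    ``correct_probability``/``excluded`` are filled in by the uncertainty
    module; exclusion flags predictions, it never deletes them.
    """

    times: np.ndarray
    labels: np.ndarray
    vote_proportion: np.ndarray
    n_votes: np.ndarray
    matches: list[MoveletMatch] = field(default_factory=list)
    metric: str = "l2"
    data_type: str = "triaxial"
    correct_probability: np.ndarray | None = None
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.times)
        if not (len(self.labels) == len(self.vote_proportion) == len(self.n_votes) == k):
            raise ValidationError("classification arrays must share length")
        if k and not (
            np.all(self.vote_proportion > 0) and np.all(self.vote_proportion <= 1)
        ):
            raise ValidationError("vote proportions must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Classification":
        """Rebuild a classification from its CSV representation."""
        out = cls(
            times=frame["t"].to_numpy(dtype=float),
            labels=frame["predicted_label"].to_numpy(dtype=str),
            vote_proportion=frame["vote_proportion"].to_numpy(dtype=float),
            n_votes=frame["n_votes"].to_numpy(dtype=int),
        )
        if "correct_probability" in frame.columns:
            out.correct_probability = frame["correct_probability"].to_numpy(dtype=float)
        if "excluded" in frame.columns:
            out.excluded = frame["excluded"].to_numpy(dtype=bool)
        return out

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "t": self.times,
                "predicted_label": self.labels,
                "vote_proportion": self.vote_proportion,
                "n_votes": self.n_votes,
            }
        )
        if self.correct_probability is not None:
            frame["correct_probability"] = self.correct_probability
        if self.excluded is not None:
            frame["excluded"] = self.excluded
        return frame


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_shapes(m: Movelet, m2: Movelet) -> None:
    if m.values.shape != m2.values.shape:
        raise TypeError(
            f"movelet shapes differ: {m.values.shape} vs {m2.values.shape}"
        )


def dist_l2(m: Movelet, m2: Movelet) -> float:
    """Mean over channels of the per-channel Euclidean distance.

    For tri-axial movelets this is (d(x,x') + d(y,y') + d(z,z')) / 3 with
    d the ordinary Euclidean vector distance; for magnitude movelets it is
    the single-channel distance.
    """
    _check_shapes(m, m2)
    per_channel = np.sqrt(np.sum((m.values - m2.values) ** 2, axis=0))
    return float(np.mean(per_channel))


def sim_corr(m: Movelet, m2: Movelet) -> float:
    """Mean over channels of the sample Pearson correlation.

    Uses the (n-1)-denominator form
    r = (1/(n-1)) * sum_i ((a_i - mean(a)) / s_a) ((b_i - mean(b)) / s_b).
    Any channel where either vector is constant (zero standard deviation)
    contributes 0 by convention.
    """
    _check_shapes(m, m2)
    n = m.n
    if n < 2:
        raise ValueError("correlation needs n >= 2 samples")
    total = 0.0
    for c in range(m.n_channels):
        a = m.values[:, c]
        b = m2.values[:, c]
        sa = np.std(a, ddof=1)
        sb = np.std(b, ddof=1)
        if sa == 0.0 or sb == 0.0:
            continue
        total += float(np.sum((a - a.mean()) * (b - b.mean())) / ((n - 1) * sa * sb))
    return total / m.n_channels


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _stacked_dictionary(dictionary: Dictionary):
    """Stack dictionary movelets as (K, n, C) in activity-order-major order.

    The stacking order *is* the tie-break order: numpy argmin/argmax return
    the first optimum, which is the earliest activity in activity_order and,
    within an activity, the earliest movelet.
    """
    mats, labels = [], []
    for activity in dictionary.activity_order:
        for m in dictionary.entries[activity]:
            mats.append(m.values)
            labels.append(activity)
    return np.stack(mats), np.array(labels)


def _score_matrix(
    windows: np.ndarray, dict_mats: np.ndarray, metric: str
) -> np.ndarray:
    """Scores of every test window against every dictionary movelet.

    ``windows``: (T, n, C) test movelets; ``dict_mats``: (K, n, C).
    Returns (T, K): distances for L2, similarities for correlation.
    """
    T, n, C = windows.shape
    K = dict_mats.shape[0]
    if metric == "l2":
        scores = np.empty((T, K))
        # direct differencing keeps the self-match distance exactly zero
        for k in range(K):
            diff = windows - dict_mats[k]
            scores[:, k] = np.sqrt(np.sum(diff * diff, axis=1)).mean(axis=1)
        return scores
    # correlation: standardize per window/channel; zero-variance channels
    # become zero vectors and so contribute exactly 0 to any dot product
    def standardize(a: np.ndarray) -> np.ndarray:
        mean = a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, ddof=1, keepdims=True)
        out = np.zeros_like(a)
        np.divide(a - mean, sd, out=out, where=sd != 0.0)
        return out

    zw = standardize(windows)
    zd = standardize(dict_mats)
    return np.einsum("tnc,knc->tk", zw, zd) / ((n - 1) * C)


def match_movelet(
    m: Movelet, dictionary: Dictionary, cfg: MatchConfig = MatchConfig()
) -> MoveletMatch:
    """Exhaustively scan the dictionary for the closest match to ``m``.

    Closest means minimum mean Euclidean distance under L2, maximum mean
    correlation under the correlation metric.  Exact score ties break by
    the dictionary's activity order, then by movelet position.
    """
    expected_c = 3 if dictionary.data_type == "triaxial" else 1
    if m.n != dictionary.n or m.n_channels != expected_c:
        raise TypeError(
            f"movelet shape {(m.n, m.n_channels)} incompatible with "
            f"dictionary ({dictionary.n}, {expected_c})"
        )
    dict_mats, dict_labels = _stacked_dictionary(dictionary)
    scores = _score_matrix(m.values[None], dict_mats, cfg.metric)[0]
    best_k = int(np.argmin(scores) if cfg.metric == "l2" else np.argmax(scores))
    reduce_ = min if cfg.metric == "l2" else max
    activity_scores = {
        a: float(reduce_(scores[dict_labels == a]))
        for a in dictionary.activity_order
    }
    return MoveletMatch(
        start_time=m.start_time,
        start_index=m.start_index,
        best_activity=str(dict_labels[best_k]),
        best_score=float(scores[best_k]),
        activity_scores=activity_scores,
    )


# ---------------------------------------------------------------------------
# Per-timepoint classification
# ---------------------------------------------------------------------------

def _vote(
    labels: Sequence[str],
    scores: Sequence[float],
    metric: str,
    activity_rank: dict[str, int],
) -> tuple[str, float]:
    """Majority vote with deterministic tie-breaking.

    Ties between labels with equal vote counts go to the tied label holding
    the single best-scoring vote; residual ties (equal best scores) fall
    back to the dictionary activity order.  Returns (label, vote proportion).
    """
    counts = Counter(labels)
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0], top / len(labels)
    sign = 1.0 if metric == "l2" else -1.0
    best_for = {
        lab: min(sign * s for lab2, s in zip(labels, scores) if lab2 == lab)
        for lab in tied
    }
    winner = min(tied, key=lambda lab: (best_for[lab], activity_rank[lab]))
    return winner, top / len(labels)


def classify(
    stream: SensorStream,
    dictionary: Dictionary,
    cfg: MatchConfig = MatchConfig(),
) -> Classification:
    """Classify every timepoint of a stream against a subject's dictionary.

    Each of the stream's movelets is labeled with its closest dictionary
    match; the prediction at timepoint t is the majority vote among the
    movelet starting at t and those starting over the following second
    (up to h + 1 votes, fewer near the stream end).  The final n - 1
    timepoints carry no movelet and get no prediction.
    """
    if stream.data_type != cfg.data_type:
        raise ValidationError(
            f"stream data_type {stream.data_type!r} != config {cfg.data_type!r}"
        )
    if dictionary.data_type != cfg.data_type:
        raise ValidationError(
            f"dictionary data_type {dictionary.data_type!r} != config "
            f"{cfg.data_type!r}"
        )
    if stream.sensor_kind != dictionary.sensor_kind:
        raise ValidationError(
            f"stream sensor {stream.sensor_kind!r} != dictionary "
            f"{dictionary.sensor_kind!r}"
        )
    n = window_samples(dictionary.window_seconds, dictionary.rate_h)
    N = stream.n_samples
    if N < n:
        raise InsufficientDataError(
            f"stream of {N} samples cannot fit one {n}-sample movelet"
        )

    sw = np.lib.stride_tricks.sliding_window_view(stream.values, n, axis=0)
    windows = np.ascontiguousarray(np.swapaxes(sw, 1, 2))  # (T, n, C)
    T = windows.shape[0]
    dict_mats, dict_labels = _stacked_dictionary(dictionary)
    scores = _score_matrix(windows, dict_mats, cfg.metric)
    best_k = (
        np.argmin(scores, axis=1) if cfg.metric == "l2" else np.argmax(scores, axis=1)
    )
    matched_labels = dict_labels[best_k]
    matched_scores = scores[np.arange(T), best_k]

    matches = [
        MoveletMatch(
            start_time=float(stream.timestamps[i]),
            start_index=i,
            best_activity=str(matched_labels[i]),
            best_score=float(matched_scores[i]),
        )
        for i in range(T)
    ]

    h = int(round(stream.rate_h))
    votes_per_point = cfg.votes_per_point or h + 1
    activity_rank = {a: r for r, a in enumerate(dictionary.activity_order)}

    labels = np.empty(T, dtype=object)
    vprop = np.empty(T)
    nvotes = np.empty(T, dtype=int)
    for i in range(T):
        stop = min(i + votes_per_point, T)
        lab, v = _vote(
            matched_labels[i:stop].tolist(),
            matched_scores[i:stop].tolist(),
            cfg.metric,
            activity_rank,
        )
        labels[i] = lab
        vprop[i] = v
        nvotes[i] = stop - i

    reduced = int(np.sum(nvotes < votes_per_point))
    logger.info(
        "classified %d timepoints (%d with reduced vote counts, %.1f%%)",
        T,
        reduced,
        100.0 * reduced / T if T else 0.0,
    )
    return Classification(
        times=stream.timestamps[:T].copy(),
        labels=labels.astype(str),
        vote_proportion=vprop,
        n_votes=nvotes,
        matches=matches,
        metric=cfg.metric,
        data_type=cfg.data_type,
    )
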