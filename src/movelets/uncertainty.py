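"""Uncertainty quantification for movelet classifications.

Given a labeled segment not used to build the dictionary, each predicted
timepoint yields a correctness indicator A(t) (1 when the predicted label
matches the true label) and the majority vote proportion v(t).  A logistic
regression of A(t) on v(t),

    P(A(t) = 1) = exp(b0 + b1 v(t)) / (1 + exp(b0 + b1 v(t))),

turns the vote proportion into an estimated probability that each prediction
is correct.  Predictions whose estimated probability falls below a chosen
threshold are flagged for exclusion; sweeping the threshold from 0 to 1
traces out exclusion proportions and an ROC curve in which sensitivity is
the probability of excluding an *incorrect* prediction and one minus
specificity the probability of excluding a *correct* one.

The fit is plain maximum likelihood.  Degenerate inputs — a single outcome
class, no variation in v, or (quasi-)separation — fall back to a weakly
penalized fit (quadratic penalty 1e-6 on the coefficients) and set a flag
rather than crash a pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .classifier import Classification
from .io import LabelTrack, ValidationError

logger = logging.getLogger("movelets")

__all__ = [
    "CorrectnessSeries",
    "UQModel",
    "correctness_series",
    "fit_uq",
    "predict_correct_prob",
    "apply_threshold",
    "apply_uq",
    "threshold_sweep",
    "exclusion_rates",
    "exclusion_roc",
    "DEFAULT_GRID",
]

#: Threshold grid 0, 0.01, ..., 1 (101 points).
DEFAULT_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)

_PENALTY = 1e-6  # quadratic coefficient penalty for the degenerate-fit fallback


@dataclass
class CorrectnessSeries:
    """Per-timepoint correctness indicator A(t) and vote proportion v(t)."""

    times: np.ndarray
    a: np.ndarray  # 0/1 correctness indicator
    v: np.ndarray  # majority vote proportion in (0, 1]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a = np.asarray(self.a, dtype=int)
        self.v = np.asarray(self.v, dtype=float)
        if not (len(self.times) == len(self.a) == len(self.v)):
            raise ValidationError("correctness series arrays must share length")
        if len(self.a) and not set(np.unique(self.a)) <= {0, 1}:
            raise ValidationError("A(t) must be 0/1")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class UQModel:
    """Fitted logistic coefficients mapping v(t) to P(A(t) = 1).

    ``extra_betas`` holds coefficients of optional additional covariates
    (the default model is intercept + v only).
    """

    beta0: float
    beta1: float
    n_fit: int
    converged: bool = True
    separation: bool = False
    extra_betas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.converged and not (
            np.isfinite(self.beta0) and np.isfinite(self.beta1)
        ):
            raise ValidationError("converged fit must have finite coefficients")


def correctness_series(cls: Classification, track: LabelTrack) -> CorrectnessSeries:
    """Compare predictions with the truth wherever both exist.

    Timepoints without a true label are dropped (their count is logged);
    an empty overlap is an error.
    """
    times, a, v = [], [], []
    dropped = 0
    for i in range(len(cls)):
        truth = track.label_at(float(cls.times[i]))
        if truth is None:
            dropped += 1
            continue
        times.append(cls.times[i])
        a.append(1 if cls.labels[i] == truth else 0)
        v.append(cls.vote_proportion[i])
    if dropped:
        logger.info("correctness series: dropped %d unlabeled timepoints", dropped)
    if not times:
        raise ValidationError("no overlap between predictions and labels")
    return CorrectnessSeries(np.array(times), np.array(a), np.array(v))


def _penalized_logistic(
    design: np.ndarray, y: np.ndarray, penalty: float = _PENALTY
) -> tuple[list[float], bool]:
    """Ridge-penalized logistic fit by Newton iteration.

    ``design`` holds the non-intercept columns.  Minimizes
    -loglik + (penalty/2) * ||beta||^2; the tiny penalty keeps the optimum
    finite under separation or a single-class outcome.
    """
    X = np.column_stack([np.ones(design.shape[0]), design])
    k = X.shape[1]
    beta = np.zeros(k)
    converged = False
    for _ in range(200):
        eta = np.clip(X @ beta, -700, 700)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p) - penalty * beta
        w = p * (1.0 - p)
        hess = X.T @ (X * w[:, None]) + penalty * np.eye(k)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    return [float(b) for b in beta], converged


def fit_uq(
    series: CorrectnessSeries, covariates: np.ndarray | None = None
) -> UQModel:
    """Maximum-likelihood logistic regression of A(t) on (1, v(t)).

    ``covariates`` (n x k) appends additional explanatory variables, e.g.
    predicted-label indicators; the default model is intercept + v only.
    Single-class outcomes, constant v, and detected (quasi-)separation fall
    back to the weakly penalized fit with ``separation=True``.
    """
    if len(series) == 0:
        raise ValidationError("cannot fit on an empty correctness series")
    y = series.a.astype(float)
    x = series.v.astype(float)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(series):
            covariates = covariates.T
        if covariates.shape[0] != len(series):
            raise ValidationError("covariates must have one row per timepoint")
        design = np.column_stack([x, covariates])
    else:
        design = x[:, None]

    degenerate = len(np.unique(y)) < 2 or np.ptp(x) == 0.0
    if not degenerate:
        X = sm.add_constant(design)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", RuntimeWarning)
                res = sm.Logit(y, X).fit(disp=0)
            params = np.asarray(res.params, dtype=float)
            big = np.max(np.abs(params)) > 1e3  # quasi-separation signature
            if res.mle_retvals.get("converged", False) and np.all(
                np.isfinite(params)
            ) and not big:
                return UQModel(
                    beta0=float(params[0]),
                    beta1=float(params[1]),
                    n_fit=len(series),
                    converged=True,
                    separation=False,
                    extra_betas=tuple(float(b) for b in params[2:]),
                )
        except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning):
            pass
        logger.warning("logistic fit degenerate; using penalized fallback")

    betas, converged = _penalized_logistic(design, y)
    return UQModel(
        beta0=betas[0], beta1=betas[1], n_fit=len(series),
        converged=converged, separation=True,
        extra_betas=tuple(betas[2:]),
    )


def predict_correct_prob(
    model: UQModel, v, covariates: np.ndarray | None = None
) -> np.ndarray | float:
    """Estimated probability the prediction is correct at vote proportion v:
    exp(b0 + b1 v) / (1 + exp(b0 + b1 v)), plus any extra covariate terms."""
    if not (np.isfinite(model.beta0) and np.isfinite(model.beta1)):
        raise ValidationError("model coefficients are not finite")
    v_arr = np.asarray(v, dtype=float)
    eta = model.beta0 + model.beta1 * v_arr
    if model.extra_betas:
        if covariates is None:
            raise ValidationError(
                "model was fitted with extra covariates; pass them to predict"
            )
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[1] != len(model.extra_betas):
            covariates = covariates.T
        eta = eta + covariates @ np.asarray(model.extra_betas)
    prob = np.where(
        eta >= 0, 1.0 / (1.0 + np.exp(-eta)), np.exp(eta) / (1.0 + np.exp(eta))
    )
    return float(prob.reshape(-1)[0]) if np.isscalar(v) and prob.size == 1 else prob


def apply_threshold(probs, c: float) -> np.ndarray:
    """Exclusion mask: True wherever the correctness probability is strictly
    below the threshold ``c`` (so c = 0 excludes nothing)."""
    if not 0.0 <= c <= 1.0:
        raise ValidationError(f"threshold must lie in [0, 1], got {c}")
    return np.asarray(probs, dtype=float) < c


def apply_uq(cls: Classification, model: UQModel, threshold: float) -> Classification:
    """Attach correctness probabilities and exclusion flags to a classification.

    Excluded predictions keep their labels; exclusion is a flag so downstream
    evaluation can compute both filtered and unfiltered metrics.
    """
    probs = predict_correct_prob(model, cls.vote_proportion)
    cls.correct_probability = np.asarray(probs, dtype=float)
    cls.excluded = apply_threshold(probs, threshold)
    return cls


def threshold_sweep(probs, grid: np.ndarray = DEFAULT_GRID) -> pd.DataFrame:
    """Proportion of predictions excluded at each threshold of the grid."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValidationError("cannot sweep an empty probability series")
    rows = [
        (float(c), float(np.mean(apply_threshold(probs, float(c))))) for c in grid
    ]
    return pd.DataFrame(rows, columns=["threshold", "prop_excluded"])


def exclusion_rates(
    mask: np.ndarray, a: np.ndarray
) -> tuple[float, float]:
    """(sensitivity, one minus specificity) of one exclusion mask.

    Sensitivity = P(excluded | incorrect); one minus specificity =
    P(excluded | correct).  A class absent from ``a`` yields NaN for its
    coordinate.
    """
    mask = np.asarray(mask, dtype=bool)
    a = np.asarray(a, dtype=int)
    n_incorrect = int(np.sum(a == 0))
    n_correct = int(np.sum(a == 1))
    sens = float(np.sum(mask & (a == 0)) / n_incorrect) if n_incorrect else float("nan")
    fpr = float(np.sum(mask & (a == 1)) / n_correct) if n_correct else float("nan")
    return sens, fpr


def exclusion_roc(
    probs,
    series: CorrectnessSeries,
    grid: np.ndarray = DEFAULT_GRID,
) -> pd.DataFrame:
    """Exclusion proportions and ROC coordinates over a threshold grid.

    Columns: threshold, prop_excluded, sensitivity, one_minus_specificity.
    Thresholding at 0 excludes nothing, giving the ROC origin (0, 0).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size != len(series):
        raise ValidationError("probability series and correctness series differ")
    rows = []
    for c in grid:
        mask = apply_threshold(probs, float(c))
        sens, fpr = exclusion_rates(mask, series.a)
        rows.append((float(c), float(np.mean(mask)), sens, fpr))
    return pd.DataFrame(
        rows,
        columns=["threshold", "prop_excluded", "sensitivity", "one_minus_specificity"],
    )
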