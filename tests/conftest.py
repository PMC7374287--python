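"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (plain-Python double loops,
textbook Newton-Raphson) so they cannot share a code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

import movelets as mv

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def oracle_match(values, entries, metric):
    """Brute-force closest-match scan.

    ``values``: (n, C) array-like; ``entries``: list of (activity, list of
    (n, C) arrays) in tie-break order.  Plain Python loops throughout.
    Returns (best_activity, best_score).
    """
    values = [list(row) for row in np.asarray(values, dtype=float)]
    n = len(values)
    n_ch = len(values[0])
    best = None
    for activity, movelets in entries:
        for dm in movelets:
            dm = [list(row) for row in np.asarray(dm, dtype=float)]
            if metric == "l2":
                total = 0.0
                for c in range(n_ch):
                    ss = 0.0
                    for i in range(n):
                        ss += (values[i][c] - dm[i][c]) ** 2
                    total += math.sqrt(ss)
                score = total / n_ch
                better = best is None or score < best[1]
            else:
                total = 0.0
                for c in range(n_ch):
                    a = [values[i][c] for i in range(n)]
                    b = [dm[i][c] for i in range(n)]
                    ma = sum(a) / n
                    mb = sum(b) / n
                    sa = math.sqrt(sum((v - ma) ** 2 for v in a) / (n - 1))
                    sb = math.sqrt(sum((v - mb) ** 2 for v in b) / (n - 1))
                    if sa == 0.0 or sb == 0.0:
                        continue
                    total += sum(
                        (a[i] - ma) * (b[i] - mb) for i in range(n)
                    ) / ((n - 1) * sa * sb)
                score = total / n_ch
                better = best is None or score > best[1]
            if better:
                best = (activity, score)
    return best


def oracle_logistic(x, y, tol=1e-12, max_iter=100):
    """Textbook Newton-Raphson for the two-parameter logistic MLE.

    Model: P(y=1) = 1 / (1 + exp(-(b0 + b1 x))).  Returns (b0, b1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    b0 = b1 = 0.0
    for _ in range(max_iter):
        eta = b0 + b1 * x
        p = 1.0 / (1.0 + np.exp(-eta))
        g0 = float(np.sum(y - p))
        g1 = float(np.sum((y - p) * x))
        w = p * (1.0 - p)
        h00 = float(np.sum(w))
        h01 = float(np.sum(w * x))
        h11 = float(np.sum(w * x * x))
        det = h00 * h11 - h01 * h01
        if det == 0.0:
            break
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        b0 += d0
        b1 += d1
        if max(abs(d0), abs(d1)) < tol:
            break
    return b0, b1


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_stream(values, rate_h=10.0, sensor_kind="gyroscope", t0=0.0, **kw):
    """Small helper: stream from an (N, C) array on a regular grid."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    channels = ("x", "y", "z") if values.shape[1] == 3 else ("magnitude",)
    return mv.SensorStream(
        sensor_kind=sensor_kind,
        placement="front_pocket",
        rate_h=rate_h,
        timestamps=t0 + np.arange(values.shape[0]) / rate_h,
        values=values,
        channels=channels,
        **kw,
    )


@pytest.fixture(scope="session")
def fixture_study():
    return mv.gen_study_fixture(seed=1)


@pytest.fixture(scope="session")
def gyro_dictionary(fixture_study):
    return mv.build_dictionary(
        fixture_study.training.gyro, fixture_study.training.track
    )


@pytest.fixture(scope="session")
def course_classification(fixture_study, gyro_dictionary):
    return mv.classify(
        fixture_study.course.gyro,
        gyro_dictionary,
        mv.MatchConfig("l2", "triaxial"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
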